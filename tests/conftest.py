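import numpy as np
import pytest

from cccbench import CellTypePair, ExpressionDataset, LRDatabase, SyntheticConfig, generate_dataset


@pytest.fixture
def tiny_ds() -> ExpressionDataset:
    """3 genes x 4 cells, two cell types, handcrafted values."""
    return ExpressionDataset(
        matrix=np.array(
            [
                [1.0, 0.0, 2.0, 3.0],
                [0.0, 4.0, 0.0, 1.0],
                [5.0, 5.0, 5.0, 5.0],
            ]
        ),
        gene_symbols=["Tgfb1", "Tgfbr1", "Apoe"],
        cell_ids=["c1", "c2", "c3", "c4"],
        cell_types=["A", "A", "B", "B"],
        dataset_id="tiny",
    )


@pytest.fixture
def two_type_ds() -> ExpressionDataset:
    """A moderately sized two-type dataset drawn once from the generator."""
    cfg = SyntheticConfig(
        n_genes=50,
        cell_counts={"sender": 80, "receiver": 40},
        planted_pairs=[("LigandP01", "ReceptorP01", "sender", "receiver", 6.0)],
        dropout_rate=0.1,
        seed=42,
    )
    return generate_dataset(cfg, 1)


@pytest.fixture
def ab_pair() -> CellTypePair:
    return CellTypePair("A", "B")


@pytest.fixture
def tiny_lrdb() -> LRDatabase:
    return LRDatabase(pairs=[("Tgfb1", "Tgfbr1"), ("Apoe", "Tgfb1")])
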