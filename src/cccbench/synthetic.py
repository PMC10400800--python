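"""Synthetic scRNA-seq datasets with planted ligand-receptor signal.

Counts are drawn per gene and cell from a negative binomial (the standard
overdispersed count model for UMI data), with an independent Bernoulli
technical-dropout layer on top.  A planted pair (ligand L, receptor R,
sender type s, receiver type r, fold change f) raises L's mean to
``baseline * f`` in sender cells and R's mean to ``baseline * f`` in
receiver cells, so co-expression of the pair marks the s -> r channel.

Replicate datasets ("mice") share every generative parameter and differ
only through a per-replicate derived seed, emulating biological replicates
whose communication pattern should be recovered consistently.  The default
cell-type composition mirrors a brain-like mixture with strongly unequal
type sizes (two abundant glial types, two sparse types).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Set, Tuple

import numpy as np

from .core import ExpressionDataset, LRDatabase, child_seed
from .io import write_expression, write_lr_pairs

__all__ = ["SyntheticConfig", "generate_dataset", "generate_replicates", "truth_set", "write_fixture"]


def _default_cell_counts() -> Dict[str, int]:
    # unequal, >= 4 types: abundant astrocytes/oligodendrocytes vs sparse
    # endothelial/microglia, a few hundred cells per replicate in total
    return {
        "astrocyte": 260,
        "endothelial": 60,
        "microglia": 45,
        "oligodendrocyte": 220,
    }


def _default_planted() -> List[Tuple[str, str, str, str, float]]:
    return [
        (f"LigandP{i:02d}", f"ReceptorP{i:02d}", "astrocyte", "endothelial", 6.0)
        for i in range(1, 6)
    ]


@dataclass
class SyntheticConfig:
    """Generative parameters shared by all replicate datasets.

    ``dispersion`` is the negative-binomial size parameter theta
    (variance = mean + mean^2 / theta); ``dropout_rate`` is the probability
    that any single count is zeroed by the technical layer.
    """

    n_genes: int = 200
    cell_counts: Dict[str, int] = field(default_factory=_default_cell_counts)
    baseline_mean: float = 1.0
    dispersion: float = 2.0
    planted_pairs: List[Tuple[str, str, str, str, float]] = field(default_factory=_default_planted)
    dropout_rate: float = 0.1
    n_replicate_datasets: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if any(c < 1 for c in self.cell_counts.values()):
            raise ValueError("every cell type needs >= 1 cells")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must lie in [0, 1)")
        types = set(self.cell_counts)
        for lig, rec, sender, receiver, fold in self.planted_pairs:
            if fold < 1.0:
                raise ValueError(f"fold change must be >= 1 (pair {lig}-{rec})")
            if sender not in types or receiver not in types:
                raise ValueError(f"planted pair {lig}-{rec} names unknown cell type")

    def gene_symbols(self) -> List[str]:
        """Background symbols G0001.. with planted genes appended (unique)."""
        background = [f"G{i:04d}" for i in range(1, self.n_genes + 1)]
        planted: List[str] = []
        for lig, rec, *_ in self.planted_pairs:
            for g in (lig, rec):
                if g in background:
                    raise ValueError(f"planted gene name {g!r} collides with background")
                if g not in planted:
                    planted.append(g)
        n_background = self.n_genes - len(planted)
        if n_background < 0:
            raise ValueError("more planted genes than n_genes")
        return background[:n_background] + planted


def _mean_matrix(cfg: SyntheticConfig, symbols: List[str], cell_types: List[str]) -> np.ndarray:
    means = np.full((len(symbols), len(cell_types)), cfg.baseline_mean)
    gene_row = {g: i for i, g in enumerate(symbols)}
    types = np.asarray(cell_types)
    for lig, rec, sender, receiver, fold in cfg.planted_pairs:
        means[gene_row[lig], types == sender] = cfg.baseline_mean * fold
        means[gene_row[rec], types == receiver] = cfg.baseline_mean * fold
    return means


def generate_dataset(cfg: SyntheticConfig, replicate_index: int = 1) -> ExpressionDataset:
    """Draw one replicate dataset from the shared generative model."""
    if replicate_index < 1:
        raise ValueError("replicate_index must be >= 1")
    rng = np.random.default_rng(child_seed(cfg.seed, "synthetic", replicate_index))
    symbols = cfg.gene_symbols()
    cell_types: List[str] = []
    cell_ids: List[str] = []
    for label in sorted(cfg.cell_counts):
        for i in range(cfg.cell_counts[label]):
            cell_types.append(label)
            cell_ids.append(f"r{replicate_index}_{label}_{i + 1:04d}")
    means = _mean_matrix(cfg, symbols, cell_types)
    theta = cfg.dispersion
    counts = rng.negative_binomial(theta, theta / (theta + means)).astype(float)
    if cfg.dropout_rate > 0:
        keep = rng.random(counts.shape) >= cfg.dropout_rate
        counts *= keep
    return ExpressionDataset(
        matrix=counts,
        gene_symbols=symbols,
        cell_ids=cell_ids,
        cell_types=cell_types,
        dataset_id=f"synthetic_rep{replicate_index}",
    )


def generate_replicates(cfg: SyntheticConfig) -> List[ExpressionDataset]:
    """All replicate datasets of the configuration (the synthetic 'mice')."""
    return [generate_dataset(cfg, r) for r in range(1, cfg.n_replicate_datasets + 1)]


def truth_set(cfg: SyntheticConfig) -> Set[Tuple[str, str]]:
    """The planted (ligand, receptor) pairs, oriented sender -> receiver."""
    return {(lig, rec) for lig, rec, *_ in cfg.planted_pairs}


def lr_database(cfg: SyntheticConfig, n_decoys: int = 20, seed: int | None = None) -> LRDatabase:
    """Planted pairs plus decoy pairs drawn from background genes.

    Decoys pair background genes (no planted signal) so scorers face
    plausible negatives; the draw is deterministic for a given seed.
    """
    symbols = cfg.gene_symbols()
    planted_genes = {g for lig, rec, *_ in cfg.planted_pairs for g in (lig, rec)}
    background = [g for g in symbols if g not in planted_genes]
    rng = np.random.default_rng(child_seed(cfg.seed if seed is None else seed, "decoys"))
    pairs = [(lig, rec) for lig, rec, *_ in cfg.planted_pairs]
    seen = set(pairs)
    while len(pairs) < len(cfg.planted_pairs) + n_decoys:
        l, r = rng.choice(len(background), size=2, replace=False)
        cand = (background[int(l)], background[int(r)])
        if cand not in seen:
            seen.add(cand)
            pairs.append(cand)
    return LRDatabase(pairs=pairs)


def write_fixture(cfg: SyntheticConfig, outdir, n_decoys: int = 20, fmt_mtx: bool = True) -> Dict[str, str]:
    """Write a complete on-disk fixture: expression, annotations, LR table.

    For each replicate an expression CSV (plus an MTX directory unless
    ``fmt_mtx=False``) and an annotation TSV are written; one LR-pair TSV
    covers planted plus decoy pairs.  A ``manifest.tsv`` records dataset
    ids, seeds and paths.  Same config + seed twice -> byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_rows = []
    paths: Dict[str, str] = {}
    for r in range(1, cfg.n_replicate_datasets + 1):
        ds = generate_dataset(cfg, r)
        csv_path = outdir / f"{ds.dataset_id}.csv"
        write_expression(ds, csv_path, fmt="csv")
        if fmt_mtx:
            write_expression(ds, outdir / ds.dataset_id, fmt="mtx")
        manifest_rows.append(
            (ds.dataset_id, str(child_seed(cfg.seed, "synthetic", r)), csv_path.name)
        )
        paths[ds.dataset_id] = str(csv_path)
    lr_path = outdir / "lr_pairs.tsv"
    write_lr_pairs(lr_database(cfg, n_decoys=n_decoys), lr_path)
    paths["lr_pairs"] = str(lr_path)
    manifest = outdir / "manifest.tsv"
    with open(manifest, "w") as fh:
        fh.write("dataset_id\tseed\tpath\n")
        for row in manifest_rows:
            fh.write("\t".join(row) + "\n")
    paths["manifest"] = str(manifest)
    return paths
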