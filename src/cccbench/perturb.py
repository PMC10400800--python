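"""Perturbation generators used to probe CCC-method robustness.

Six dataset constructions are supported: biological replicates (pairing of
independent datasets), simulated replicates (per-type cell subsampling at
proportion p), Gaussian expression noise (per-gene entry replacement from
Normal(mean_g, var_g)), dropout (random zeroing of matrix positions),
cell-type label permutation, and gene-symbol permutation (corrupting
ligand-receptor lookup).  All generators are deterministic under a seed,
and all ``round(p * n)`` counts use round-half-away-from-zero per stratum.
"""

from __future__ import annotations

import itertools
from typing import List, Sequence, Tuple

import numpy as np

from .core import (
    ExpressionDataset,
    GeneNoiseStats,
    PerturbationSpec,
    PERTURBATION_KINDS,
    child_seed,
    round_half_up,
)

__all__ = [
    "pair_biological_replicates",
    "sample_replicate",
    "gene_noise_stats",
    "add_gaussian_noise",
    "apply_dropout",
    "permute_cell_labels",
    "permute_gene_symbols",
    "generate_batch",
    "apply_perturbation",
]


def pair_biological_replicates(
    datasets: Sequence[ExpressionDataset],
) -> List[Tuple[ExpressionDataset, ExpressionDataset]]:
    """All unordered pairs (i < j) of independent replicate datasets.

    Datasets must share a common gene universe; each is restricted to the
    intersection (original gene order of the first member preserved).
    """
    if len(datasets) < 2:
        raise ValueError("need at least 2 datasets to form biological replicate pairs")
    common = set(datasets[0].gene_symbols)
    for ds in datasets[1:]:
        common &= set(ds.gene_symbols)
    if not common:
        raise ValueError("datasets share no genes")
    restricted = []
    for ds in datasets:
        if set(ds.gene_symbols) == common:
            restricted.append(ds)
        else:
            keep = [i for i, g in enumerate(ds.gene_symbols) if g in common]
            restricted.append(
                ExpressionDataset(
                    matrix=ds.matrix[keep, :],
                    gene_symbols=[ds.gene_symbols[i] for i in keep],
                    cell_ids=ds.cell_ids,
                    cell_types=ds.cell_types,
                    dataset_id=ds.dataset_id,
                )
            )
    return list(itertools.combinations(restricted, 2))


def sample_replicate(ds: ExpressionDataset, p: float, seed: int) -> ExpressionDataset:
    """Subsample round(p * n_c) cells per cell type without replacement.

    Emulates a batch-effect replicate of the same tissue.  Cell order of
    the original dataset is preserved; p = 1 returns the identical cell set.
    """
    if not (0.0 < p <= 1.0):
        raise ValueError("sampling proportion must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    keep = np.zeros(ds.n_cells, dtype=bool)
    types = np.asarray(ds.cell_types)
    for label in sorted(set(ds.cell_types)):
        idx = np.flatnonzero(types == label)
        k = round_half_up(p * len(idx))
        if k == 0:
            raise ValueError(
                f"sampling proportion {p} leaves 0 cells of type {label!r}"
            )
        chosen = rng.choice(idx, size=k, replace=False)
        keep[chosen] = True
    return ds.select_cells(keep)


def gene_noise_stats(ds: ExpressionDataset) -> GeneNoiseStats:
    """Per-gene mean and population variance (denominator n) over all cells."""
    if ds.n_cells < 2:
        raise ValueError("need at least 2 cells to estimate gene noise statistics")
    return GeneNoiseStats(
        mean=ds.matrix.mean(axis=1),
        variance=ds.matrix.var(axis=1),  # ddof=0: population variance
    )


def add_gaussian_noise(ds: ExpressionDataset, p: float, seed: int) -> ExpressionDataset:
    """Replace round(p * n_cells) entries per gene by Normal(mean_g, var_g) draws.

    Models expression divergence between cells: a p fraction of each gene's
    values is regenerated from that gene's own Gaussian noise distribution,
    the remaining (1 - p) stays exactly original.  Negative draws are
    clipped to 0 to preserve non-negativity.
    """
    if not (0.0 <= p <= 1.0):
        raise ValueError("noising proportion must lie in [0, 1]")
    out = ds.copy()
    if p == 0.0:
        return out
    stats = gene_noise_stats(ds)
    sd = np.sqrt(stats.variance)
    rng = np.random.default_rng(seed)
    k = round_half_up(p * ds.n_cells)
    if k == 0:
        return out
    for g in range(ds.n_genes):
        cols = rng.choice(ds.n_cells, size=k, replace=False)
        draws = rng.normal(stats.mean[g], sd[g], size=k)
        out.matrix[g, cols] = np.clip(draws, 0.0, None)
    return out


def apply_dropout(
    ds: ExpressionDataset, p: float, seed: int, nonzero_only: bool = False
) -> ExpressionDataset:
    """Set round(p * n_positions) uniformly chosen matrix positions to 0.

    By default all positions (including already-zero ones) are eligible;
    ``nonzero_only=True`` restricts the draw to currently expressed entries.
    """
    if not (0.0 <= p <= 1.0):
        raise ValueError("dropout proportion must lie in [0, 1]")
    out = ds.copy()
    rng = np.random.default_rng(seed)
    if nonzero_only:
        eligible = np.flatnonzero(out.matrix.ravel() > 0)
    else:
        eligible = np.arange(out.matrix.size)
    k = round_half_up(p * len(eligible))
    if k == 0:
        return out
    chosen = rng.choice(eligible, size=k, replace=False)
    flat = out.matrix.ravel()
    flat[chosen] = 0.0
    out.matrix = flat.reshape(out.matrix.shape)
    return out


def permute_cell_labels(ds: ExpressionDataset, p: float, seed: int) -> ExpressionDataset:
    """Permute the type labels of a round(p * n_cells) cell subset.

    A true permutation within the chosen subset: the label multiset (and
    hence per-type cell counts) of the whole dataset is preserved, only the
    assignment of labels to cells is corrupted.  Expression is untouched.
    """
    if not (0.0 <= p <= 1.0):
        raise ValueError("permuting proportion must lie in [0, 1]")
    if len(set(ds.cell_types)) != 2:
        raise ValueError("cell-label permutation expects a two-cell-type dataset")
    out = ds.copy()
    rng = np.random.default_rng(seed)
    k = round_half_up(p * ds.n_cells)
    if k == 0:
        return out
    chosen = rng.choice(ds.n_cells, size=k, replace=False)
    shuffled = rng.permutation(chosen)
    labels = list(out.cell_types)
    for src, dst in zip(chosen, shuffled):
        labels[dst] = ds.cell_types[src]
    out.cell_types = labels
    return out


def permute_gene_symbols(ds: ExpressionDataset, p: float, seed: int) -> ExpressionDataset:
    """Permute the symbols of a round(p * n_genes) gene subset.

    Matrix rows keep their values; symbols move between the chosen rows,
    corrupting ligand-receptor database lookup (prior-knowledge noise).
    """
    if not (0.0 <= p <= 1.0):
        raise ValueError("permuting proportion must lie in [0, 1]")
    out = ds.copy()
    rng = np.random.default_rng(seed)
    k = round_half_up(p * ds.n_genes)
    if k == 0:
        return out
    chosen = rng.choice(ds.n_genes, size=k, replace=False)
    shuffled = rng.permutation(chosen)
    symbols = list(out.gene_symbols)
    for src, dst in zip(chosen, shuffled):
        symbols[dst] = ds.gene_symbols[src]
    out.gene_symbols = symbols
    return out


_GENERATORS = {
    "simulated_replicate": sample_replicate,
    "gaussian": add_gaussian_noise,
    "dropout": apply_dropout,
    "cell_type_permutation": permute_cell_labels,
    "lr_permutation": permute_gene_symbols,
}


def apply_perturbation(ds: ExpressionDataset, spec: PerturbationSpec) -> ExpressionDataset:
    """Apply the perturbation a spec describes, tagging the output id."""
    gen = _GENERATORS[spec.kind]
    out = gen(ds, spec.proportion, spec.seed)
    out.dataset_id = (
        f"{ds.dataset_id}|{spec.kind}|p={spec.proportion:g}|rep={spec.replicate_index}"
    )
    return out


def generate_batch(
    ds: ExpressionDataset,
    kind: str,
    proportions: Sequence[float],
    n_repeats: int,
    seed: int,
) -> List[Tuple[PerturbationSpec, ExpressionDataset]]:
    """One perturbed dataset per (proportion, repeat).

    Child seeds derive deterministically from (seed, kind, proportion,
    repeat, dataset_id), so a batch is reproducible independent of order.
    """
    if kind not in PERTURBATION_KINDS:
        raise ValueError(f"unknown perturbation kind {kind!r}; valid: {PERTURBATION_KINDS}")
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    out = []
    for p in proportions:
        for rep in range(1, n_repeats + 1):
            spec = PerturbationSpec(
                kind=kind,
                proportion=float(p),
                replicate_index=rep,
                seed=child_seed(seed, kind, f"{float(p):.10g}", rep, ds.dataset_id),
            )
            out.append((spec, apply_perturbation(ds, spec)))
    return out
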