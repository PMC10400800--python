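"""Core domain types for cell-cell communication (CCC) robustness benchmarking.

The central object is :class:`ExpressionDataset`, a dense genes x cells
non-negative expression matrix with gene symbols, cell barcodes and
per-cell type labels.  Ligand-receptor prior knowledge is an ordered
:class:`LRDatabase`; one scoring method's output on one dataset is an
:class:`LRResult` holding a full ranking (scores), optional p-values and
the boolean "inferred" selection set that robustness comparison operates on.
"""

from __future__ import annotations

import hashlib
import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

__all__ = [
    "ExpressionDataset",
    "CellTypePair",
    "LRDatabase",
    "LRResult",
    "PerturbationSpec",
    "GeneNoiseStats",
    "RobustnessRecord",
    "PERTURBATION_KINDS",
    "enumerate_pairs",
    "subset_pair",
    "round_half_up",
    "child_seed",
]

#: Perturbation kinds applied to a dataset (biological replicates are a
#: pairing of independent datasets, not a generator, so they are not here).
PERTURBATION_KINDS = (
    "simulated_replicate",
    "gaussian",
    "dropout",
    "cell_type_permutation",
    "lr_permutation",
)


def round_half_up(x: float) -> int:
    """Round half away from zero (for non-negative x: floor(x + 0.5)).

    Used for every ``round(p * n)`` count so perturbed-entry counts are
    reproducible across platforms (Python's built-in round is banker's).
    """
    if x < 0:
        raise ValueError("round_half_up expects non-negative input")
    return int(math.floor(x + 0.5))


def child_seed(root_seed: int, *parts) -> int:
    """Derive a stable 63-bit child seed from a root seed and context parts.

    The derivation hashes the string rendering of ``(root_seed, *parts)``,
    so batches are reproducible independent of execution order.
    """
    key = "\x1f".join(str(p) for p in (root_seed, *parts))
    digest = hashlib.blake2b(key.encode("utf-8"), digest_size=8).digest()
    return int.from_bytes(digest, "little") >> 1


@dataclass
class ExpressionDataset:
    """A genes x cells expression matrix with cell-type annotations.

    Invariants enforced on construction: non-negative finite values,
    unique gene symbols, unique cell ids, one type label per cell.
    """

    matrix: np.ndarray
    gene_symbols: List[str]
    cell_ids: List[str]
    cell_types: List[str]
    dataset_id: str = "dataset"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.gene_symbols = list(self.gene_symbols)
        self.cell_ids = list(self.cell_ids)
        self.cell_types = list(self.cell_types)
        if self.matrix.ndim != 2:
            raise ValueError("expression matrix must be 2-dimensional")
        n_genes, n_cells = self.matrix.shape
        if len(self.gene_symbols) != n_genes:
            raise ValueError(
                f"{len(self.gene_symbols)} gene symbols for {n_genes} matrix rows"
            )
        if len(self.cell_ids) != n_cells:
            raise ValueError(
                f"{len(self.cell_ids)} cell ids for {n_cells} matrix columns"
            )
        if len(self.cell_types) != n_cells:
            raise ValueError("cell_types must provide one label per cell")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("expression matrix contains non-finite values")
        if np.any(self.matrix < 0):
            bad = int(np.sum(self.matrix < 0))
            raise ValueError(f"expression matrix contains {bad} negative values")
        dup_genes = _duplicates(self.gene_symbols)
        if dup_genes:
            raise ValueError(f"duplicate gene symbols: {sorted(dup_genes)[:10]}")
        dup_cells = _duplicates(self.cell_ids)
        if dup_cells:
            raise ValueError(f"duplicate cell ids: {sorted(dup_cells)[:10]}")

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[1]

    def type_counts(self) -> Dict[str, int]:
        counts: Dict[str, int] = {}
        for t in self.cell_types:
            counts[t] = counts.get(t, 0) + 1
        return counts

    def cells_of_type(self, label: str) -> np.ndarray:
        """Boolean mask over cells with the given type label."""
        return np.array([t == label for t in self.cell_types], dtype=bool)

    def gene_index(self) -> Dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_symbols)}

    def select_cells(self, mask: np.ndarray, dataset_id: Optional[str] = None) -> "ExpressionDataset":
        """New dataset keeping cells where ``mask`` is True, order preserved."""
        mask = np.asarray(mask, dtype=bool)
        idx = np.flatnonzero(mask)
        return ExpressionDataset(
            matrix=self.matrix[:, idx].copy(),
            gene_symbols=list(self.gene_symbols),
            cell_ids=[self.cell_ids[i] for i in idx],
            cell_types=[self.cell_types[i] for i in idx],
            dataset_id=dataset_id or self.dataset_id,
        )

    def copy(self, dataset_id: Optional[str] = None) -> "ExpressionDataset":
        return ExpressionDataset(
            matrix=self.matrix.copy(),
            gene_symbols=list(self.gene_symbols),
            cell_ids=list(self.cell_ids),
            cell_types=list(self.cell_types),
            dataset_id=dataset_id or self.dataset_id,
        )


def _duplicates(items: Sequence[str]) -> Set[str]:
    seen: Set[str] = set()
    dups: Set[str] = set()
    for it in items:
        if it in seen:
            dups.add(it)
        seen.add(it)
    return dups


@dataclass(frozen=True)
class CellTypePair:
    """An ordered (sender, receiver) cell-type pair.

    Sender cells contribute ligand expression; receiver cells contribute
    receptor expression.  Order matters: (A, B) and (B, A) are distinct.
    """

    sender: str
    receiver: str

    def __post_init__(self) -> None:
        if self.sender == self.receiver:
            raise ValueError("sender and receiver cell types must differ")

    def __str__(self) -> str:  # used in dataset ids and report rows
        return f"{self.sender}->{self.receiver}"


@dataclass
class LRDatabase:
    """Ordered, duplicate-free list of (ligand gene, receptor gene) pairs."""

    pairs: List[Tuple[str, str]]

    def __post_init__(self) -> None:
        self.pairs = [(str(l), str(r)) for l, r in self.pairs]
        dup = _duplicates([f"{l}\x1f{r}" for l, r in self.pairs])
        if dup:
            raise ValueError("LRDatabase contains duplicate ligand-receptor pairs")

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    def genes(self) -> Set[str]:
        out: Set[str] = set()
        for l, r in self.pairs:
            out.add(l)
            out.add(r)
        return out


@dataclass
class LRResult:
    """One method's output on one dataset.

    ``scores`` is the full ranking; ``selected`` is the inferred set S used
    by the Jaccard robustness indicator; ``pvalues`` is present only for
    permutation- or test-based scorers.
    """

    method: str
    dataset_id: str
    scores: Dict[Tuple[str, str], float]
    pvalues: Optional[Dict[Tuple[str, str], float]] = None
    selected: Set[Tuple[str, str]] = field(default_factory=set)
    extras: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not set(self.selected) <= set(self.scores):
            raise ValueError("selected pairs must be a subset of scored pairs")
        if self.pvalues is not None:
            for pair, p in self.pvalues.items():
                if not (0.0 <= p <= 1.0):
                    raise ValueError(f"p-value out of [0,1] for pair {pair}: {p}")

    def top_k(self, k: int) -> Set[Tuple[str, str]]:
        """Top-k pairs by score descending, ties broken lexicographically."""
        if k < 1:
            raise ValueError("k must be >= 1")
        ordered = sorted(self.scores.items(), key=lambda kv: (-kv[1], kv[0]))
        return {pair for pair, _ in ordered[:k]}


@dataclass(frozen=True)
class PerturbationSpec:
    """Identifies one perturbed dataset: kind, proportion p, replicate, seed."""

    kind: str
    proportion: float
    replicate_index: int
    seed: int

    def __post_init__(self) -> None:
        if self.kind not in PERTURBATION_KINDS:
            raise ValueError(
                f"unknown perturbation kind {self.kind!r}; valid: {PERTURBATION_KINDS}"
            )
        if not (0.0 <= self.proportion <= 1.0):
            raise ValueError("proportion must lie in [0, 1]")
        if self.replicate_index < 1:
            raise ValueError("replicate_index must be >= 1")


@dataclass
class GeneNoiseStats:
    """Per-gene mean and population variance of expression over all cells."""

    mean: np.ndarray
    variance: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.variance = np.asarray(self.variance, dtype=float)
        if np.any(self.variance < 0):
            raise ValueError("variance must be non-negative")


@dataclass(frozen=True)
class RobustnessRecord:
    """One Jaccard value: (method, kind, proportion, dataset, compared pair).

    ``kind`` is a perturbation kind or ``biological_replicate``; biological
    replicates carry ``proportion=None``.
    """

    method: str
    kind: str
    proportion: Optional[float]
    dataset_id: str
    pair_id: str
    jaccard: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.jaccard <= 1.0):
            raise ValueError("jaccard must lie in [0, 1]")


def normalize_log1p_cpm(ds: ExpressionDataset, scale: float = 1e4) -> ExpressionDataset:
    """log1p counts-per-``scale`` normalization for raw count matrices.

    Each cell's counts are scaled to sum to ``scale`` (all-zero cells are
    left at zero) and log1p-transformed.  Scoring statistics built on
    quantiles behave poorly on raw integer counts (heavy ties); this is
    the standard preprocessing applied when the input is raw counts.
    """
    totals = ds.matrix.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = np.where(totals > 0, ds.matrix * (scale / totals), 0.0)
    out = ds.copy()
    out.matrix = np.log1p(scaled)
    return out


def enumerate_pairs(cell_types: Sequence[str]) -> List[CellTypePair]:
    """All ordered (sender, receiver) pairs of distinct labels.

    Duplicated labels are collapsed first; output is lexicographic, so
    k distinct labels yield exactly k*(k-1) pairs in a deterministic order.
    """
    labels = sorted(set(cell_types))
    if len(labels) < 2:
        raise ValueError("need at least 2 distinct cell-type labels")
    return [CellTypePair(s, r) for s, r in itertools.permutations(labels, 2)]


def subset_pair(ds: ExpressionDataset, pair: CellTypePair) -> ExpressionDataset:
    """Restrict a dataset to the cells of one sender/receiver type pair.

    Gene set and cell order are preserved; the subset's dataset_id is
    suffixed with the pair so downstream records stay identifiable.
    """
    present = set(ds.cell_types)
    for label in (pair.sender, pair.receiver):
        if label not in present:
            raise ValueError(f"cell type {label!r} absent from dataset {ds.dataset_id}")
    mask = np.array([t in (pair.sender, pair.receiver) for t in ds.cell_types], bool)
    counts = ds.type_counts()
    if counts.get(pair.sender, 0) == 0 or counts.get(pair.receiver, 0) == 0:
        raise ValueError("both cell types must have at least one cell")
    return ds.select_cells(mask, dataset_id=f"{ds.dataset_id}|{pair}")
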