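"""File I/O: dense CSV/TSV and MatrixMarket expression matrices, annotation
tables, ligand-receptor pair tables, and per-method result files.

On-disk matrices may be genes x cells or cells x genes; orientation is
resolved by matching annotation cell ids to an axis (override with
``orientation=``).  All writers are deterministic: re-writing the same
object is byte-identical.
"""

from __future__ import annotations

import logging
import os
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .core import ExpressionDataset, LRDatabase, LRResult

logger = logging.getLogger(__name__)

__all__ = [
    "read_annotations",
    "read_expression",
    "write_expression",
    "read_lr_pairs",
    "write_lr_pairs",
    "read_result",
    "write_result",
]

_HEADER_TOKENS = {
    "ligand", "receptor", "ligand_gene", "receptor_gene",
    "ligand_symbol", "receptor_symbol", "from", "to", "source", "target",
}

#: floats in report/result files carry 6 significant digits
FLOAT_FMT = "%.6g"


def read_annotations(path: str | os.PathLike) -> Dict[str, str]:
    """Read a 2-column (cell_id, cell_type) TSV with a header row."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"annotation table {path} needs >= 2 columns")
    ids = df.iloc[:, 0].tolist()
    if len(set(ids)) != len(ids):
        raise ValueError(f"annotation table {path} contains duplicate cell ids")
    return dict(zip(ids, df.iloc[:, 1].tolist()))


def _detect_format(path: Path) -> str:
    if path.is_dir() or path.suffix == ".mtx":
        return "mtx"
    if path.suffix in (".tsv", ".txt"):
        return "tsv"
    return "csv"


def read_expression(
    path: str | os.PathLike,
    annotations: str | os.PathLike | Dict[str, str],
    fmt: Optional[str] = None,
    dataset_id: Optional[str] = None,
    orientation: str = "auto",
) -> ExpressionDataset:
    """Read an expression matrix plus cell annotations into a dataset.

    Parameters
    ----------
    path
        CSV/TSV file (first column = gene symbol, header = cell ids), a
        ``matrix.mtx`` file, or a directory holding ``matrix.mtx`` +
        ``genes.tsv`` + ``barcodes.tsv``.
    annotations
        Path to a (cell_id, cell_type) TSV, or an already-loaded mapping.
    orientation
        ``auto`` matches annotation ids against both axes; ``genes_x_cells``
        or ``cells_x_genes`` force an orientation.
    """
    path = Path(path)
    fmt = fmt or _detect_format(path)
    ann = annotations if isinstance(annotations, dict) else read_annotations(annotations)

    if fmt == "mtx":
        matrix, rows, cols = _read_mtx(path)
    elif fmt in ("csv", "tsv"):
        sep = "," if fmt == "csv" else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        matrix = df.to_numpy(dtype=float)
        rows = [str(x) for x in df.index]
        cols = [str(x) for x in df.columns]
    else:
        raise ValueError(f"unknown expression format {fmt!r}")

    rows, cols, matrix = _orient(rows, cols, matrix, ann, orientation)

    missing = [c for c in cols if c not in ann]
    if missing:
        raise ValueError(
            f"{len(missing)} cells present in matrix but absent from annotations "
            f"(first offenders: {missing[:5]})"
        )
    return ExpressionDataset(
        matrix=matrix,
        gene_symbols=rows,
        cell_ids=cols,
        cell_types=[ann[c] for c in cols],
        dataset_id=dataset_id or path.stem,
    )


def _orient(rows, cols, matrix, ann, orientation):
    if orientation == "genes_x_cells":
        return rows, cols, matrix
    if orientation == "cells_x_genes":
        return cols, rows, matrix.T
    if orientation != "auto":
        raise ValueError(f"unknown orientation {orientation!r}")
    col_hits = sum(c in ann for c in cols)
    row_hits = sum(r in ann for r in rows)
    if col_hits >= row_hits:
        return rows, cols, matrix
    return cols, rows, matrix.T


def _read_mtx(path: Path) -> Tuple[np.ndarray, List[str], List[str]]:
    if path.is_dir():
        mtx_path = path / "matrix.mtx"
        genes_path = path / "genes.tsv"
        barcodes_path = path / "barcodes.tsv"
    else:
        mtx_path = path
        genes_path = path.with_name("genes.tsv")
        barcodes_path = path.with_name("barcodes.tsv")
    for p in (mtx_path, genes_path, barcodes_path):
        if not p.exists():
            raise FileNotFoundError(f"MTX sidecar file missing: {p}")
    mat = scipy.io.mmread(str(mtx_path))
    if scipy.sparse.issparse(mat):
        mat = mat.toarray()
    rows = [line.split("\t")[0] for line in _read_lines(genes_path)]
    cols = [line.split("\t")[0] for line in _read_lines(barcodes_path)]
    return np.asarray(mat, dtype=float), rows, cols


def _read_lines(path: Path) -> List[str]:
    with open(path) as fh:
        return [line.rstrip("\n") for line in fh if line.strip()]


def write_expression(
    ds: ExpressionDataset,
    path: str | os.PathLike,
    fmt: str = "csv",
    write_annotations: bool = True,
) -> None:
    """Write a dataset to disk (csv/tsv file or mtx directory).

    The annotation TSV is written next to the matrix as
    ``<stem>.annotations.tsv`` (csv/tsv) or ``annotations.tsv`` (mtx dir).
    """
    path = Path(path)
    if fmt in ("csv", "tsv"):
        sep = "," if fmt == "csv" else "\t"
        df = pd.DataFrame(ds.matrix, index=ds.gene_symbols, columns=ds.cell_ids)
        df.index.name = "gene"
        df.to_csv(path, sep=sep, float_format="%.17g")
        ann_path = path.with_name(path.stem + ".annotations.tsv")
    elif fmt == "mtx":
        path.mkdir(parents=True, exist_ok=True)
        sparse = scipy.sparse.coo_matrix(ds.matrix)
        scipy.io.mmwrite(str(path / "matrix.mtx"), sparse, precision=17)
        _write_lines(path / "genes.tsv", ds.gene_symbols)
        _write_lines(path / "barcodes.tsv", ds.cell_ids)
        ann_path = path / "annotations.tsv"
    else:
        raise ValueError(f"unknown expression format {fmt!r}")
    if write_annotations:
        ann = pd.DataFrame({"cell_id": ds.cell_ids, "cell_type": ds.cell_types})
        ann.to_csv(ann_path, sep="\t", index=False)


def _write_lines(path: Path, lines: Iterable[str]) -> None:
    with open(path, "w") as fh:
        for line in lines:
            fh.write(f"{line}\n")


def read_lr_pairs(path: str | os.PathLike, header: Optional[bool] = None) -> LRDatabase:
    """Read a two-column (ligand, receptor) delimited table.

    ``header=None`` auto-detects: the first row is skipped iff both fields
    look like header tokens (e.g. "ligand"/"receptor"); pass True/False to
    override.  Duplicate rows are dropped with a logged count.
    """
    rows: List[Tuple[str, str]] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t") if "\t" in line else line.split(",")
            if len(fields) < 2:
                raise ValueError(f"ligand-receptor table {path}: row has <2 columns: {line!r}")
            rows.append((fields[0].strip(), fields[1].strip()))
    if rows:
        first = rows[0]
        looks_like_header = (
            first[0].lower() in _HEADER_TOKENS and first[1].lower() in _HEADER_TOKENS
        )
        skip = looks_like_header if header is None else header
        if skip:
            rows = rows[1:]
    seen = set()
    pairs: List[Tuple[str, str]] = []
    for pair in rows:
        if pair in seen:
            continue
        seen.add(pair)
        pairs.append(pair)
    dropped = len(rows) - len(pairs)
    if dropped:
        logger.warning("dropped %d duplicate ligand-receptor rows from %s", dropped, path)
    return LRDatabase(pairs=pairs)


def write_lr_pairs(db: LRDatabase, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("ligand\treceptor\n")
        for l, r in db.pairs:
            fh.write(f"{l}\t{r}\n")


def write_result(result: LRResult, path: str | os.PathLike) -> None:
    """Write an LRResult as a TSV: (ligand, receptor, score, pvalue, selected)."""
    with open(path, "w") as fh:
        fh.write("ligand\treceptor\tscore\tpvalue\tselected\n")
        for (l, r) in sorted(result.scores):
            score = FLOAT_FMT % result.scores[(l, r)]
            if result.pvalues is not None and (l, r) in result.pvalues:
                pval = FLOAT_FMT % result.pvalues[(l, r)]
            else:
                pval = "NA"
            sel = "1" if (l, r) in result.selected else "0"
            fh.write(f"{l}\t{r}\t{score}\t{pval}\t{sel}\n")


def read_result(path: str | os.PathLike, method: str = "", dataset_id: str = "") -> LRResult:
    """Read an LRResult TSV, validating every field."""
    df = pd.read_csv(path, sep="\t", dtype={"ligand": str, "receptor": str})
    for col in ("ligand", "receptor", "score", "selected"):
        if col not in df.columns:
            raise ValueError(f"result file {path} missing column {col!r}")
    scores: Dict[Tuple[str, str], float] = {}
    pvalues: Dict[Tuple[str, str], float] = {}
    selected = set()
    for row in df.itertuples(index=False):
        pair = (row.ligand, row.receptor)
        score = float(row.score)
        if not np.isfinite(score):
            raise ValueError(f"result file {path}: non-finite score for {pair}")
        scores[pair] = score
        pval = getattr(row, "pvalue", None)
        if pval is not None and not pd.isna(pval):
            pvalues[pair] = float(pval)
        if int(row.selected) == 1:
            selected.add(pair)
    return LRResult(
        method=method or str(path),
        dataset_id=dataset_id,
        scores=scores,
        pvalues=pvalues or None,
        selected=selected,
    )
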