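"""Jaccard-based robustness quantification, aggregation, ranking, reports.

The robustness of a CCC method is the stability of its inferred
ligand-receptor set S under perturbation.  For replicated data the Jaccard
coefficient is computed between replicate results at each proportion p;
for noise perturbations it is computed between the original result S_o and
each noised result S_i^p.  Per-proportion means are averaged (unweighted)
into an overall ("OV") value per perturbation kind, from which methods are
ranked (rank 1 = most robust; the overall rank is the mean of per-kind
ranks).

Empty-set convention: Jaccard({}, {}) = 1.0 (a method returning nothing on
both datasets is perfectly consistent) and 0.0 when exactly one side is
empty; the 0/0 case is logged whenever the convention is applied.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
import scipy.stats

from .core import LRResult, PerturbationSpec, RobustnessRecord

logger = logging.getLogger(__name__)

__all__ = [
    "jaccard",
    "jaccard_top_k",
    "evaluate_replicates",
    "evaluate_noise",
    "records_to_frame",
    "read_records",
    "average_jaccard",
    "summary_table",
    "rank_methods",
    "pairwise_method_agreement",
    "build_report",
]

FLOAT_FMT = "%.6g"


def jaccard(a: Set, b: Set) -> float:
    """|a ∩ b| / |a ∪ b|, with 1.0 for two empty sets and 0.0 for one."""
    a, b = set(a), set(b)
    if not a and not b:
        logger.debug("jaccard: both sets empty, applying convention -> 1.0")
        return 1.0
    union = a | b
    return len(a & b) / len(union)


def jaccard_top_k(a: LRResult, b: LRResult, k: int) -> float:
    """Jaccard of the top-k pairs of each result ranked by score descending.

    k is capped at each result's number of scored pairs; ties are broken
    by (ligand, receptor) lexicographic order for determinism.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    top_a = a.top_k(min(k, len(a.scores))) if a.scores else set()
    top_b = b.top_k(min(k, len(b.scores))) if b.scores else set()
    return jaccard(top_a, top_b)


def _common_method(results: Iterable[LRResult]) -> str:
    methods = {r.method for r in results}
    if len(methods) != 1:
        raise ValueError(f"results mix methods: {sorted(methods)}")
    return methods.pop()


def evaluate_replicates(
    grouped: Mapping[Optional[float], Sequence[LRResult]],
    kind: str = "simulated_replicate",
    dataset_id: str = "",
) -> List[RobustnessRecord]:
    """Jaccard between every unordered result pair within each proportion group.

    For biological replicates pass a single group keyed by ``None`` and
    ``kind="biological_replicate"``.  Groups with fewer than two results
    are skipped with a warning.
    """
    records: List[RobustnessRecord] = []
    for proportion, results in grouped.items():
        if len(results) < 2:
            logger.warning(
                "replicate group (kind=%s, p=%s) has %d result(s); skipped",
                kind, proportion, len(results),
            )
            continue
        method = _common_method(results)
        for i in range(len(results)):
            for j in range(i + 1, len(results)):
                records.append(
                    RobustnessRecord(
                        method=method,
                        kind=kind,
                        proportion=proportion,
                        dataset_id=dataset_id or results[i].dataset_id,
                        pair_id=f"{results[i].dataset_id}|vs|{results[j].dataset_id}",
                        jaccard=jaccard(results[i].selected, results[j].selected),
                    )
                )
    return records


def evaluate_noise(
    original: LRResult,
    noised: Sequence[Tuple[PerturbationSpec, LRResult]],
    dataset_id: str = "",
) -> List[RobustnessRecord]:
    """Jaccard between the original result S_o and each noised result S_i^p."""
    records: List[RobustnessRecord] = []
    for spec, result in noised:
        if result.method != original.method:
            raise ValueError(
                f"method mismatch: original {original.method!r} vs noised {result.method!r}"
            )
        records.append(
            RobustnessRecord(
                method=original.method,
                kind=spec.kind,
                proportion=spec.proportion,
                dataset_id=dataset_id or original.dataset_id,
                pair_id=f"original|vs|rep{spec.replicate_index}",
                jaccard=jaccard(original.selected, result.selected),
            )
        )
    return records


def records_to_frame(records: Sequence[RobustnessRecord]) -> pd.DataFrame:
    """Long-form table: method, kind, proportion, dataset_id, pair_id, jaccard."""
    return pd.DataFrame(
        {
            "method": [r.method for r in records],
            "kind": [r.kind for r in records],
            "proportion": [np.nan if r.proportion is None else r.proportion for r in records],
            "dataset_id": [r.dataset_id for r in records],
            "pair_id": [r.pair_id for r in records],
            "jaccard": [r.jaccard for r in records],
        }
    )


def read_records(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def average_jaccard(records, level: str = "per_proportion") -> pd.DataFrame:
    """Average Jaccard per (method, kind, proportion) or overall per (method, kind).

    ``overall`` is the unweighted mean of the per-proportion means (each
    proportion block counts equally); biological replicates, which carry no
    proportion, form a single block.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    if df.empty:
        raise ValueError("no robustness records to average")
    per_prop = (
        df.groupby(["method", "kind", "proportion"], dropna=False)["jaccard"]
        .mean()
        .reset_index()
        .rename(columns={"jaccard": "mean_jaccard"})
    )
    if level == "per_proportion":
        return per_prop.sort_values(["method", "kind", "proportion"]).reset_index(drop=True)
    if level == "overall":
        overall = (
            per_prop.groupby(["method", "kind"])["mean_jaccard"]
            .mean()
            .reset_index()
            .rename(columns={"mean_jaccard": "overall_jaccard"})
        )
        return overall.sort_values(["method", "kind"]).reset_index(drop=True)
    raise ValueError("level must be 'per_proportion' or 'overall'")


def summary_table(records, kind: str) -> pd.DataFrame:
    """Heatmap-shaped summary for one perturbation kind.

    Rows = methods; one column per proportion (or none for biological
    replicates) plus an "OV" column holding the unweighted mean of the
    per-proportion averages.  Cells with no records are missing (NaN) and
    excluded from OV.
    """
    per_prop = average_jaccard(records, level="per_proportion")
    sub = per_prop[per_prop["kind"] == kind]
    if sub.empty:
        raise ValueError(f"no records for perturbation kind {kind!r}")
    if sub["proportion"].isna().all():
        table = sub.set_index("method")[["mean_jaccard"]].rename(
            columns={"mean_jaccard": "OV"}
        )
        table = table.sort_index()
    else:
        table = sub.pivot(index="method", columns="proportion", values="mean_jaccard")
        table = table[sorted(table.columns)]
        table.columns = [f"{100 * p:g}%" for p in table.columns]
        table["OV"] = table.mean(axis=1, skipna=True)
        table = table.sort_index()
    table.index.name = "method"
    return table


def rank_methods(overall: pd.DataFrame) -> pd.DataFrame:
    """Rank methods by overall average Jaccard within each perturbation kind.

    Rank 1 = highest average Jaccard; ties share the mean of covered ranks
    (midrank).  The overall rank is the mean of a method's per-kind ranks;
    output rows are sorted ascending by it.
    """
    if isinstance(overall, list):
        overall = average_jaccard(overall, level="overall")
    methods = overall["method"].unique()
    if len(methods) < 2:
        raise ValueError("ranking needs at least 2 methods")
    wide = overall.pivot(index="method", columns="kind", values="overall_jaccard")
    ranks = pd.DataFrame(index=wide.index)
    for kind in wide.columns:
        col = wide[kind]
        valid = col.dropna()
        ranks.loc[valid.index, kind] = scipy.stats.rankdata(-valid.to_numpy(), method="average")
    ranks["overall_rank"] = ranks.mean(axis=1, skipna=True)
    ranks = ranks.sort_values(["overall_rank", "method"], kind="mergesort")
    ranks.index.name = "method"
    return ranks


def pairwise_method_agreement(
    results: Sequence[LRResult],
) -> Tuple[pd.DataFrame, pd.Series]:
    """Cross-method consistency on one dataset.

    Returns the symmetric matrix of Jaccard coefficients between the
    methods' selected sets (unit diagonal) and each method's mean
    agreement with the others (diagonal excluded).
    """
    if len(results) < 2:
        raise ValueError("agreement needs at least 2 methods")
    names = [r.method for r in results]
    if len(set(names)) != len(names):
        raise ValueError("duplicate method names in agreement input")
    n = len(results)
    mat = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = jaccard(results[i].selected, results[j].selected)
    frame = pd.DataFrame(mat, index=names, columns=names)
    mean = (frame.sum(axis=1) - 1.0) / (n - 1)
    mean.name = "mean_agreement"
    return frame, mean


def build_report(
    records: Sequence[RobustnessRecord] | pd.DataFrame,
    outdir,
    agreement: Optional[pd.DataFrame] = None,
) -> List[Path]:
    """Write the tabular robustness report.

    Emits ``records.tsv`` (long form), one ``summary_<kind>.tsv`` per kind
    with records (heatmap-shaped with OV column), and ``ranking.tsv`` when
    >= 2 methods are present; ``agreement.tsv`` when a matrix is supplied.
    Re-running on the same inputs is byte-identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    df = df.sort_values(
        ["method", "kind", "proportion", "dataset_id", "pair_id"], kind="mergesort"
    ).reset_index(drop=True)
    written: List[Path] = []

    path = outdir / "records.tsv"
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
    written.append(path)

    kinds = sorted(df["kind"].unique())
    for kind in kinds:
        try:
            table = summary_table(df, kind)
        except ValueError:
            logger.warning("no records for kind %s; summary omitted", kind)
            continue
        path = outdir / f"summary_{kind}.tsv"
        table.to_csv(path, sep="\t", float_format=FLOAT_FMT)
        written.append(path)

    if df["method"].nunique() >= 2:
        ranking = rank_methods(average_jaccard(df, level="overall"))
        path = outdir / "ranking.tsv"
        ranking.to_csv(path, sep="\t", float_format=FLOAT_FMT)
        written.append(path)

    if agreement is not None:
        path = outdir / "agreement.tsv"
        agreement.to_csv(path, sep="\t", float_format=FLOAT_FMT)
        written.append(path)
    return written
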