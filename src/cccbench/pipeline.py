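"""End-to-end benchmark driver: simulate -> perturb -> score -> evaluate -> report.

The run configuration mirrors the study design the framework emulates:
several replicate source datasets ("mice"), every ordered cell-type pair,
a set of scoring methods, and per-kind perturbation proportions
(cell-subsampling replicates default to 95/90/85%, noise and permutation
perturbations to 5/10/15%, three repeats each).  Every stage derives its
random seed deterministically from the root seed, so a rerun with the same
configuration produces a byte-identical report directory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
import yaml

from .core import (
    CellTypePair,
    ExpressionDataset,
    LRDatabase,
    LRResult,
    PERTURBATION_KINDS,
    child_seed,
    enumerate_pairs,
    subset_pair,
)
from .io import read_expression, read_lr_pairs
from .methods import ScorerParams, available_methods, score_pairs
from .perturb import generate_batch, pair_biological_replicates
from .robustness import (
    build_report,
    evaluate_noise,
    evaluate_replicates,
    pairwise_method_agreement,
)
from .synthetic import SyntheticConfig, generate_replicates, lr_database

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "ConfigError"]

ALL_KINDS = ("biological_replicate",) + PERTURBATION_KINDS

DEFAULT_REPLICATE_PROPORTIONS = (0.95, 0.90, 0.85)
DEFAULT_NOISE_PROPORTIONS = (0.05, 0.10, 0.15)


class ConfigError(ValueError):
    """Invalid run configuration; message names the offending field."""


@dataclass
class RunConfig:
    """Validated configuration of one benchmark run."""

    outdir: str
    synthetic: Optional[SyntheticConfig] = None
    expression_paths: List[str] = dc_field(default_factory=list)
    annotation_paths: List[str] = dc_field(default_factory=list)
    lr_path: Optional[str] = None
    methods: List[str] = dc_field(
        default_factory=lambda: ["kumar_fraction", "natmi_style", "scsr_style"]
    )
    kinds: List[str] = dc_field(default_factory=lambda: list(ALL_KINDS))
    replicate_proportions: List[float] = dc_field(
        default_factory=lambda: list(DEFAULT_REPLICATE_PROPORTIONS)
    )
    noise_proportions: List[float] = dc_field(
        default_factory=lambda: list(DEFAULT_NOISE_PROPORTIONS)
    )
    cell_type_pairs: Optional[List[Tuple[str, str]]] = None
    n_repeats: int = 3
    n_permutations: int = 1000
    alpha: float = 0.05
    n_decoys: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        known = available_methods()
        for m in self.methods:
            if m not in known:
                raise ConfigError(f"methods: unknown method {m!r}; registered: {known}")
        for k in self.kinds:
            if k not in ALL_KINDS:
                raise ConfigError(f"kinds: unknown kind {k!r}; valid: {list(ALL_KINDS)}")
        for name, props in (
            ("replicate_proportions", self.replicate_proportions),
            ("noise_proportions", self.noise_proportions),
        ):
            for p in props:
                if not (0.0 < p <= 1.0):
                    raise ConfigError(f"{name}: proportion {p} outside (0, 1]")
        if self.n_repeats < 1:
            raise ConfigError("n_repeats: must be >= 1")
        if not (0.0 < self.alpha < 1.0):
            raise ConfigError("alpha: must lie in (0, 1)")
        if self.synthetic is None and not self.expression_paths:
            raise ConfigError("synthetic/expression_paths: provide one input source")
        if self.expression_paths and self.lr_path is None:
            raise ConfigError("lr_path: required when expression_paths are given")

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        syn = data.pop("synthetic", None)
        if syn is not None:
            if "planted_pairs" in syn:
                syn["planted_pairs"] = [tuple(p) for p in syn["planted_pairs"]]
            try:
                syn = SyntheticConfig(**syn)
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"synthetic: {exc}") from exc
        pairs = data.pop("cell_type_pairs", None)
        if pairs is not None:
            pairs = [tuple(p) for p in pairs]
        try:
            return cls(synthetic=syn, cell_type_pairs=pairs, **data)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


def _load_sources(config: RunConfig) -> Tuple[List[ExpressionDataset], LRDatabase]:
    if config.synthetic is not None:
        sources = generate_replicates(config.synthetic)
        lrdb = (
            read_lr_pairs(config.lr_path)
            if config.lr_path
            else lr_database(config.synthetic, n_decoys=config.n_decoys)
        )
        return sources, lrdb
    if config.annotation_paths and len(config.annotation_paths) != len(config.expression_paths):
        raise ConfigError("annotation_paths: must match expression_paths in length")
    sources = []
    for i, path in enumerate(config.expression_paths):
        ann = (
            config.annotation_paths[i]
            if config.annotation_paths
            else str(Path(path).with_suffix("")) + ".annotations.tsv"
        )
        sources.append(read_expression(path, ann))
    return sources, read_lr_pairs(config.lr_path)


def _cell_type_pairs(config: RunConfig, sources: Sequence[ExpressionDataset]) -> List[CellTypePair]:
    if config.cell_type_pairs is not None:
        return [CellTypePair(s, r) for s, r in config.cell_type_pairs]
    types = set()
    for ds in sources:
        types |= set(ds.cell_types)
    return enumerate_pairs(sorted(types))


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full benchmark and write the tabular report.

    Individual (method, dataset) failures are recorded in ``errors.tsv``
    and do not abort the run.  Returns the report directory.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sources, lrdb = _load_sources(config)
    ct_pairs = _cell_type_pairs(config, sources)
    logger.info(
        "%d source datasets x %d cell-type pairs -> %d pair datasets",
        len(sources), len(ct_pairs), len(sources) * len(ct_pairs),
    )

    errors: List[Tuple[str, str, str]] = []

    def params_for(method: str, dataset_id: str) -> ScorerParams:
        return ScorerParams(
            n_permutations=config.n_permutations,
            alpha=config.alpha,
            seed=child_seed(config.seed, "score", method, dataset_id),
        )

    def score(method: str, ds: ExpressionDataset, pair: CellTypePair) -> Optional[LRResult]:
        try:
            return score_pairs(method, ds, pair, lrdb, params_for(method, ds.dataset_id))
        except Exception as exc:  # recorded, not fatal
            errors.append((method, ds.dataset_id, str(exc)))
            return None

    # base (unperturbed) results per cell-type pair, source, method
    bases: Dict[Tuple[str, int], ExpressionDataset] = {}
    originals: Dict[Tuple[str, int, str], LRResult] = {}
    for pi, pair in enumerate(ct_pairs):
        for si, src in enumerate(sources):
            base = subset_pair(src, pair)
            bases[(str(pair), si)] = base
            for method in config.methods:
                res = score(method, base, pair)
                if res is not None:
                    originals[(str(pair), si, method)] = res

    records = []
    perturbed_counts: Dict[str, int] = {}
    for pi, pair in enumerate(ct_pairs):
        for method in config.methods:
            if "biological_replicate" in config.kinds and len(sources) >= 2:
                group = [
                    originals[(str(pair), si, method)]
                    for si in range(len(sources))
                    if (str(pair), si, method) in originals
                ]
                if len(group) >= 2:
                    records.extend(
                        evaluate_replicates(
                            {None: group},
                            kind="biological_replicate",
                            dataset_id=str(pair),
                        )
                    )

    for kind in config.kinds:
        if kind == "biological_replicate":
            continue
        proportions = (
            config.replicate_proportions
            if kind == "simulated_replicate"
            else config.noise_proportions
        )
        for pi, pair in enumerate(ct_pairs):
            for si in range(len(sources)):
                base = bases[(str(pair), si)]
                batch = generate_batch(
                    base, kind, proportions, config.n_repeats,
                    seed=child_seed(config.seed, "perturb"),
                )
                perturbed_counts[kind] = perturbed_counts.get(kind, 0) + len(batch)
                for method in config.methods:
                    scored = [
                        (spec, score(method, pds, pair)) for spec, pds in batch
                    ]
                    scored = [(spec, r) for spec, r in scored if r is not None]
                    if kind == "simulated_replicate":
                        grouped: Dict[Optional[float], List[LRResult]] = {}
                        for spec, r in scored:
                            grouped.setdefault(spec.proportion, []).append(r)
                        records.extend(
                            evaluate_replicates(grouped, kind=kind, dataset_id=base.dataset_id)
                        )
                    else:
                        orig = originals.get((str(pair), si, method))
                        if orig is not None:
                            records.extend(
                                evaluate_noise(orig, scored, dataset_id=base.dataset_id)
                            )
    for kind, count in sorted(perturbed_counts.items()):
        logger.info("%d perturbed datasets generated for kind %s", count, kind)

    agreement = None
    if len(config.methods) >= 2:
        mats = []
        for key in sorted(bases):
            group = [
                originals[(key[0], key[1], m)]
                for m in config.methods
                if (key[0], key[1], m) in originals
            ]
            if len(group) >= 2 and len({r.method for r in group}) == len(group):
                mats.append(pairwise_method_agreement(group)[0])
        if mats:
            agreement = sum(mats[1:], mats[0].copy()) / len(mats)

    build_report(records, outdir, agreement=agreement)
    if errors:
        err_df = pd.DataFrame(errors, columns=["method", "dataset_id", "error"])
        err_df.sort_values(["method", "dataset_id"], kind="mergesort").to_csv(
            outdir / "errors.tsv", sep="\t", index=False
        )
    logger.info("report written to %s (%d records, %d errors)", outdir, len(records), len(errors))
    return outdir
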