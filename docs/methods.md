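# Methods

## Scope and model

`cccbench` treats a cell-cell communication (CCC) method as a black box
that maps (expression matrix, sender type, receiver type, ligand-receptor
database) to a scored ranking of (ligand, receptor) pairs and a selected
set *S*. Robustness is defined as the stability of *S* under controlled
perturbation of the inputs, measured by the Jaccard coefficient
`J(A,B) = |A∩B| / |A∪B|`. Replicated data are compared replicate against
replicate at each sampling proportion; noise-type perturbations are
compared against the unperturbed result. Per-proportion means are averaged
with equal weight into an overall ("OV") value per perturbation kind —
each proportion block counts once regardless of how many records it holds
— and methods are ranked per kind by OV (rank 1 = highest, midrank ties),
with the overall rank the mean of per-kind ranks. The alternative of
pooling all records irrespective of proportion is deliberately not used,
so that OV is insensitive to unbalanced record counts between blocks.

**Empty-set convention.** `J` is 0/0-undefined when both sets are empty.
We define `J(∅,∅) = 1` — a method that selects nothing on both datasets is
perfectly consistent — and `J = 0` when exactly one set is empty.
Selection-style methods with strict thresholds genuinely produce empty
sets on small or noisy inputs, so the convention is load-bearing and is
logged when applied.

## Perturbation generators

All generators are deterministic given a seed, and every count of the
form `round(p·n)` uses round-half-away-from-zero, applied within each
stratum, so perturbed-entry counts are exactly reproducible.

- **Simulated replicates** — `round(p·n_c)` cells per type *c* drawn
  without replacement, order preserved; a proportion that leaves a type
  empty is an error rather than a silent degenerate dataset.
- **Gaussian expression noise** — for each gene, `round(p·n_cells)`
  entries are replaced by draws from `N(μ_g, σ_g²)` with the gene's own
  mean and population variance (denominator *n*) over all cells. Entry
  replacement (rather than a convex combination of a noise matrix with the
  data) keeps exactly a `1−p` fraction of the data untouched, making *p*
  comparable with the dropout and permutation proportions. Negative draws
  are clipped to 0 to preserve non-negativity; genes with zero variance
  are consequently invariant.
- **Dropout** — `round(p·n_genes·n_cells)` positions drawn uniformly over
  *all* matrix positions are set to 0. Counting already-zero positions is
  the literal reading of "set a fraction of values to 0"; restriction to
  currently expressed entries is available via `nonzero_only=True`.
- **Cell-type permutation** — a `round(p·n_cells)` subset of cells has its
  labels permuted *within the subset* (a true permutation). Type sizes are
  conserved, isolating annotation noise from composition change.
- **Gene-symbol permutation** — same construction on the gene axis; rows
  keep their values, symbols move, corrupting database lookup. This
  emulates noise in the ligand-receptor prior without touching expression.
- **Biological replicates** — not a generator: all C(n,2) pairings of
  independent source datasets, restricted to their common gene set.

Child seeds for batches are a 64-bit BLAKE2b hash of (root seed, kind,
proportion, replicate index, dataset id), so any single perturbed dataset
can be regenerated without replaying the batch.

## Scoring schemes

The nine scorers are simplifications that retain each published method's
scoring idea while removing pathway databases, network layers and other
external resources; names carry a `_style` suffix to make this explicit.
All means, fractions and trimeans are computed over the cells of a stated
type; "expressed" means strictly above `expressed_threshold` (default 0).

| scorer | score | selection rule |
|---|---|---|
| `cpdb_style` | `(μ_L^s + μ_R^r)/2` | permutation `p < α`, pre-filter: expressed fraction > 0.10 in both roles |
| `cellchat_style` | `TL·TR/(0.5 + TL·TR)`, `T` = Tukey trimean `(Q1+2Q2+Q3)/4` | permutation `p < α` |
| `skelly_product` | `μ_L^s · μ_R^r` | permutation `p < α` |
| `kumar_fraction` | `min(f_L^s, f_R^r)` | both expressed fractions > 0.20 |
| `natmi_style` | `(μ_L^s/(μ_L^s+μ_L^r)) · (μ_R^r/(μ_R^s+μ_R^r))` (0 on zero denominators) | both numerators > 0 |
| `scsr_style` | `√(μ_L^s μ_R^r)/(μ̄ + √(μ_L^s μ_R^r))`, `μ̄` = whole-matrix mean | score > 0.5 (strict; the boundary value is excluded) |
| `icellnet_style` | product of per-gene means max-scaled to [0,10] across the two types | score > 0; dataset-level sum reported in `extras` |
| `italk_style` | `μ_L^s · μ_R^r` | ligand in sender's top ⌈n/2⌉ genes by mean AND receptor in receiver's, ties by symbol |
| `zhou_de` | `min(log2FC_L, log2FC_R)` (pseudocount 1) | one-sided Wilcoxon rank-sum in both directions, BH-adjusted `p < α` AND both log2FC > 0.25 |

The permutation engine shuffles the pooled cell labels uniformly with type
sizes preserved and uses the add-one estimator
`p = (1 + #{null ≥ observed})/(1 + N)` (N defaults to 1000), the standard
bias correction that avoids `p = 0`. Ties against the observed statistic
count as extreme, so p-values are valid (conservative) for discrete
statistics. Selection thresholds (α = 0.05, fractions 0.10/0.20, log2FC
0.25) are package defaults, all overridable; threshold-based selection is
known to be data-dependent, which is precisely the fragility the
benchmark measures. Every scorer emits both a complete ranking and a
boolean selection: sets feed the Jaccard indicator, rankings feed the
top-k overlap analysis (`jaccard_top_k`, default intent k = 30).

External tools are integrated via `register_external_method`, which runs
an adapter on the module's file formats once per dataset and validates its
result table; network-based methods are reachable only through this route.

## Synthetic data

Counts are negative binomial with mean `λ` (default 1.0, a moderately
expressed gene in UMI data) and dispersion `θ` (default 2.0, variance
`λ + λ²/θ`), with independent Bernoulli dropout at rate `d` (default 0.1)
multiplied on top. A planted pair (L, R, sender, receiver, f) raises L's
mean to `λf` in sender cells and R's to `λf` in receiver cells (default
five pairs at f = 6 between the most abundant and the sparsest type). The
default composition — 260 astrocyte-like, 60 endothelial-like, 45
microglia-like, 220 oligodendrocyte-like cells — mimics a brain-tissue
mixture with strongly unequal type sizes at a scale where every scorer
runs in well under a second. Replicate datasets share all parameters and
differ only by a derived seed, emulating biological replicates whose
communication pattern should be conserved.

The generator does **not** model library-size variation between cells,
gene-gene correlation, batch covariates, mean-variance trends or
cell-type-specific expression programs beyond the planted pairs. Passing
tests therefore demonstrate correctness and internal consistency of the
benchmark machinery — exact perturbation accounting, calibrated
permutation nulls, recovery of an unambiguous planted signal — not that
any scorer is accurate on real tissue.

## Numerical choices and edge cases

- **Normalization.** Expression values are used as provided; an optional
  `normalize_log1p_cpm` helper (counts scaled per cell to 10⁴, log1p) is
  available for raw counts and is applied in the null-calibration test.
  On raw sparse counts the trimean takes few distinct values, the
  permutation null becomes atomic, and p-values — though valid — are too
  discrete for a continuous-uniformity check; normalization (library sizes
  differ per cell) restores an effectively continuous statistic. This is
  the recommended preprocessing for quantile-based scorers generally.
- **Determinism.** Quantiles use numpy's default linear interpolation;
  rankings break score ties by (ligand, receptor) lexicographic order;
  report files serialize floats with 6 significant digits and fixed column
  order, making whole report directories byte-comparable.
- **Degenerate inputs.** Empty ligand-receptor overlap yields a valid
  empty result; an all-constant gene is invariant under Gaussian noise; a
  group with fewer than two results is skipped with a warning rather than
  producing a vacuous Jaccard; summary cells with no records are missing,
  not zero, and excluded from OV.
- **Orientation.** On-disk matrices may be genes×cells or cells×genes;
  orientation is auto-detected by matching annotation ids against each
  axis, with an explicit override.

## Problem sizes

The test suite and the acceptance script run the design-bookkeeping checks
at 4 sources × 4 types × 40 genes, the calibration and recovery checks at
200 genes × 300–585 cells with 200–500 permutations, and the end-to-end
pipeline at 2 sources × 2 types × 60–120 genes with 25–100 permutations —
sizes at which every stage's behaviour (counts, calibration, recovery,
byte-level reproducibility) is already fully exercised. The defaults baked
into `RunConfig` (proportions 95/90/85 % and 5/10/15 %, 3 repeats, 1000
permutations) reflect the full study design and scale linearly.

## Known limitations

- Scorers are single-dataset and two-cell-type; multi-way communication,
  pathway enrichment and network propagation are out of scope (external
  adapters can supply them).
- The `zhou_de` ranking score (min log2FC) is a pragmatic choice; DE-based
  selection has no canonical single-number ranking.
- The Gaussian-noise model draws entries independently per gene, ignoring
  cell-level covariance.
- `icellnet_style` max-scales within the two compared types only, not
  across a larger panel of types as the original tool does.
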