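# Methods

## Network generator

Networks grow from a seed graph by preferential attachment. The seed is one
node per group connected in a directed cycle (for `k = 1`, a single isolated
node); the cycle guarantees every group is populated and every seed node has
positive degree. Each growth event is, with probability `p`, a **node event**
— a new node joins (group drawn uniformly over the `k` groups) and becomes
the target of one new edge — and otherwise an **edge event** between existing
nodes. Targets are drawn with probability proportional to `in-degree + δin`,
sources proportional to `out-degree + δout`. Because every event adds exactly
one edge and a node is added once per `1/p` events on average, the mean
number of regulators per gene approaches `1/p`. Larger `δ` values flatten
the corresponding degree distribution (lower coefficient of variation);
small values concentrate attachment on hubs.

Group affinity is two-stage: the source's group is drawn first, with weight
`w` on the target's own group and 1 on each other group, then the source node
is drawn by preferential attachment restricted to that group. The expected
within-group edge fraction is therefore exactly `w/(w + k − 1)`, independent
of degree imbalance across groups.

Self-loops and duplicate edges are excluded *inside* the within-group node
choice (illegal sources get weight zero) rather than by rejecting and
redrawing the whole event. Whole-event rejection would discard within-group
candidates more often than between-group ones — the within-group subgraph is
denser, so duplicates concentrate there — biasing the within-group fraction
measurably below `w/(w + k − 1)` at moderate `n`; masking only the node
choice preserves the group marginal. If the drawn group has no legal source
the event is redrawn, up to `100·n` attempts (then `GraphSaturatedError`).
One special case is handled exactly: during early growth at small `p` the
existing graph can be *complete* (≈15 edge events arrive per node event
while only a handful of nodes exist), in which case no legal edge exists and
the edge event is skipped; this matters only while the graph has tens of
nodes and leaves the asymptotic mean degree unchanged.

The full study grid is the factorial
`p ∈ {1/2, 1/4, 1/8, 1/16} × k ∈ {1, 5, 10, 50, 100} × w ∈ {1, 9, 40, 90,
400, 900} × δin ∈ {10, 30, 100, 300} × δout ∈ {1, 3, 10, 30}` (1,920
parameter sets), exposed as `grid_preset()`. `stratified_grid_sample(m)`
cycles independently through the sorted levels of each parameter, so any
`m ≥ 6` covers every level of every parameter at least once; it is the
default network sample for the scaled-down replications.

## Expression model

Expression follows the Euler–Maruyama discretization

    x' = x + Δt·(σ(α + βᵀx) − ℓ·x) + N(0, Δt·s²·diag(x)),

with σ the logistic sigmoid, `Δt = 0.01`, and global noise magnitude
`s = 1e-4` by default (noise variance scales with expression, mimicking
intrinsic synthesis/degradation noise). Expression is clipped to be
non-negative after each full update (drift plus noise); with the
multiplicative noise floor at zero and strictly positive drift `σ(·) > 0`,
zero is re-inflating rather than absorbing.

Parameters are sampled as: `σ(αi) ~ Beta(2, 8)` (low but nonzero innate
transcription), `ℓi ~ Beta(8, 2)` hard-clipped from below at `e^{−αi}`, and
per-edge weights `βji = (2pj − 1)(1 + |N(0, 1)|)` with a single activator/
repressor sign per regulator (`pj ~ Bernoulli(0.8)`) and minimum magnitude 1.

The decay clip deserves a note because it effectively replaces the Beta
draw for most genes (for `α < 0`, `e^{−α} > 1 ≥ Beta(8, 2)`). It bounds the
isolated-gene steady state by `σ(α)e^{α} < 1` and keeps typical expression
well below one. The consequence for dynamics is central: regulator inputs
`Σ βji·xj` stay within the responsive range of the sigmoid rather than its
saturated tails, so knockouts of direct regulators produce detectable
changes in most targets. We verified the alternative reading — clipping at
`e^{+α}`, which leaves `ℓ ≈ Beta(8, 2)` and steady states of order one —
and found it drives inputs deep into sigmoid saturation, suppressing
direct-effect rates on dense networks by several-fold; the implemented clip
reproduces the expected direct-effect calibration (see the acceptance
statistics) while the alternative does not. Under the implemented clip the
Jacobian diagonal `−ℓ` is strongly negative, so equilibria are almost always
linearly stable; mediated (multi-hop) effects attenuate by roughly
`β·x·(1 − σ)` ≈ 0.1 per hop and are correspondingly rarer than direct ones.

## Steady states and stability

Baseline simulation starts at `x = 0` and runs `b = 5,000` burn-in
iterations; running means accumulate afterwards and are compared every
`h = 1,000` iterations. The system converges when the largest |log2 ratio|
of running means between consecutive checks — over genes whose running mean
exceeds `s` — drops below `1e-3`, with a cap of `t_max = 20,000` total
iterations (non-convergence is a warning; the final running mean serves as
an approximate equilibrium). The earliest possible convergence is therefore
at iteration `b + 2h`. Stability is assessed in the deterministic limit via
the eigenvalues of the Jacobian `J[i,j] = βji·σ'(ui) − 1{i=j}·ℓi` at the
running-mean state: stable iff every real part is negative. The
eigendecomposition is dense and computed once per network.

## Knockout screens

A knockout zeroes a gene's outgoing β row (equivalently, for the rest of the
network, to holding the gene at zero; the β-row form is canonical here since
holding expression fixed would interact with the multiplicative noise). Each
knockout re-equilibrates from the baseline steady state under the full
baseline protocol, and effects are `log2FC = log2(x̄_ko) − log2(x̄_base)`
(machine-tiny floor before the log; the diagonal is NaN and excluded from
every summary). Knockouts are batched through one shared step loop as
independent systems — a correction term subtracts the knocked-out row's
contribution per system — which is numerically identical to one-at-a-time
simulation at `s = 0` (asserted in tests). Batch state can be float32
(running means always accumulate in float64); the induced |log2FC| error is
≈1e-4, negligible at the 0.01 analysis threshold. Converged systems are
frozen and dropped from the batch at each check.

Hub statistics use the thresholds |log2FC| > 0.1 in ≥ 100 genes, with
lowly-expressed genes (baseline `x̄ ≤ s`) removed from both axes.

## Cells, coexpression, programs

"Cells" are consecutive SDE steps at equilibrium — one cell per forward
step, deliberately autocorrelated (the sampler emulates stationary
fluctuation, not independent draws). Mixed experiments assign a fraction
(default 8.1%) of cells to baseline and the rest uniformly at random to
single-gene knockouts; each knockout's cells are consecutive steps of one
chain after re-equilibration under that knockout. Coexpression is the
Pearson correlation across cells with population (divide-by-m) moments —
immaterial at the default 10⁴ cells — and zero-variance genes fixed at
correlation 0.

Programs: genes are z-normalized across cells (constant genes zeroed),
truncated SVD retains the top `k = 200` components (seeded randomized
solver, columns re-orthonormalized by QR with zero-variance rows pinned at
zero), and each component's program is the 200 genes with the largest
squared loadings, ties broken toward the lower gene id. Program overlap
between two experiments reports, per reference program, the maximum
intersection size with any program of the other set. Canonical correlations
between two loading spaces are the singular values of `VᵀV'` — CCA for
orthonormal inputs — clipped to [0, 1].

## Comparison against empirical screens

Simulated screens are reduced to per-gene outgoing/incoming effect-degree
fractions by thresholding |log2FC| at the top `d = 3.16%` of off-diagonal
pairs among non-lowly-expressed genes (matching the empirical discovery
rate at FDR-corrected p < 0.05); the threshold is the `(1 − d)` quantile and
only strictly larger values are called, so ties at the boundary are not
significant and the realized rate can fall one pair short. Fractions are
normalized by the number of analyzed genes. Candidate networks are ranked
against an empirical table by two-sample Kolmogorov–Smirnov tests
(`scipy.stats.ks_2samp`) on both distributions, combined either by summed
p-value ranks or by the smallest joint rank containing `k` networks; both
modes are implemented, with ties broken by summed rank then index.

The hub-fraction regression is OLS of `logit(fraction)` on
`1 + 1/p + k' + w + δin + δout` with covariates on their natural scales,
`k = 1` recoded to `k' = n` (one group and one-group-per-gene are the same
dissolution of structure), and boundary fractions nudged to `1/(2n)` and
`1 − 1/(2n)` before the logit. The p-value reweighting for master-regulator
prioritization is `p'ij = pij/ni` with `ni` the count of genome-wide
significant outgoing effects of perturbation i; rows with `ni = 0` are
excluded, and truth-set evaluation honors directed or undirected pair lists.

## Problem sizes for the scaled-down replications

The full study design (1,920 networks × n = 2,000 genes × full screens) is
hours of single-CPU compute. The packaged replications instead use, as the
package's own study conditions:

- **Acceptance script**: 10 stratified grid parameter sets at n = 2,000 with
  150 randomly sampled knockouts per network. Pair-level fractions are
  unbiased under knockout subsampling; only their variance grows.
- **Test suite**: 4 parameter sets × 100 knockouts for the distance
  statistics; a 16-run resolution-V fractional factorial at n = 200 (hub
  thresholds scaled to the same 5%-of-genes geometry) for the regression
  trends; 3 networks at n = 300 for the edge-recovery comparison; n = 300,
  5,000 cells, 50 components for the program analyses.

## Known limitations

- The synthetic screens model no measurement process (no mRNA counting,
  UMI sampling, or library-size effects); passing tests show properties of
  the dynamical model, not of any assay.
- With the implemented decay clip, equilibria are essentially always
  linearly stable and mediated effects attenuate quickly; network-average
  non-edge supra-threshold rates are accordingly low, and the
  stability-by-parameter trend is degenerate (all stable) at tested scales.
- At the reduced test scale (n = 200–300), two full-grid regression signs
  (modularity `w`, out-degree uniformity `δout`) flip relative to the
  full-scale geometry: confinement of cascades inside groups only caps hub
  counts when group size falls below the hub threshold, which depends on
  `n/k` vs the hub-count cutoff. Reduced-scale assertions therefore cover
  the dominant density term only.
- Program reproducibility between perturbation replicates exceeds
  baseline-vs-perturbed overlap only while knockout signal dominates noise;
  at the reduced scale (5,000 cells, ~15 cells per knockout, n = 300) this
  regime ends near `s ≈ 0.1` rather than `s = 0.3`.
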