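# Methods

## The analysis model

The pipeline treats each participant's reading network during one task
run as an undirected graph over a fixed node set (a cortical
parcellation restricted to reading-related regions; 43 nodes for the
core network, 154 for the outside-network control). Functional
connectivity is the zero-lag Pearson correlation between node time
series — no lagged cross-correlation, partial correlation, or directed
estimation, because the underlying task design (fast event-related,
jittered onsets) makes lag-dependent quantities hard to interpret.

Two thresholding rules turn the weighted correlation matrix into a
binary graph:

* **Significance** (`significance_threshold`): edge iff the two-sided
  exact t test of r rejects at α (default .05, uncorrected). The test is
  t = r √((n−2)/(1−r²)) on n−2 df; |r| = 1 is treated as p = 0.
  Negative significant correlations produce edges by default, because
  the rule is a two-sided significance rule, not a sign rule; a
  `positive_only` flag restricts to positive coupling for sensitivity
  analysis. At ~200 time points the implied boundary is |r| ≈ .14, so
  these networks are dense (~70–80% of pairs).
* **Minimum connected component** (`mcc_threshold`): edges are inserted
  in descending weight order until the graph first spans all nodes in a
  single component; all edges strictly above the stopping weight plus
  all edges tied with it are kept. Including ties makes the output
  independent of sort order, at the cost of occasionally a few extra
  edges; an all-tied matrix degenerates to the complete graph (logged).
  Ranking is by signed correlation (most positive = strongest), the
  conventional reading of edge strength in functional connectivity;
  `rank="abs"` is available. The two schemes are intentionally
  different: significance is two-sided, MCC is positive-first.

### Network measures

All three measures operate on binary undirected graphs with the node set
fixed by the parcellation — isolated nodes stay in the graph (they
depress efficiency and contribute nothing to transitivity).

* **Modularity**: maximised Newman quality at resolution γ = 1. The
  optimiser is the Leiden multi-level greedy search (leidenalg,
  RBConfiguration quality, which is 2m·Q at γ), run `n_restarts` times
  (default 10) with sub-seeds spawned from an explicit seed; the best
  partition is kept and Q is recomputed from it with the Newman formula,
  so the returned value and partition agree exactly. Community detection
  is a heuristic: tests verify it attains the exhaustive-search optimum
  on ≥95% of uniform random 8-node graphs and never exceeds it.
* **Transitivity**: Σ 2tᵢ / Σ kᵢ(kᵢ−1) via the trace of A³; 0 by
  convention when no node has degree ≥ 2 (logged).
* **Global efficiency**: mean inverse breadth-first path length over
  ordered pairs; disconnected pairs contribute 0 — required for
  significance-thresholded graphs, which may be disconnected.

### Aggregation

Run-level metrics are averaged over the (default two) runs within each
subject × modality × scheme, then winsorized at mean ± 2 SD within each
metric × modality × scheme column across subjects — i.e. each column
that enters the regression, which is the most defensible reading of
"per measure". Boundary statistics use the sample (n−1) SD and are
computed once from the pre-replacement values, so the operation is a
single pass, idempotent whenever nothing was replaced. Pooling
modalities within a metric is available via `group_cols`.

### Inference

The hierarchical regression is ordinary least squares throughout:
step 1 regresses PDE on age (months), task accuracy, and response
latency (ms); step 2 adds the nine connectivity predictors. The
increment is tested by F = ((R²₂−R²₁)/q)/((1−R²₂)/df₂), numerically
identical to the residual-sum-of-squares formulation (asserted in
tests against statsmodels' nested comparison). The coefficient table
reports raw B, SE, standardized β (z-scored fit), and a signed
association column: the partial correlation of each predictor with the
outcome given all other terms, derived as t/√(t²+df). It is reported
under that neutral name, with its square alongside, rather than as a
classical effect-size label, because signed values bounded by 1 are what
a partial correlation is.

LMG relative importance is computed exactly: the R² of every predictor
subset is evaluated from the covariance matrix (2^p subsets, capped at
p = 20; subsets made singular by duplicated predictors fall back to the
minimum-norm solution, whose fit is still unique), and each predictor's
share is its weighted average sequential contribution. Shares are
nonnegative and sum to the full-model R² (tested to 1e-10); a
`normalized` flag rescales them to sum to 1. The decomposition runs on
the full 12-predictor model; contrasts are reported only among the nine
connectivity predictors, in two layouts (same metric across modalities,
same modality across metrics). Bootstrap CIs come from nonparametric
case resampling of subjects (B = 1000, percentile 95% intervals, fixed
seed); a resample whose predictor block loses rank relative to the
design is redrawn and counted. At n = 24 with 12 predictors a resample
needs ≥ 13 distinct subjects for full rank, so occasional redraws are
expected; cohorts much smaller than 24 cannot support the 12-predictor
bootstrap at all.

## The synthetic cohort generator

`generate_cohort` emulates the study design: `n_subjects` = 24
participants, three presentation modalities (VV, AV, AA), two runs per
modality of `n_timepoints` = 202 samples (≈ 6:45 at TR = 2 s), 43-node
networks (the 154-node outside-network variant is just a config
change). For each subject × modality a block correlation matrix is
planted: `n_modules` = 4 communities (mirroring the four anatomical
subdivisions of the reading network), pairwise correlation `within_r`
inside modules and `between_r` across them, both drawn per
subject × modality from uniform ranges so cohort members genuinely
differ. Per-pair Gaussian jitter (`edge_jitter_sd` = 0.08) is added
around the block levels: real connectivity is not block-constant, and
without heterogeneity the noiseless thresholded graphs would be
degenerate (complete, or exact module cliques) and the true metrics
would be step functions. Any non-PSD matrix (from extreme levels or
jitter) is repaired by the smallest shrinkage toward the identity that
restores PSD, and the shrinkage is recorded in the ground truth.

Time series are i.i.d. Gaussian across time from the planted matrix —
the analysis consumes only zero-lag correlations, so temporal structure
is irrelevant to its math; an AR(1) knob (`ar1_phi`) that preserves the
zero-lag covariance exists for robustness checks only. Each
(subject, modality, run) draws from a sub-seed hashed from the master
seed and the index tuple, so generation is deterministic and stable
under reordering.

The outcome is linear in *true* metrics: the planted (noiseless)
correlation matrix is binarized with the same rule the pipeline applies
(default: the significance threshold at the configured run length) and
measured; PDE = intercept + Σ β·(true metric) + N(0, σ). Defaults:
intercept 90.5 and noise σ = 5 (the scale of a standardized reading
score), with a single planted link of +80 on AV modularity, sized so the
planted model explains roughly half the outcome variance given the
true-metric spread (~0.06) of the default cohort. Nuisance columns are
uniform over ranges typical of such a cohort (age 94–164 months,
accuracy .51–.85, latency 900–1863 ms) and are recorded in the ground
truth; they are independent of the outcome by construction.

### Calibration of the defaults

`within_r` ~ U(.30, .55) and `between_r` ~ U(.12, .38) were chosen once
so the two thresholding schemes land in the regimes the method expects:
dense significance networks (mean Q ≈ .05–.08, efficiency ≈ .87–.92)
and sparse MCC networks (efficiency ≈ .44–.50). One known departure
from real cohorts: MCC modularity runs high (~.5) because planted
communities are idealized blocks — real networks are less cleanly
modular. Passing tests on this generator therefore demonstrate the
pipeline's correctness and calibration, not that real data would yield
any particular effect size.

A structural property worth knowing: with both levels free, a subject's
significance-scheme modularity is dominated by overall density, i.e. by
−between_r alone (rank correlation ≈ .97 at the true level), while the
within-minus-between *gap* correlates at only ≈ .75. The gap → modularity
relationship is therefore tested with the within-level held at its
central value (0.45), where the planted gap is the single varying factor
and the measured rank correlation is ≈ .94. Relatedly, the three metrics
of the same dense graph are nearly collinear across subjects
(|r| ≈ .97–1.0), so partial regression coefficients at n = 24 are
unstable in sign even when marginal correlations are perfectly
consistent — the recovery tests quantify exactly this.

## Problem sizes used by the test suite

Simulation-backed checks are sized to be decisive yet quick, and every
random element is explicitly seeded, so results are reproducible runs,
not flaky samples: 200 random ≤8-node graphs against brute-force metric
oracles and 100 against exhaustive modularity search; 500 null
simulations for nested-F calibration (KS test at α = .01); 100 cohorts
at full design scale (24 × 43 × 202) for coefficient-sign recovery and
20 for the gap→modularity rank correlation; 12 full-scale null cohorts
for the no-link control (the published control used a 154-node set; the
node count is config-only and exercised separately). Pipeline-level
tests use 24-subject cohorts with smaller graphs (12–14 nodes, T = 60).

## Known limitations

* The generator varies connectivity through two levels plus pairwise
  jitter; it does not emulate hemodynamics, scanner noise, motion, or
  spatially structured artifacts, and its metric intercorrelations are
  stronger than real cohorts would show.
* Modularity is a heuristic optimum; on 43-node graphs restarts make it
  stable in practice (and tests bound it by the exhaustive optimum on
  small graphs), but tie-breaking among near-optimal partitions is
  seed-dependent.
* LMG is exact-enumeration only (p ≤ 20); no sampling approximation is
  provided, and none is needed for the 12-predictor model.
* The published-value reproduction requires the original deposited
  cohort; synthetic cohorts reproduce regimes, not the published
  coefficients.
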