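# Methods

This note records the models implemented by cerebstat, the defaults that
matter, the numerical choices made where the design was genuinely open, and
what the synthetic-data generators do and do not emulate.

## Sampling power for rare cell types

The count of nuclei of one rare type among *n* profiled is modelled as
X ~ Binomial(*n*, *p*), with prevalence *p* per type.  The probability of
adequately sampling a type is the exact upper tail P(X ≥ k), where *k* is
the minimum number of nuclei considered sufficient to resolve the type as a
cluster; for *m* equally rare types, independence is assumed and the overall
probability is the per-type tail raised to the *m*-th power.  Independence
is a mild approximation — the types compete for the same *n* draws — but
with *p·m* ≪ 1 the dependence is negligible.  Defaults (k = 70, p = 0.0015,
m = 10) describe a design in which ten very rare types at 0.15% prevalence
must each be seen 70 times.  A Poisson tail is available (`approx=
"poisson"`) for very small *p*; the exact binomial is the default and is
cross-checked in the tests against direct log-pmf summation to 1e-10.
`min_nuclei_for_power` inverts the monotone tail by bisection, so the
returned *n\** satisfies the target and *n\**−1 does not.

## Spatially variable genes (logVMR)

Expression is depth-normalized per cell (each cell scaled to a fixed total,
default 1e4), then summarised per region as the **mean** of normalized
expression over the region's cells (pseudobulk mean).  The aggregation is
configurable (`aggregate="sum"`), as is working from externally produced
region summaries; mean-of-normalized is the default because it is the
simplest estimator that is invariant to region size.  For each gene the
index of dispersion of region summaries uses the sample (n−1) variance and
the natural log:

    logVMR = ln( Var_j(x_j) / Mean_j(x_j) ).

Genes with zero cross-region mean or zero variance have no defined logVMR
and are excluded (counted in the log).

**Null model.**  Most genes are not regionally patterned, so the bulk of
the logVMR distribution is treated as the null.  A Gaussian is centred on
the distribution's mode and its spread estimated from the left half only:

* *Mode.*  A Gaussian-kernel KDE with Silverman's rule-of-thumb bandwidth
  is the base estimate.  The raw argmax of a density evaluated at the
  density-optimal bandwidth is a noisy mode estimator — over the flat top
  of a near-symmetric distribution it wanders with a standard deviation of
  roughly 0.11 at n = 5,000 — so the mode is located on a KDE oversmoothed
  2× (oversmoothing leaves the mode of a symmetric bulk unbiased while
  shrinking its variance) and refined as the density-weighted centroid of
  the contiguous grid region within 95% of the peak, on a 512-point grid
  spanning the data range ±3 bandwidths.  This estimator has standard
  deviation ≈ 0.04 at n = 5,000 with negligible bias under 5% right-tail
  contamination.  If several local maxima lie within 5% of the top density
  a warning is emitted and the highest is used.
* *Sigma.*  The values ≤ mode are pooled with their mirror images across
  the mode and the standard deviation about the mode of that reflected
  sample is used.  Because truly spatial genes inflate only the right tail,
  this half-sample estimate tracks the null spread where the full-sample SD
  would be dragged upward.

Per-gene p-values are the Gaussian upper tail at each logVMR; q-values are
Benjamini–Hochberg; the default significance level is q < 0.01, with
stricter presets 0.001 and 0.002 for analyses within highly abundant cell
types where more genes are tested at higher power.  A floor of 50 defined
logVMRs (configurable) guards against fitting a null to a handful of genes.

## Regional composition and lobule enrichment

All quantities are computed within a cluster's coarse ("outer") cell type:
`N_j` is the number of nuclei of that outer type in lobule *j*.  Expected
counts are `E_ij = N_i · N_j / Σ_j N_j`; the test statistic is Pearson's
chi-squared over lobules with `E_ij > 0` (zero-expectation lobules are
dropped and the degrees of freedom reduced; with all 16 lobules populated,
df = 15).  No continuity correction is applied.  BH adjustment runs across
all clusters tested in one call — the scope is a choice; restricting to one
outer type at a time simply means calling the test per subtable.
Enrichment `LE_ij` is 0 where the cluster has no cells in a populated
lobule and undefined where the outer type itself has none; the
`N_j`-weighted mean of each cluster's LE vector is identically 1.

**Replicate consistency.**  Within each (outer type, lobule) cell the most
represented replicate's nuclei are assigned to set 1 and the second most
represented to set 2 (ties broken by replicate label; lobules with a single
replicate contribute to set 1 only).  LE is recomputed per set and the
Pearson correlation of the two LE vectors taken per cluster over the
lobules populated in both sets; clusters present in only one set get an
undefined r and can never be labeled.  This two-set design tolerates
uneven replicate coverage across regions at the cost of discarding third
and later replicates.

**Downsampling.**  A hugely abundant outer type (granule cells in the
motivating data, downsampled there to 60,000) can be subsampled uniformly
at random, with an explicit seed, *before* both the composition test and
the replicate analysis, so one class does not dominate `N_j`.

**Labeling.**  A cluster is called spatially significant when q < 0.001,
max_j LE_ij > 2 and replicate r > 0.85 — all strict inequalities.

## Continuity of expression between two populations

Two populations are pooled, downsampled to at most 5,000 nuclei (uniform,
seeded) to bound the fitting cost, and ordered along a trajectory: the
supplied pseudotime's ranks when available (the fidelity path; ties broken
by cell order), otherwise the projection of z-scored expression of the 500
most variable genes onto the first principal axis, a deliberately simple
stand-in for graph-based trajectory inference.  The principal-axis sign is
arbitrary, so orientation is fixed (first supplied cell ranks low) and
reported; m is invariant to reversal.

Expression is z-scored per gene across the pooled cells and clipped to
±10.  Candidate genes are the Wilcoxon rank-sum differentially expressed
genes between the two populations (BH q < 0.05) — a standard pre-filter,
isolated in one function so it can be swapped — and among them the top 200
by absolute Spearman correlation with pseudotime rank (ties by gene id).

Each gene is fit by nonlinear least squares with

    y(x) = a + (d − a) / (1 + exp(−b (x − x0))),   x = rank/N ∈ (0, 1],

initialized at a = min(y), d = max(y), b = 4, x0 = 0.5, with a restart grid
(x0 ∈ {0.25, 0.5, 0.75} × b ∈ {1, 10, 100}) on failure.  The asymptotes are
unbounded — for shallow curves they lie far outside the observed range —
while b ∈ [1e-3, 4N] (so a one-cell transition is representable but
log10(m) stays finite; hitting the cap is recorded per gene) and
x0 ∈ [0, 1].  Falling curves are normalized by swapping asymptotes so
d ≥ a, b ≥ 0.

The analytic maximum slope of the curve is b(d−a)/4 at x = x0.  Dividing by
the dynamic range (d−a) and fitting on the per-unit normalized rank scale
removes the dependence on expression magnitude and on the number of cells,
giving the continuity metric

    m = b / 4,

the minimal normalization that makes m comparable across genes and across
pairs of different sizes.  Raw b, a and d are always emitted so alternative
normalizations can be recomputed.  Pairs are compared through the empirical
CDF of log10(m) over their fitted genes; a continuum shifts the ECDF left
(small m), a discrete switch shifts it right.

## Synthetic data

* `simulate_atlas` draws, per cluster, lobule labels from the configured
  composition, replicate labels from shared proportions, and counts from a
  gamma-Poisson model (variance μ + φμ², dispersion φ = 0.2 by default)
  with a disjoint block of marker genes per cluster elevated
  `marker_effect`-fold over the base rate.  Replicates are drawn
  independently of lobule, so replicate sets share each cluster's true
  composition — the regime in which replicate consistency should be high.
* `simulate_trajectory_pair` draws latent times t ~ Uniform(0,1) (or an
  evenly spaced grid, `time_sampling="grid"`, under which rank/N equals t
  exactly — the right mode for exact parameter-recovery checks, since with
  random uniform times the empirical-quantile gap between rank/N and t
  perturbs recovered steepness by order n^(−1/2)) and gene means
  a + d/(1+exp(−b(t−x0))), with Gaussian noise on the mean or
  negative-binomial counts around it.  The Gaussian mode separates fit
  correctness from noise-model effects.
* `simulate_spatial_expression` emits region-level summaries directly:
  null genes x_gj ~ Poisson(μ_g) with μ_g lognormal across genes, so the
  index of dispersion sits near 1 for every gene regardless of its mean and
  the logVMR distribution is unimodal and near-symmetric — exactly the bulk
  the null estimator assumes; spatial genes multiply μ_g by
  exp(N(0, effect_sd)) per region before the draw.

What the generators do **not** emulate: ambient RNA, doublets, batch or sex
effects, realistic gene-gene correlation, library-size variation across
cells, or any real cerebellar expression landscape.  Passing tests
therefore demonstrate the statistics behave as designed under their own
assumptions — calibrated nulls, recoverable parameters, correct labels when
the generative truth matches the model — not that the pipeline is robust to
every artefact of real tissue.

## Problem sizes and numerical conventions

Test and validation runs use desk-scale sizes chosen to make the Monte
Carlo error comfortably smaller than the tolerance being checked: 2,000
null clusters for composition calibration, 200 replicates of 500 genes for
spatial-null calibration, 50 seeds at n = 2,000 cells for noisy continuity
recovery, 100 atlas replicates for end-to-end labeling, pairs of 1,600
cells and 220 genes for the discrete-vs-continuous comparison.  Natural log
is used wherever a log has no stated base (logVMR); log10 for reporting m;
log2 for maximum lobule enrichment.  Sample (n−1) variance throughout.
All stochastic steps take explicit integer seeds; a pipeline rerun with the
same config and seed reproduces its output files byte for byte.

## Known limitations

* The composition test treats `N_j` as fixed although the tested cluster
  contributes to it; for clusters that are a large share of their outer
  type the test is conservative (a cluster identical to its whole outer
  type is degenerate and flagged in the log).
* The internal principal-axis ordering assumes a single dominant trajectory
  and no branching; external pseudotime should be supplied where a real
  trajectory method has been run.
* The logistic steepness b is weakly identified for very shallow gradients
  (the curve is near-linear on [0,1]); m remains well-defined but its
  variance grows as b → 0.
* BH adjustment assumes p-values that are valid marginally; the Gaussian
  logVMR null is an empirical approximation whose calibration is itself
  checked by simulation, not guaranteed analytically.
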