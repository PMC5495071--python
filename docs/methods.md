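# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the limits of what the package's tests
demonstrate.

## Differential count model

Counts for gene (or region) g in sample s are negative binomial with mean
μ_gs = q_g·f_s and variance μ + α·μ², where f_s is a per-sample size
factor and α the dispersion.  Size factors are DESeq-style
median-of-ratios: only genes positive in every sample contribute, and the
factors are rescaled to geometric mean 1, which also makes the test
exactly invariant to a global rescaling of the claimed library sizes.
Within `nb_two_group_test`, supplied factors are re-normalized to
geometric mean 1 for the same reason.

The two-group test is a likelihood-ratio test of a common mean q against
per-group means (q₁, q₂), maximized at fixed α by a damped fixed-point
iteration on the score equation (vectorized across genes; relative
tolerance 1e-12, ≤ 200 iterations; zero-total genes get q = 0).  The
log₂ fold change is log₂((m₁ + ½)/(m₂ + ½)) on normalized group means, so
swapping numerator and denominator negates it exactly; the pseudo-mean ½
keeps it finite for groups with zero counts.

**Dispersion and calibration.**  A per-gene method-of-moments estimate
α̂ = (s² − m̄)/m̄² (within-group pooled variance s², grand mean m̄, floored
at 1e-8) carries only (n₁−1)+(n₂−1) degrees of freedom at this design's
replicate numbers (2–3 per cell).  Plugging such an estimate into a
χ²(1) reference roughly doubles the type-I error (measured 0.118 at
nominal 0.05 with n = 3 vs 3, α = 0.1, μ = 100).  The package therefore
offers two calibrated modes:

* **pooled** (default): the raw, unfloored per-gene moment estimates are
  averaged across all genes of the tested matrix into one common α, which
  is then effectively known (thousands of genes), and the LRT is referred
  to χ²(1).  Measured null rejection at nominal 0.05: 0.054 (n = 3 vs 3)
  and 0.051 (n = 2 vs 2); null p-values uniform (KS D < 0.02).
* **genewise**: each gene keeps its own floored estimate and the LRT is
  referred to F(1, d) with d the residual df — the quasi-likelihood
  device — restoring calibration (measured 0.049) at a substantial power
  cost when d ≤ 3.

The pooled mode assumes genes share a dispersion scale, which is exactly
true for the generator and only approximately true for real RNA-seq;
empirical-Bayes shrinkage toward a mean–dispersion trend, the standard
remedy on real data, is deliberately out of scope.  Genes with zero
counts across the contrast samples are excluded before testing and
reported as untested (their fold change is undefined).
Benjamini–Hochberg adjustment (scipy's step-up implementation) is applied
across tested genes; defaults are q < 0.05 for gene contrasts (a
conventional cutoff, configurable) and q < 0.01 for region contrasts.

## Interval operations

Coordinates are strictly 0-based half-open everywhere (BED/bedGraph
semantics); no 1-based dialect detection, no "chr" aliasing.  A peak's
reference point is its summit when recorded, else the integer-floor
midpoint — one rule covering both summit-bearing TF peaks and
edge-defined histone regions.  Assignment takes, per peak, the gene with
minimal |reference − TSS| on the same chromosome, accepted iff the
distance is ≤ 10 kb (default), with exact-distance ties broken by the
lexicographically smaller gene id so results are order-independent.
Distances use the TSS only, not gene bodies.

Peak-set comparison declares a region of A shared iff its half-open
overlap with some region of B is ≥ min_overlap bp (default 1); the
shared/unique counts partition each set.

Profile matrices bin the window [−flank, +flank) around each summit
(defaults flank = 1000 bp, bin_width = 50 bp; bin_width must divide the
window).  Bin values are exact per-base coverage sums — computed from a
prefix integral of the piecewise-constant track, so no resolution is
lost — divided by (bin_width/1000)·(library_size/10⁶).  Track values are
treated as per-base read depth; any read-length factor is absorbed into
the recorded normalization constant, which is what makes profiles
comparable across conditions.  Bins truncated at a chromosome start are
zero-filled, flagged, and excluded from per-bin means.

## Concordance statistics

Quadrant classification uses the sign pair of (x = log₂FC GF/CV within
WT, y = log₂FC WT/Mut within CV) for genes significant on both axes;
(+,+) is *suppressed_activated*.  Since the pipeline computes the
WTCV/WTGF contrast, x is obtained by exact sign flip.  A significant axis
with exactly zero fold change is rejected as contradictory input.  The
headline fraction is suppressed_activated over all microbiota-suppressed
coregulated genes.

The KS statistic is the maximum absolute ECDF difference over all pooled
points.  Its p-value uses the asymptotic Kolmogorov distribution at
√(n₁n₂/(n₁+n₂))·D; an exact mode (scipy) is available and intended for
n₁·n₂ ≤ 10⁴.  Because the statistic is discrete, null p-values are
conservative (stochastically above uniform); the tests assert the
one-sided property — the p ECDF never exceeds the uniform line — rather
than two-sided uniformity, which no KS implementation can deliver at
these sample sizes.  The enhancer/expression concordance compares CV/GF
fold changes of genes assigned to CV-enriched regions against those
assigned to GF-enriched regions (genes near both contribute to both
samples, with the overlap count reported); an alternative mode compares
each group against all tested genes instead.

## Orthology and enrichment

The one-to-one filter removes every pair whose gene occurs in more than
one pair (so a paralog conflict removes the true pair as well — the
intended behavior of a strict filter) and is idempotent; chaining two
filtered maps through the shared middle species yields
one-to-one-to-one triples.  Enrichment is the upper-tail hypergeometric
probability P(X ≥ k) with k the query/annotated overlap, computed inside
an explicit universe.  The universe is defined as genes that survive
ortholog chaining *and* were tested in the expression data — published
work rarely states this choice, so it is recorded in the report
metadata.  BH adjustment is applied across the disease-direction ×
condition grid; raw −log₁₀ p is emitted alongside.

## Deming regression

With δ = σ²_y/σ²_x (default 1: both axes are log₂ fold-change estimates
of comparable precision), the closed-form slope is the positive root of
the errors-in-variables normal equations; the intercept is ȳ − m·x̄.
When s_xy = 0 the orientation is degenerate unless δ·s_xx > s_yy, in
which case the flat line (slope 0) is returned.  The slope standard
error is a leave-one-out jackknife, computed by vectorized downdating of
the second moments (O(n) per fit); 95% CIs are ±1.96·SE.  Jackknife
rather than an analytic SE: it is assumption-light and directly
validated by CI coverage on simulations (measured coverage 0.93–0.95 at
n = 100).  Slope comparisons use z = (m₁−m₂)/√(SE₁²+SE₂²) with a
one-sided "greater" default; two exact fits with equal slopes give
z = 0, unequal ones are flagged degenerate with p = 0.  OLS on the same
noisy-x data is attenuated by 1/(1+σ²_x/var(x*)), which the tests
demonstrate against the Deming estimate — the reason errors-in-variables
regression is used at all.

## The synthetic-data generator

The generator emulates a gnotobiotic 2×2 study: genotype (WT vs TF
mutant) × colonization (GF vs CV), with replicate numbers
{WTCV 3, WTGF 3, MutCV 2, MutGF 2} matching the transcriptome design it
mirrors, and 2000 genes across three 40-Mb chromosomes (TSSs uniform
with ≥ 2 kb spacing) by default.

Each gene draws one class: null (70%), the four coregulated quadrants,
or a single-axis class.  The suppressed side splits 9%/1%
activated/repressed, planting the ~90% headline fraction; the induced
side splits symmetrically (9%/1%), reflecting the TF's activator role on
both sides and making the planted microbiota effect μ and genotype
effect γ uncorrelated across genes — the property that lets the
genotype-axis comparisons carry the disease slope while the
colonization-axis comparisons are genuine nulls for it.  Effects are
±effect_size (default 2 on log₂, a clearly detectable but realistic
magnitude) added to a log₂-uniform baseline (3–10, i.e. ~8–1000 counts);
no genotype×colonization interaction by default (a knob exists).
Per-sample library factors are log-uniform on [0.7, 1.4] to exercise
normalization.  NB sampling uses dispersion α = 0.1, typical of bulk
RNA-seq biological replicates.

Every planted-effect gene receives one peak (width 200–400 bp, summit
within 8 kb of the TSS so the 10-kb assignment rule captures it, and one
peak per gene so assignment ground truth is unambiguous).
Condition-specificity follows the gene's microbiota direction:
suppressed genes lose their peak in CV with probability peak_gf_bias
(default 0.8), induced genes gain a CV-only peak with the same
probability, microbiota-neutral planted genes keep shared peaks.  Null
genes contribute background peaks (rate 0.05) placed uniformly over the
genome, exercising the unassigned path.  Coverage tracks carry a
triangular bump (height ~40× a flat background of 1, half-width 600 bp)
at each summit, discretized at 25 bp; region counts over the peak union
(means 80 where present, 4 where absent, 3 replicates per condition)
feed the region differential stage.

Ortholog tables chain each gene to a mouse-like and a human-like
namespace with per-link dropout 0.1 and paralog-conflict rate 0.05 (the
conflicts must be removed by the one-to-one filter).  The disease list
sets y = 0.8·x* + ε_y where x* is the planted MutCV/WTCV effect (−γ) and
ε ~ N(0, 0.3²) on both axes; genes enter the published-style list when
|y| ≥ 0.25 (~1.2-fold, a typical inclusion bar), with direction = sign(y).
A noisy observed x is recorded alongside for standalone regression
checks.

**What the generator does not emulate** — and hence what green tests do
not show about real data: gene-length and GC biases, mean-dependent
dispersion trends, multi-peak regulatory landscapes, genuine
genotype×colonization interactions (the mutant's microbiota response
differing from WT's), correlated replicates or batch effects, and
sequence content of any kind.  Parameter recovery here demonstrates the
estimators and the integration logic, not robustness to those real-data
features.

## Determinism and problem sizes

A run is a pure function of (config, seed): one `SeedSequence` spawns
per-stage substreams, so stage re-runs reproduce run-all results, and
report JSON is byte-identical across repeats.  The test suite and the
acceptance script size their simulations to desk scale as a design
choice — 2000 genes per pipeline run, 200-replicate recovery studies,
1000-layout brute-force oracle sweeps — which keeps the full suite under
a minute while leaving every Monte Carlo well inside its tolerance.

## Known limitations

* The pooled-dispersion default trades real-data realism for exact
  calibration under the package's own model; on real counts with
  dispersion trends it will over-reject for high-dispersion genes.
* Asymptotic KS p-values are conservative at small n; the exact mode is
  provided but quadratic in sample size.
* The Deming δ is assumed known (default 1); per-point error variances
  and weighted fits are out of scope.
* The quadrant classification inherits the significance thresholds'
  FDR character: contaminating false positives on one axis appear as
  misclassified quadrant members at roughly the BH-controlled rate.
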