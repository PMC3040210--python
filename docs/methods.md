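# Methods

This note documents the statistical procedures implemented in `equiscreen`,
the defaults chosen where the methodology leaves room, and what the
synthetic-data generator does and does not emulate.

## Data model and preprocessing

A peak table is a samples × peaks matrix of positive abundances with
missing entries; the study design records genotype, role
(control / transgenic / reference), ripening stage, treatment, harvest order
and replicate per sample. Preprocessing removes peaks with a missing
fraction strictly above 0.30, log10-transforms the remainder and autoscales
each peak (center, unit variance) over its *observed* entries. Scaling on
observed entries only keeps autoscaling well defined under missingness;
log base 10 is the convention of MS peak-table analysis. Mean-centering
precedes unit-variance scaling because every downstream method (PCA,
OPLS-DA, TOST on differences) assumes centered inputs. Zero-variance peaks
are dropped with a warning since autoscaling is undefined for them.
Applying `preprocess` twice is rejected via the `transformed` flag.

## NIPALS PCA

Missing-value-robust PCA uses NIPALS: components are extracted one at a
time by alternating regressions of the residual matrix on the score and
loading vectors, with every inner product restricted to observed cells.
Columns are centered on observed-entry means. Convergence per component is
a relative score change below 1e-9 with at most 5000 iterations (matching
common implementations); non-convergence raises an error naming the
component. Under missingness the raw NIPALS loadings drift slightly from
orthogonality, so each new loading is re-orthogonalized against the
previous ones inside the iteration; on complete data the algorithm then
reproduces SVD PCA to numerical precision (verified against an SVD oracle
in the tests). Explained-variance fractions are computed as observed-entry
sum-of-squares reductions, so they are additive and non-increasing.
Requesting more components than the matrix rank raises rather than
returning noise components.

## Identifier unification and fusion

Peaks are nodes of a graph; any shared namespaced identifier (name, KEGG,
CAS, ChemSpider, platform-local) adds an edge, and connected components
form identifier groups. This is transitive on purpose: it mirrors
identifier-graph unification without re-implementing curation layers.
Unannotated peaks are singletons. Groups whose mean pairwise Pearson
correlation (pairwise-complete) reaches `r_min` are replaced by their first
NIPALS principal component, rescaled to unit variance, with the sign fixed
so the consensus correlates positively with the member mean profile;
poorly correlated groups stay as duplicates, as do groups whose members
share fewer than three common observed samples (a correlation on fewer
points is meaningless). Design choices worth noting:

- `r_min = 0.5` by default, motivated by typical cross-platform
  reproducibility of annotated metabolites (≈0.5 on real multi-platform
  data); configurable.
- The merge criterion is the *mean* pairwise correlation, robust to one
  weak pair in groups of three or more; users preferring the minimum can
  test pairs themselves via `mean_pairwise_correlation`.
- Negative correlations never merge: anti-correlated peaks with the same
  annotation indicate an annotation conflict and are safer kept separate.

The cross-platform correlation report averages Pearson r over peak pairs
that straddle two platforms within a group, then over metabolites.

## Chemical-diversity coverage

Both the reference metabolome and the detected metabolites are described by
18 physicochemical descriptors (vapor pressure, partition/distribution
coefficients, bioconcentration and adsorption coefficients, molecular
volume/refractivity/weight, rotatable bonds, boiling/flash points, enthalpy
of vaporization, polar surface area, H-bond donors/acceptors, surface
tension, density, refractive index). Vapor pressure is log10-transformed;
all columns are centered and unit-variance scaled. Subsets are standardized
**with the reference's parameters** so both matrices share one coordinate
system. Coverage fits PCA to the subset (centered on the subset's own
means) and reports `100·(1 − SS(X − X̂)/SS(X))`, where X is the reference
matrix centered on its own column means and X̂ its projection onto the
subset loadings; rows with missing descriptors are projected by least
squares on their observed coordinates, and missing cells are skipped in
both sums. This centering convention makes subset = reference at full rank
give exactly 100%. The default component count is the smallest reaching
95% of the subset's variance (capped at descriptors − 1), since no single
canonical choice exists; it is configurable and coverage is monotone
non-decreasing in it.

## Design-response screen and ANOVA decomposition

Each peak is regressed (OLS, complete-case rows per peak) on additive
first-order encodings of the design: categorical factors in treatment
coding, harvest chronology as a centered numeric covariate (a many-level
harvest factor would exhaust residual degrees of freedom). The screen keeps
peaks whose overall model F-test gives p < α (default 0.05, configurable);
no multiplicity correction is applied because the screen controls data
quality, not inference. Rank-deficient designs raise an error naming the
aliased columns. Constant peaks have undefined F and are excluded with a
warning. Under a pure-noise null the retention rate is calibrated to α
(simulation-tested).

The variance decomposition uses sequential (type-I) sums of squares in the
declared factor order (default stage → genotype → treatment → harvest,
interactions last), scaled so each peak's total SS is 100; sequential SS is
exactly additive, so the scaled rows sum to 100 including the residual.
Per-factor F-tests against the residual mean square flag significance at
the 95th percentile of the corresponding F distribution. The implementation
is cross-checked against an independent sequential-ANOVA oracle
(statsmodels `anova_lm`, type I) in the tests.

## Moderated t

For focused two-group comparisons the pooled per-peak variances s² (df
pooled degrees of freedom) are shrunk toward an empirical-Bayes prior:
under the hierarchical model s² ~ s₀²·F(df, d₀), the hyperparameters are
estimated by moment-matching the log variances (digamma/trigamma
moments, trigamma inverted by Newton iteration), and the posterior variance
is s̃² = (d₀s₀² + df·s²)/(d₀ + df) with the t statistic on df + d₀ degrees
of freedom. With d₀ = 0 the ordinary pooled t is recovered exactly. When
the observed log-variance dispersion does not exceed what a single common
variance predicts, d₀ is not estimable and the implementation falls back to
the ordinary t with a warning. Benjamini–Hochberg adjusted p-values are
reported as an extra column. Parameter recovery (d₀ within ±1, s₀² within
±0.2 at 5000 peaks) is verified in the tests.

## Proof of safety (TOST with panel-derived margins)

For each peak and ripening stage, every reference cultivar's mean
difference from the control gets a two-sided 90% Welch confidence interval
(Welch–Satterthwaite degrees of freedom). In symmetric mode the cultivar
*furthest* from the control — operationalized as the largest absolute mean
difference on the log scale — defines `margin_high` as the maximum absolute
CI bound, and `margin_low = −margin_high`. The alternative reading
(furthest = largest absolute CI bound over all cultivars) is available via
`selection="ci"`. Asymmetric mode takes the envelope of all cultivars' CI
bounds instead, clipped to bracket zero.

Safety of a transgenic line is tested with two one-sided Welch t-tests of
the compound null δ ≤ margin_low ∨ δ ≥ margin_high; the reported p is the
larger one-sided p and safety is declared at p < α (default 0.05). Margins
are derived per stage by default (pooling is available) because ripening
dominates metabolite variation and a pooled margin would mix stage effects
into the equivalence band. With zero variance in both groups the outcome
degenerates to whether the observed difference lies strictly inside the
margins (p set to 0 or 1, flagged). A one-sample Kolmogorov–Smirnov test of
the standardized residuals against the standard normal is reported as a
diagnostic column; because the residuals are standardized with estimated
moments the test is conservative, and it never gates the TOST. No
multiplicity correction is applied, matching per-endpoint equivalence
reporting; a BH column is emitted for users who want one. In
hypothetical-panel mode each reference cultivar is tested as if it were a
transgenic line, with margins re-derived from the remaining cultivars
(leave-one-out), benchmarking the procedure's behaviour on lines of known
provenance. Operating characteristics verified by simulation: size ≤ α at
either margin boundary under unequal variances, power non-decreasing in
replicates under true equivalence, and monotonicity in the margins.

## OPLS-DA

Genotypes are encoded as one indicator column per class. Orthogonal
components are extracted iteratively: each is the part of the current PLS
loading orthogonal to the column space of XᵀY, which guarantees its score
vector has exactly zero covariance with every class indicator; the matrix
is deflated and the basis recomputed each round. PLS2 (NIPALS) predictive
components are then fitted on the deflated matrix. Score orthogonality and
the exact partition of the total sum of squares into predictive +
orthogonal + residual follow from the deflation scheme and are asserted in
tests (with zero orthogonal components the predictive scores match a
PLS-DA oracle). `n_predictive` is capped at classes − 1. Missing entries
are column-mean imputed with a warning, both at fit and at prediction.

Class prediction uses the nearest class centroid in predictive-score space
— standard and parameter-free. Model assessment uses stratified k-fold
cross-validation (fold assignment bit-stable under a seed) and a label
permutation test with empirical p = (b+1)/(m+1), the positively biased
estimator that can never be zero. The orthogonal component count is best
chosen by cross-validated accuracy (`accuracy_by_components` helps with the
predictive count). Correlation loadings are plain Pearson correlations of
each peak with each predictive score; loading concordance between
independently fitted models is Spearman's rank correlation over shared
metabolites with a one-sided (ρ > 0) p-value, requiring at least five
shared keys.

## Sammon MDS

The predictive-score geometry is compressed to two dimensions by minimizing
Sammon stress E = (1/Σδ) Σ (δ−d)²/δ with a diagonal-Newton update scaled by
the original magic factor 0.3, at most 500 iterations, initialized from
classical (Torgerson) MDS. Any step that would increase the stress is
halved (up to 30 times), making the accepted-stress trajectory
non-increasing by construction. Zero off-diagonal distances are jittered
with a warning because the stress divides by them. Configurations that are
exactly two-dimensional are reproduced with stress < 1e-6 (classical MDS
already solves them; the descent merely confirms).

## Synthetic-data generator

`generate_study` emulates the *statistical* structure of a multi-platform
SE study — not spectra or chromatograms. Log10 abundances are
baseline + stage effect + cultivar effect + GM effect + smooth harvest
drift + noise. Defaults model a hydroponic-style experiment: 8 genotypes
(control, 2 transgenic, 5 reference) × 2 stages × 8 replicates, 600 peaks
over three platforms, 40 latent metabolites detected on all three. Effect
scales (stage 0.5, cultivar 0.4, drift 0.2, noise 0.25 log10 units) are
chosen to reproduce the qualitative behaviour of fruit metabolomics data:
ripening dominates, cultivars differ clearly, replicate noise is a fraction
of both. Transgenic lines share the control's genetic background, so their
only systematic deviation is the planted GM effect on a ledgered subset of
50 metabolites, sized at 1.5× the margin the reference panel is expected to
imply for that peak (largest absolute cultivar effect plus the Welch CI
slack at the configured noise and replicate count) — large enough that a
correct TOST must refuse to declare it safe. For latents shared across
platforms, a configured fraction ρ of the noise variance is common to all
platforms, planting the cross-platform correlation (the *realized*
correlation also includes the shared biological effects, so it exceeds ρ
in effect-rich configurations; configurations with effects disabled
recover ρ itself). Missingness is censoring-dominated (lowest raw
abundances removed below a platform quantile) plus a small random fraction,
matching metabolomics reality — note this biases naive mean estimates for
strongly down-shifted peaks, which is intended realism.

`generate_property_tables` samples a reference metabolome from a low-rank
Gaussian descriptor model (geometrically decaying eigenvalues, random
orthogonal loadings) and emits raw-scale tables (vapor pressure
exponentiated so the standard log transform applies). Subsets are drawn
exactly inside chosen principal planes of the standardized reference, so
their true coverage equals the plane's variance share, computed directly
from the generated matrix by SVD — an oracle independent of the package's
PCA.

What passing tests on these data do *not* show: robustness to retention
time shifts, annotation errors, batch-to-batch normalization artifacts, or
non-Gaussian biological effect distributions; those are upstream of or
orthogonal to the statistical claims tested here.

## Problem sizes and numerical choices

The test suite and the acceptance script run the full pipeline at the
default generator scale (128 samples × 600 peaks), TOST operating
characteristics at 2000 Monte-Carlo replicates, screen calibration at 2000
null peaks, and moderated-t recovery at 5000 peaks — sizes at which
Monte-Carlo error is small relative to the asserted tolerances while the
whole suite stays fast. Numerical tolerances: NIPALS 1e-9 (relative score
change), PLS 1e-10, loading orthonormality asserted at 1e-8, SS partitions
at 1e-6–1e-8. Missing-token set for I/O: empty cell, `NA`, `NaN`.

## Known limitations

- The identifier unifier is graph-transitive with no curation layer; a
  single wrong shared identifier merges two metabolites.
- Fixed-effects linear models only; no mixed-effects or repeated-measures
  support.
- The TOST operates on relative (log-scaled) data; absolute-concentration
  margins are out of scope.
- O2PLS and kernel variants of OPLS-DA are not implemented.
- Raw instrument files (mzML/netCDF), chromatogram deconvolution and batch
  normalization are upstream of this tool.
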