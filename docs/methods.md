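# Methods

This note documents the statistical procedures implemented in
`cryoextender`, the defaults chosen where the workflow leaves choices
open, and what the synthetic-data generator does and does not emulate.

## Synthetic experiment tables

The generator emulates a screening study of 12 extender components over
fixed physical ranges (water 0–4 mL, tris 3–8 mL, egg yolk 1–2 mL, milk
0–0.4 mL, fructose 0–125 mg, trehalose 0–165 mg, CLC 2–10 mg,
glutathione 0–10 µL, melatonin 5–12 µL, NGF 0–500 ng, glycerol
0–0.75 mL, ethylene glycol 0–0.85 mL), with 122 runs × 4 replicates =
488 media and 43 Holstein bulls.

The ground-truth response surface is linear in the concentrations, with
intercepts and main-effect coefficients taken from the reference PLS
prediction equations (`reference.COEFFICIENTS`), e.g. for total motility
TM = 72.329 + 21.724·glycerol − 23.890·ethylene-glycol + …  Two-way
interactions are off by default because the reference equations are
main-effects only; the pairs that reached significance in the reference
ANOVA are available as a preset whose magnitudes the user supplies
(only their mean squares, not coefficients, were reported).

Residual noise is Gaussian with SD √(residual mean square) of the
reference ANOVA: √14.49 ≈ 3.81 %-points for TM and √13.59 ≈ 3.69 for PM
— the only dispersion anchor available.

Bull effects are additive intercept shifts. Cohort sizes default to the
reported cluster sizes (28, 10, 3, 1); these sum to 42 although 43 bulls
entered the study — both numbers are reported in the source and the
discrepancy is preserved rather than resolved. Bull-effect dispersion
was not reported; the defaults (between-cohort SD 5, within-cohort SD 2
%-points) were chosen once as a realistic bull-to-bull spread comparable
to, but larger than, the residual noise, so that bull structure is
detectable but does not dominate the composition signal. Each run's four
replicates are assigned to four distinct bulls round-robin from a seeded
permutation, mirroring the collection protocol in which each day's
ejaculates were split across that day's extenders.

Responses are clipped to [0, 100] because motility is a percentage;
clipping events are counted and logged. Consequences: the linear ground
truth holds exactly only on the interior, so exact-recovery tests
exclude clipped rows, and the generator's defaults keep clipping rare.

What the generator does **not** emulate: day/season/ejaculate effects,
CASA measurement error structure, heteroscedasticity, and any
correlation between components and bulls. Passing tests therefore
demonstrate correctness of the algorithms under the stated model, not
robustness to those real-data features.

## I-optimal design

The criterion is the average prediction variance over the coded cube
[−1, 1]^k under the uniform measure, `I = tr[(XᵀX)⁻¹M]`, with the
moments matrix computed exactly from E[x^e] = 1/(e+1) for even e and 0
for odd e (so E[x²] = 1/3, E[x⁴] = 1/5, E[x²y²] = 1/9). Coordinate
exchange sweeps every (run, factor) coordinate over a five-level
candidate grid {−1, −0.5, 0, 0.5, 1} (optionally refined by a bounded
continuous line search), accepting only improvements, from `n_starts`
random non-singular grid starts (default 10). Candidate evaluations use
rank-one up/downdates of (XᵀX)⁻¹, so each costs O(p²); the inverse is
refactorized every sweep to control drift. Convergence: a full sweep
improving by < `tol` (default 1e−9). The coded design maps affinely onto
the physical ranges. No mixture constraint is imposed (the component
ranges are not volume-constrained). Default pipeline runs cap the number
of sweeps (the criterion improvement beyond a few sweeps is marginal for
the 122-run, 91-term quadratic case); the cap is configurable.

## Response-surface fitting and ANOVA

OLS via `numpy.linalg.lstsq`; rank-deficient model matrices are fitted
with the pseudo-inverse and the dependent (aliased) terms flagged via
pivoted QR. The sequential fit summary tests linear → quadratic → cubic
orders with extra-sum-of-squares F tests; an order is aliased when its
added monomial columns are not estimable at the available run count
(e.g. the 455-term cubic in 12 factors at 122 distinct runs). Type III
(partial) sums of squares are computed by full-vs-term-deleted model
comparison, which for continuous covariates equals the partial SS
without contrast machinery. The residual df of the reference ANOVA
(43) is not reproducible because the replicate averaging used there is
unstated; the term list is configuration instead.

## Preprocessing

Outlier removal deletes exactly the k rows with largest |residual|
(default k = 88 of 488, the reported count), ties broken by row order.
The "box-plot" rule used originally is under-specified; the stated count
is the operative quantity. Splitting permutes rows with a seeded
generator and takes the first ⌊0.75·n⌋ as calibration (300/100 for
n = 400). Quantiles use linear interpolation (numpy default) throughout.
Whether outliers were removed per response or pooled is unstated; the
package uses the configured response's residuals.

## PLS regression

NIPALS PLS2 on autoscaled X and Y (centered, unit variance, ddof = 1).
The score iteration is seeded with the dominant singular direction of
XᵀY — the NIPALS fixed point — so convergence is immediate and robust
even for late, near-degenerate components; the loop still iterates to
the stated tolerance (1e−10 relative change in t) and errors on
non-convergence. X and Y are deflated on each component. Rotated weights
W* = W(PᵀW)⁻¹ give scores from undeflated data; coefficients B = W*Cᵀ
are back-transformed to original units. Full-component PLS equals OLS,
which the tests verify against independent least squares.

The default of 3 components matches the downstream clustering on
(t₁, t₂, t₃); leave-one-bull-out jackknife CV reports Q²(A) =
1 − PRESS/TSS and recommends the smallest A within 1% of the maximum.
"Taking bulls into account" is operationalized as this grouping — the
only reading that changes the computation reproducibly. Coefficient
uncertainty uses the delete-one-bull jackknife (SE² = (g−1)/g·Σ(B₍ᵢ₎−B̄)²)
with t(g−1) intervals; the interval method behind the reference
coefficient table is unstated, so these are provided but not matched to
printed values.

Validation metrics: R² uses the standard total-sum-of-squares
denominator Σ(Mᵢ−M̄)². The variant with denominator Σ(Ā−Pᵢ)² that
appears in some formula listings is available behind
`printed_variant=True` but is not the default, since it can exceed 1 for
near-perfect fits. MAPE excludes rows with measured value exactly 0
(motility can be 0.00) and reports the excluded count. RPD = SD/RMSE
with the sample (ddof = 1) standard deviation.

## Bull clustering

Rows are projected to the first three PLS scores and averaged per bull;
Euclidean distances between the per-bull means feed average-linkage
(UPGMA) agglomeration (scipy backend; tests verify equivalence with a
naive O(n³) re-implementation). Scores are not standardized before the
distance computation by default (a config flag standardizes them), since
the original choice is unstated. Cutting the tree at k removes the k−1
highest merges; groups are numbered by size descending. Newick export
places each node at half its merge height, so leaf-to-root depths are
equal (ultrametric).

## Monte Carlo screening

Each component is drawn independently from a normal distribution
truncated to its physical range (inverse-CDF sampling; sd = 0 yields a
constant). The source does not state the distribution parameters;
defaults are mean = range midpoint and sd = range/6, which puts ~99.7%
of the untruncated mass inside the bounds, and all parameters are
overridable. Predicted motility is the linear PLS equation evaluated at
each draw. Sensitivity: Pearson correlation rⱼ between each component's
draws and the prediction, and contribution (%) = 100·rⱼ²/Σₖrₖ² — this
normalized-squared-correlation statistic exactly reproduces the
reference sensitivity table's contribution column from its correlation
column, which is how the formula was identified. Top-k tables are
reported ascending (best last). Distribution summaries use moment-based
skewness: positive skew among top-performing draws indicates lower
concentrations suffice, negative skew indicates headroom above.

## Multiple factor analysis

Active groups' columns are standardized (population SD), each group is
weighted by 1/λ₁ (inverse of its leading PCA eigenvalue, computed as the
top squared singular value of Z/√n), and a global PCA of the weighted
concatenation yields eigenvalues, row coordinates (√n·U·S), variable
coordinates (correlations with the dimensions) and contributions
(squared loadings, summing to 100% per dimension across active groups).
The supplementary categorical group is projected as level barycenters
and contributes nothing to the axes. The default variable-to-group map
(basic compound = water/tris/fructose; extracellular protectant =
egg yolk/milk; CPA = glycerol/ethylene glycol; osmoregulator =
trehalose/CLC; antioxidant class = glutathione/melatonin/NGF; motility =
TM/PM) is an inference exposed as configuration — the merged
"CPA and osmoregulator" grouping used for path modeling is equally
valid here.

## PLS path modeling

All blocks are reflective (mode A). Outer weights start at 1, inner
proxies use the centroid scheme by default (factorial and path are
selectable; the original scheme is unstated, and centroid is the
conventional default of reference implementations), and the alternation
stops when the normalized outer weights change by < 1e−9. Latent scores
are standardized (ddof = 1); loadings are manifest–latent correlations
with signs oriented so each block's loading sum is positive.
Dillon-Goldstein's rho = (Σλ)²/[(Σλ)² + Σ(1−λ²)] with λ the correlations
with the block's first principal component; single-manifest blocks
return 1 by convention, and rho > 0.70 sets the unidimensionality flag.
Path coefficients are OLS of each endogenous latent on its predecessors;
R² per regression; GoF = √(mean communality × mean R²) where the
communality mean runs over blocks with more than one manifest variable
only — single-indicator blocks have communality 1 by construction and
would inflate the index. The default structural model (basic compound
and extracellular protectant exogenous; CPA-and-osmoregulator and
antioxidant class intermediate; motility terminal) is configuration.
The path matrix must be acyclic; bootstrap intervals and formative
blocks are out of scope.

## Numerical conventions and degenerate inputs

* Seeds: every stochastic operation takes an explicit seed
  (`numpy.random.default_rng`); the pipeline derives stage seeds from
  one master seed, and identical configs reproduce outputs
  bit-identically.
* Zero-variance columns raise errors naming the column (PLS, MFA,
  PLS-PM, sensitivity).
* Singular information matrices in the design module raise errors naming
  the deficient model terms.
* Constant measured vectors make R² undefined and raise; perfect fits
  report RPD as infinity.
* Tie-breaks: outlier removal by row order; tree-group numbering by
  size then first appearance.

## Problem sizes used in the examples and tests

Tests and the pipeline default to the study's own scale (488 rows, 42
bulls, 10,000 Monte Carlo draws). Design construction in automated runs
uses a single start with a capped number of coordinate-exchange sweeps;
multi-start, fully converged searches are a one-line configuration
change. The five-block path-model recovery study uses n = 400 rows and
two indicators per block with loading 0.97, averaged over five seeds —
with highly reliable indicators the attenuation bias of composite scores
is below the ±0.05 tolerance being checked.

## Known limitations

* PLS-PM composite scores attenuate structural coefficients when
  indicator loadings are far below 1; no disattenuation (consistent
  PLS) is implemented.
* The MFA omits the RV coefficient matrix and mixed categorical-active
  groups.
* The I-optimal search is heuristic; global optimality is verified only
  on enumerable instances.
* Real-data-dependent quantities from the motivating study (validation
  R²/RMSE on its measurements, its dendrogram, its MFA variance shares,
  its GoF) are not reproduction targets: they depend on data that the
  generator only emulates structurally.
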