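# Methods

`sympmix` studies how the composition of a sample — specifically, the
proportion of non-affected subjects it contains — shapes the results of
standard psychometric analyses of an ordinal symptom battery. This note
documents the data-generating model, each analysis stage, the numerical
choices, and what the synthetic experiments can and cannot show.

## The collider mechanism

Caseness on a symptom scale is defined from the scale's own sum score: a
subject is "affected" when the total of their item responses reaches a
cutoff. The sum score is a common effect of all items, i.e. a collider.
Selecting subjects by case status therefore conditions every inter-item
association on (a coarsening of) their common effect, which attenuates the
correlations and can push them negative. Adding non-affected subjects back
into an affected-only sample relaxes the conditioning, so every statistic
built on the inter-item associations — correlations, eigenvalue structure,
factor fit, scalability, network edges — changes systematically with the
mixing proportion. The mixture experiment (`sympmix.experiment`) traces
those trajectories.

## Synthetic cohort (`sympmix.synthetic`)

Data come from a probit graded-response model. A latent severity
θ ~ N(0, 1) drives item j through y_j = λ_j θ + e_j with
e_j ~ N(0, 1 − λ_j²), so each latent response is standard normal and the
population latent (polychoric) correlation of items i and j is λ_i λ_j.
The observed code is the interval of the item's threshold vector into which
y_j falls. With `n_factors > 1`, items split into contiguous blocks driven
by equicorrelated traits.

Defaults and why:

- **12 items × 6 categories** (codes 0–5): the shape of a standard
  self-report depression inventory with six-point frequency scales.
- **Loadings 0.5–0.8** (evenly spaced): mid-to-high, heterogeneous
  discriminations typical of a well-constructed clinical scale;
  heterogeneity matters because it makes the collider attenuation
  pair-specific rather than a uniform shift.
- **Thresholds** right-skewed (base cutpoints 0.5, 1.02, 1.54, 2.06, 2.58
  with per-item shifts ±0.2): roughly 69% of the population in category 0
  and under 1% in the top category, mimicking symptom-frequency data in a
  general population.
- **Target prevalence 0.061**: caseness of "at least mild" severity in a
  general-population cohort of young adults.
- **Cutoff calibration**: the cutoff is the smallest *observed* sum-score
  value whose upper-tail fraction does not exceed the target prevalence.
  Restricting candidates to observed values makes the rule well defined on
  discrete scores; with all scores equal no tail exists and the
  calibration raises an error. Realized prevalence is reported alongside
  (e.g. 5.5–6.0% for the 6.1% target at n = 6,000).

One root seed governs everything; latent draws, item noise, replicate
subsampling, parallel-analysis permutations and bootstrap streams all come
from independently spawned child streams, so each stage is replayable in
isolation.

## Polychoric correlations (`sympmix.polychoric`)

Two-step maximum likelihood, the standard convention: thresholds are the
normal quantiles of each item's cumulative margin, then each pair's latent
correlation maximizes the bivariate ordinal likelihood with thresholds held
fixed. Cell probabilities are bivariate-normal rectangle probabilities
computed by Gauss–Legendre quadrature (48 nodes per x-interval, truncation
at |x| = 8) of φ(x)·[Φ((d−ρx)/√(1−ρ²)) − Φ((c−ρx)/√(1−ρ²))]; against an
adaptive 2-D quadrature oracle the cells agree to ~1e−15. The likelihood
is maximized by bounded scalar search on [−1+1e−6, 1−1e−6] with tolerance
1e−6; the tests verify agreement with an exhaustive grid search to 1e−3.

Numerical conventions, all configurable:

- cell probabilities floored at 1e−12 before logging;
- |ρ| clipped at 1−1e−6, boundary solutions flagged;
- zero-count categories collapsed into their neighbour toward the nearer
  tail (equivalently: observed codes densified per item), which keeps
  thresholds finite and strictly increasing;
- items with fewer than two observed categories are dropped with a warning.

The assembled matrix is repaired to positive definiteness once, before any
eigen/CFA/network consumption, by clipping eigenvalues at 1e−6,
reconstructing, and rescaling to unit diagonal. The repair is the identity
on already-PD input.

## Dimensionality (`sympmix.dimensionality`)

Eigen summaries report the variance share of the first eigenvalue (λ₁/p)
and the first/second eigenvalue ratio, with the conventional
unidimensionality rules of thumb: share strictly above 20% and ratio of at
least 3 (the 20% boundary is strict because the rule is stated as
"higher than").

Parallel analysis perturbs the data by independently permuting every
column — margins preserved, inter-item structure destroyed — 100 times by
default, and retains components whose observed eigenvalue exceeds the 95th
percentile of the permuted eigenvalues at the same rank, stopping at the
first failure (the standard sequential convention). The permuted sets use
the same correlation kind as the main analysis (polychoric) by default; a
Pearson fast path exists for replicated designs, where the ~100×
correlation-matrix cost would otherwise dominate. Ordinal Pearson
eigenvalues are biased toward 1 relative to polychoric ones, but retention
decisions compare observed and permuted eigenvalues of the *same* kind, so
the fast path changes the component count only in borderline cases.

## One-factor CFA (`sympmix.cfa`)

The model Σ_ij(λ) = λ_i λ_j (unit diagonal) is fitted to the latent
correlation matrix by weighted least squares over the p(p−1)/2 unique
correlations, with loadings constrained to (−1+1e−6, 1−1e−6) (Heywood
solutions flagged at the boundary), analytic gradients, and three starts:
a first-eigenvector scaling, a flat 0.5 vector, and zero. Ties between
zero-residual optima break toward the smaller-norm solution, making the
all-zero vector the canonical fit to an identity matrix. The sign is
normalized so the mean loading is nonnegative.

The test statistic is residual-based with diagonal weights:
T = Σ_{i<j} (r_ij − λ_i λ_j)²/v_ij, with the zero-correlation model as
baseline. The per-pair variances v_ij are estimated by nonparametric
bootstrap over subjects (full two-step re-estimation per resample, 200
resamples by default) when requested; the fast default is the uniform
v_ij = 1/(n−1), which places T on a chi-square-like scale (under the true
model the replicate-mean T/df sits below 1 because the fitted loadings
absorb part of the residual variation, and because diagonal weights ignore
the covariance among the r_ij). Fit indices use the standard formulas
CFI = 1 − max(T−df, 0)/max(T_b−df_b, T−df, ε) (clipped to [0, 1]),
TLI = ((T_b/df_b) − (T/df))/((T_b/df_b) − 1) (flagged undefined when
T_b/df_b ≤ 1), RMSEA = √(max((T−df)/(df(n−1)), 0)), with
df = p(p−1)/2 − p: the fit is to the correlation matrix only, so
thresholds are not counted as parameters.

This statistic is deliberately *not* the mean-and-variance-adjusted WLSMV
statistic, which requires the full asymptotic covariance of the polychoric
correlations. Index values are therefore comparable in behaviour —
monotone in misfit, 1/0 at perfect fit — but not numerically exchangeable
with WLSMV software output, and all assertions about them in the test
suite are property-based (recovery, monotonicity, directional contrasts).

## Mokken scalability (`sympmix.mokken`)

Polytomous H by the covariance-ratio convention:
H_ij = Cov(X_i, X_j)/Cov^max(X_i, X_j), where the denominator is the
covariance of the comonotonic (Fréchet-upper-bound) coupling of the two
item margins, built by merging the cumulative margins in sorted order.
Item and scale coefficients aggregate the same numerators and denominators
(per-item H uses all other retained items). Covariances use the 1/n
normalization in both numerator and denominator; the ratio is invariant to
that choice. The comonotonic construction is verified in the tests against
a transportation-LP oracle that maximizes covariance over all couplings.

## Networks (`sympmix.network`)

Gaussian graphical models on the PD-repaired polychoric matrix. The
penalty path is log-spaced over 100 points from λ_max = max|off-diagonal|
down to λ_max/100; each fit solves the graphical lasso with off-diagonal
L1 penalty; the L1 solver is scikit-learn's coordinate-descent
`graphical_lasso` (inner tolerance 1e−10), wrapped with a KKT check
(stationarity residual ≤ 1e−3, tolerance tightened and the fit retried if
violated). EBIC = −2ℓ + E log n + 4Eγ log p with γ = 0.5 selects the
penalty; ties go to the sparser model. Edges are partial correlations
−K_ij/√(K_ii K_jj); summaries (median, quartiles, extremes) are taken over
all p(p−1)/2 possible edges *including zeros*, so a sparse network
legitimately has median edge 0. Support along the path is monotone up to
coefficients crossing zero as the penalty relaxes — a real, if rare,
feature of L1 paths — and the tests treat exactly that case as the only
admissible exception.

## The mixture experiment (`sympmix.experiment`)

The default grid has 22 conditions: proportions 0.10–0.90 (step 0.10),
1.00–10.00 (step 1.00), plus the three reference samples `dep` (affected
only), `full`, and `nondep` (non-affected only). A numeric condition π
draws all affected subjects plus round(π · n_affected) non-affected
subjects without replacement (half-up rounding: 356 affected at π = 0.10
gives exactly 36), 500 replicates by default, each on an independently
spawned stream. Every statistic is computed per replicate and averaged
across the replicates in which its stage succeeded (per-stage failure does
not discard the replicate's other statistics; per-stage valid counts are
reported). Correlation matrices are additionally averaged elementwise, and
`statistics_from_mean_matrix` re-runs the eigen/CFA/network stages on the
averaged matrix — the alternative reading of "average the analyses" —
so both interpretations are available. Reference samples run once.

## Problem sizes used in the shipped analyses and tests

The shipped analysis scripts and the acceptance script use a cohort of
n = 6,000 with ~6% prevalence (≈ 330–360 affected subjects), a reduced
grid of 9–3 numeric conditions, 50 replicates, and the Pearson fast path
for parallel analysis inside replicated designs; with those sizes a full
trajectory takes a few minutes on one core. Estimator-accuracy tests use
n up to 100,000 for single pairs and n = 50,000 for full matrices. The
complete 22 × 500 design is available behind `--full-grid --replicates
500` and scales linearly.

## What the generator does and does not emulate

It reproduces the structural ingredients the composition experiment needs:
a dominant latent dimension, six-category right-skewed items, sum-score
caseness at realistic prevalence, and the resulting collider geometry. It
does **not** emulate real symptom data in other respects: no local
dependence beyond the single factor, no covariates or subgroup
heterogeneity, no missing data (listwise deletion exists only in the
reader), and a plain calibrated sum-score cutoff rather than any
instrument's diagnostic algorithm. Selection on a sum score of a *pure*
one-factor battery conditions away nearly all common variance, so the
affected-only attenuation here is stronger than in real cohorts (average
affected-only correlations near 0.03–0.05, versus ~0.3 reported for real
depressed-only samples); passing directional tests therefore demonstrates
the mechanism and the pipeline, not the magnitudes to expect in any real
data set. Likewise the diagonal-weight CFA statistic makes well-fitting
samples hit CFI = 1 exactly rather than 0.97-ish.

## Known limitations

- Polychoric standard errors are not computed; only bootstrap-level
  variability enters (as CFA weights).
- TLI is undefined (and flagged) when the baseline model already fits;
  with near-saturated baselines TLI can exceed 1 slightly.
- The EBIC γ, path length and min-ratio are ecosystem defaults, not tuned.
- Parallel analysis inside replicated designs defaults to the Pearson fast
  path; polychoric PA on every replicate is available but ~100× slower.
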