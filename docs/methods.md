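# Methods

This note documents the statistical procedures implemented in `sdqnorm`,
the choices made where the design was genuinely open, and what the
synthetic-data tests do and do not demonstrate.

## Scoring

The built-in instrument definition (`sdqnorm.instrument`, version
`sdq-standard-1`) uses the standard published SDQ key: five 5-item scales,
five reverse-coded items (7, 11, 14, 21, 25 — all on difficulties scales),
composites externalizing (conduct ∪ hyperactivity), internalizing
(emotional ∪ social) and total (all 20 difficulties items). The key can be
overridden from JSON for translated or re-ordered forms.

**Missing items.** A scale score is computed when at least 80% of member
items are present (≥ 4 of 5 on base scales); the sum of present items is
prorated to the full item count and rounded half-away-from-zero. With the
~0.2% item missingness typical of these cohorts any reasonable rule gives
the same result; prorating was chosen because it keeps the score an
unbiased estimate of the complete-data sum under MCAR. The threshold is a
parameter of `score_scales`.

Ages are carried as integer years (norms are per year of age); fractional
input ages are floored. Gender is restricted to {male, female}; other
values are excluded with a logged count rather than an error, since the
norming model has no cell for them.

## Post-stratification weights

A record in cell *c* of the stratification cross gets raw weight
(population share of *c*) / (sample share of *c*); weights are rescaled to
mean 1 so that the raw subject count remains the natural N for BIC.
Population cell shares for two-variable strata are the product of the
one-way margins (independence); raking (IPF) is available as a fallback
when a full cross-classification cannot be justified. Joint norms weight on
gender × ethnic background, gender-specific norms on ethnic background
only — the gender effect is then carried by the model, not the weights.
Empty sample cells with positive population mass are an error, not a
silent renormalization.

## Response families

**Beta-binomial.** Parameterized by mean proportion μ ∈ (0,1) and
overdispersion σ > 0 (beta shapes a = μ/σ, b = (1−μ)/σ), so the mean is
n·μ and the variance n·μ(1−μ)(1+nσ)/(1+σ); σ → 0 recovers the binomial.
The pmf is evaluated in log space (`gammaln`/`betaln`) — naive
beta-function ratios underflow on the 0–40 support with small σ.

**Box-Cox power exponential.** z = ((y/μ)^ν − 1)/(νσ) (log branch for
|ν| < 1e-5) follows a standardized power exponential with kurtosis
parameter τ; the density on y > 0 is divided by the truncation constant
(the untruncated transform puts mass below y = 0 when ν ≠ 0). Many
references neglect this constant; here it is applied and the quadrature
normalization is tested to 1e-6. The quantile function inverts the
incomplete-gamma representation of the power-exponential CDF analytically.
Because of the truncation the median equals μ only up to the truncation
mass; for the σ values arising in score norming that mass is far below any
tolerance of interest.

**Discretization of the BCPE.** Total difficulties scores (0–40, 0
attainable) are shifted by +1 before fitting, since the BCPE needs y > 0.
All downstream output is produced from a half-integer discretization of
the fitted density back onto the score grid (cell (s−0.5, s+0.5] on the
shifted scale, tails folded into the endpoint scores, renormalized). This
gives norm tables, cutoffs, sampling and detection rates one uniform
discrete interface for both families, and makes the "up to 10%" guarantee
exact for the discretized model rather than approximate under a continuous
reading.

## Regression and model selection

Each distribution parameter gets a linear predictor on its link scale
(logit for BB μ; log for BCPE μ, both σ and τ; identity for ν) over a
Legendre polynomial basis in age standardized from [12, 17] to [−1, 1].
Raw age powers up to 6 are numerically hostile; the orthogonal basis keeps
the optimizer conditioned, and the basis definition is serialized with the
coefficients so predictions are basis-independent.

Estimation maximizes the weighted log-likelihood Σᵢ wᵢ log f(yᵢ | θ(ageᵢ,
genderᵢ)) with L-BFGS-B (numerical gradients, moment-based starting
values, up to three perturbed restarts from a fixed-seed generator on
non-convergence, relative tolerance 1e-12). Rows are sorted into a
canonical order before the likelihood is assembled, so refitting a
permuted dataset reproduces coefficients exactly.

**Search policy.** BIC = −2·logL + k·log(N) with N the raw subject count
(weights are mean-1). For BB the search is an exhaustive grid over
(μ-degree, σ-degree) ∈ {0..6}². For BCPE, where a full 7⁴ grid is
wasteful, the search is staged: grid over μ/σ with ν, τ at degree 0, then
expand ν, τ, μ, σ one parameter at a time holding the others at the
current best, iterating until the selected degrees are stable (≤ 3
rounds). Gender-specific norms come from a single model with a gender
main effect on every parameter; the age × gender interaction (gender ×
each non-constant age basis column) is compared by BIC *at the selected
degrees* rather than doubling the whole grid — with n ≈ 10³ the degree
choice is insensitive to the interaction term, and this halves the search
cost.

**Diagnostics.** Randomized quantile residuals (probit of U ~
Uniform(F(y−1), F(y)) under the per-subject fitted discrete distribution;
probit of F(y) for the continuous BCPE) are standard normal under a
correctly specified model. Worm plots show the detrended QQ deviation with
pointwise 95% order-statistic bands 1.96·√(p(1−p)/n)/φ(z); calibration and
the sensitivity of the residual variance to a misspecified σ are covered
by tests.

## Norm tables and cutoffs

A norm-table entry E(s) is the percent of the reference distribution
ranking **strictly below** s for difficulties scales and strictly above s
for the prosocial scale. This convention is the only one under which (a)
the abnormal rule "smallest s with E(s) ≥ 90" guarantees a flagged share
100 − E(s) ≤ 10% on a discrete scale, and (b) detection rates under
foreign cutoffs are simply 100 − E(cutoff). Published SDQ percentile
tables are not always explicit about their column alignment, so the
"at-or-below" reading (E(s) = 100·F(s)) is implemented behind a
`convention` flag for comparison; cutoff extraction itself operates on the
printed entries either way. Entries are rounded to one decimal only at
emission; extraction from a fitted model uses unrounded CDFs, while
extraction from a transcribed printed table necessarily uses the rounded
values.

The borderline cutoff (80th level) is reported as unavailable (sentinel
`-`) when it coincides with the abnormal cutoff: a coarse, strongly
right-skewed score distribution can jump straight past the 80–90 band.
The abnormal cutoff itself can be unavailable in the extreme case where
even the top score carries more than 10% mass; detection rates then report
NaN (nobody can be flagged within the bound). In *approximately* mode the
score whose flagged share is closest to nominal is chosen, ties resolved
toward the smaller share.

Joint norms are evaluated from the age-only model fitted on the jointly
weighted sample — not by averaging gender-specific tables, which would
answer a different question.

## Reliability

Per scale, Cronbach's α and the nonlinear SEM coefficient ρ_NL are
computed on reverse-coded member items. ρ_NL comes from a one-factor
tau-equivalent model on the polychoric scale: thresholds from the marginal
cumulative proportions (two-step estimation), pairwise correlations by ML
over the bivariate-normal cell probabilities (clamped to ±0.999), common
loading λ by least squares on the off-diagonals (under equal loadings the
model-implied off-diagonal is λ² everywhere, so λ² is their mean). The
coefficient is the ratio of the factor-attributable covariance of the
observed ordinal items to the model-implied variance of the sum score,
both obtained by integrating the bivariate normal over threshold cells
(latent correlation λ² off-diagonal and for the factor part of the
diagonal; 1 for total item variances). The bivariate normal CDF uses a
32-node Gauss-Legendre quadrature of the tetrachoric integral, accurate to
~1e-15 against scipy's implementation. Tau equivalence is imposed on the
underlying-variate loadings; estimation is least-squares rather than ML on
the polychoric matrix — the estimator variant is not pinned down in the
reliability literature consumed here, and ULS is standard, fast and
documented.

Missing items are completed before the reliability analysis by single
two-way imputation: person mean + item mean − grand mean + N(0, σ̂²)
error, with σ̂² the residual variance of the two-way decomposition of the
observed cells, rounded and clipped into the category range (the source
method is continuous; rounding keeps the ordinal machinery valid).
Reliability is computed unweighted on the raw imputed sample — survey
weights answer a representativity question that reliability of the
measurement instrument does not pose.

## Synthetic cohorts

The generator (`sdqnorm.simulate`) emulates the structure the analysis
assumes: five correlated latent scale traits (difficulties inter-trait
correlation 0.40, prosocial −0.25), trait means linear in age and shifted
by gender, items generated by a graded-threshold model (default loading
0.6, per-scale thresholds giving right-skewed difficulties and high
prosocial scores, as in community samples), reversed items stored raw so
the scoring path is genuinely exercised. Demographic composition defaults
mirror a typical norm group: n = 993 (self) / 736 (parent), 53.1% female,
89.1% majority ethnic background, maternal education 24.0/41.4/34.6, the
norm-group age distribution, 0.2% MCAR item missingness. Default gender
effects point the way the field's findings do (self-reported internalizing
higher for females, externalizing and parent-reported hyperactivity higher
for males) so demo output is qualitatively comparable to published tables.

A separate harness draws scale scores directly from beta-binomial strata
with known parameters for parameter-recovery tests.

**What the generator does not emulate:** informant disagreement between
self and parent reports beyond separate trait models, differential item
functioning across gender or ethnicity, non-MCAR missingness, cluster
structure from school-based sampling, and secular trends across collection
waves. Passing tests therefore demonstrate the correctness and calibration
of the *procedures*, not the validity of any particular real-world norm
table.

## Problem sizes and numerical choices

Tests run parameter recovery at n = 50,000 (intercepts, slopes) and BIC
selection consistency at n = 5,000 with 20 replications over a degree-0..2
grid; cutoff calibration uses 10⁶ draws per stratum; the end-to-end
pipeline test runs the full 48-norm-set configuration at the default
cohort sizes with the full degree-0..6 search. Optimizer tolerances:
relative logL 1e-12, gradient 1e-8; BB parameters are clipped away from
their boundaries (μ ∈ [1e-9, 1−1e-9], σ ≥ 1e-9) and BCPE shape parameters
to ν ∈ [−10, 10], τ ∈ [0.05, 100] inside the likelihood only — selected
models sit well inside these ranges. Ties in discrete quantile inversion
resolve to the smallest score with CDF ≥ q. All stochastic steps
(simulation, residual randomization, imputation) take explicit seeds, and
the pipeline derives per-stage seeds deterministically from its master
seed, recorded in the run manifest.

## Known limitations

* The BCPE fit treats discrete 0–40 scores as continuous (then
  re-discretizes); for very low-scoring cohorts a discrete family for the
  total scale might behave better near 0.
* The staged BCPE search and the staged gender-interaction comparison can
  in principle miss a jointly-optimal configuration an exhaustive search
  would find.
* Cell weighting assumes independent population margins when crossing two
  variables; use the raking fallback when that is untenable.
* Polychoric estimation is two-step and pairwise; with severely sparse
  cells the boundary clamp at ±0.999 can bias λ upward.
* No standard errors are reported for fitted coefficients or norm-table
  entries; the package follows the norming practice of model selection by
  BIC plus graphical adequacy checks.
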