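# Methods

This note records the statistical model behind each stage of the
pipeline, the defaults and why they were chosen, the numerical details,
and what the synthetic-cohort generator does and does not emulate. It
states no empirical result beyond what the test suite and
`scripts/acceptance.py` compute.

## Outcome-wide design

One focal Wave-1 exposure is related to every configured Wave-2 outcome
with a common covariate script, and every configured outcome appears in
the report — nulls included (`assemble_report` raises if a row is
missing). All models are fit separately by country; cross-country
structure enters only at the pooling stage. Two covariate sets are
supported: Model 1 (nine demographic plus eight retrospective childhood
covariates) and Model 2 (Model 1 plus the first k principal components of
the contemporaneous confounder block, default k = 7).

## Country-level regressions

Outcomes are modeled as `E[Y] = f(Xβ)`. Continuous outcomes use weighted
least squares; binary outcomes use modified Poisson regression — Poisson
estimating equations with a log link applied to a 0/1 outcome — so the
exponentiated exposure coefficient is a risk ratio. Risk ratios are not
invariant to relabeling the outcome's reference category, and the test
suite checks this on an asymmetric fixture. Log-binomial fitting is out
of scope: with many controls and small countries it fails to converge too
often to anchor a coordinated analysis.

Variances are design-based throughout, never the model-based Poisson or
OLS variances: per-respondent weighted score contributions are summed to
PSU totals, centered within strata, and combined as
`(n_h/(n_h−1))·Σ (t_hj − t̄_h)(t_hj − t̄_h)'`, then sandwiched between the
inverse expected-derivative ("bread") matrices. A stratum with a single
PSU is treated as sampled with certainty and contributes zero variance.
This is the with-replacement linearization approximation; no
finite-population correction is applied anywhere.

The four-category exposure item (never/rarely/often/always) supports four
codings: the default collapses often/always vs never/rarely; the
alternatives split never vs any-positive, all-but-always vs always, and a
1–4 approximately-continuous coding. Binary contrasts carry `sd_x = 1`,
so a standardized effect is the change in outcome SDs (or in log-RR)
between the exposure categories; the continuous coding uses the weighted
SD of the codes.

Standardization: continuous outcomes use `b_std = b·sd_x/sd_y` with the
variance scaled by the squared ratio; binary outcomes multiply by `sd_x`
only, staying on the log-RR scale. The variance transforms by the
*squared* ratio — anything else would break confidence-interval
equivariance — even where verbal descriptions of such procedures say
"multiplied by the ratio". Weighted SDs use `Σw(x−x̄_w)²/Σw` with no
degrees-of-freedom or finite-population adjustment; this convention is
deliberate and matters only at second order.

With multiple imputations, b and v are pooled by Rubin's rules on the
coefficient (linear / log-RR) scale *before* standardization, and the
standardizing SDs are across-imputation means of the weighted SDs.
Pooling on the coefficient scale keeps Rubin's normal-theory assumptions
closest to true; the ordering is a design choice documented here because
reasonable alternatives (standardize-then-pool) exist.

## Random-effects pooling

Standardized country effects follow `b_i ~ N(θ_i, v_i)`,
`θ_i ~ N(μ, τ²)`. τ² is the Paule–Mandel root of the generalized-Q moment
equation `Σ w_i(τ²)(b_i − μ̂(τ²))² = k − 1`, `w_i = 1/(v_i + τ²)`, found
by bracketed Brent iteration on [0, upper] with geometric upper expansion
and tolerance 1e-10, truncated at zero when Q(0) ≤ k−1. μ̂ is the
weighted mean at τ̂², with Wald-normal confidence intervals (SE =
(Σw_i)^{-1/2}); Knapp–Hartung adjustment is not applied, keeping the
intervals symmetric and matching the common default of reference
meta-analysis software. τ intervals come from the Q-profile: the τ²
values at which the generalized Q equals the χ²(k−1) 0.975 and 0.025
quantiles, lower bound truncated at zero.

τ̂ < 0.01 raises an instability flag: with imprecise country estimates
(e.g. exposure collinear with a covariate) moment estimators can collapse
heterogeneity to nearly zero even when country effects visibly differ, so
such cells deserve a forest-plot look rather than trust in τ̂.

The global p-value tests the joint null that the association is zero in
every country. The default statistic is `Σ (b_i/√v_i)²` against χ²(k);
Fisher's combination of two-sided per-country p-values (χ²(2k)) is
selectable, and the method used is recorded in the result. Both are
interpretations of an omnibus "at least one country" test — the exact
combiner used in published applications of this design is not specified
in their main texts — and both are calibrated under the null in the test
suite.

Influence diagnostics re-estimate the pool without each country:
leave-one-out μ̂₋ᵢ, externally studentized residuals
`(b_i − μ̂₋ᵢ)/√(v_i + τ̂²₋ᵢ + SE(μ̂₋ᵢ)²)`, and a Cook's-D-like statistic
`(μ̂ − μ̂₋ᵢ)²/SE(μ̂)²`.

## Missing data

Imputation runs independently within each country (a pooled imputation
model would let large countries impose their covariate structure on small
ones). Each incomplete variable is regressed on its predictors — Wave-1
predictors for Wave-1 gaps, Wave-1 plus Wave-2 for Wave-2 gaps —
coefficients are perturbed by a draw from their approximate normal
posterior (with a scaled inverse-chi-square draw for the residual
variance), predictions for missing cases are matched to the `donor_k = 5`
nearest observed predictions (type-1 matching: fitted coefficients
predict donors, drawn coefficients predict missing cases), and a donor's
observed value is copied. Imputed values therefore always lie in the
observed support; binary variables stay binary. Ten cycles are the
default — more than the usual five because the Wave-2 block is entirely
missing for attritors — and variables are visited in increasing order of
missingness to stabilize early cycles. Constant or absent predictors are
dropped with a logged notice; a variable with fewer observed values than
`donor_k` in some country is an error naming both.

Rubin pooling uses `T = W̄ + (1 + 1/m)B` with the Barnard–Rubin
small-sample degrees of freedom and
`FMI = (r + 2/(df+3))/(r+1)`, `r = (1+1/m)B/W̄`.

FMI for a dataset is estimated by a pilot imputation: Rubin FMI of each
incomplete variable's mean, summarized by the maximum, since the worst
variable is what drives the required number of imputations via the rule
`m = smallest integer with FMI/m < 0.05` (FMI 0.84 → m = 17). The
pilot-imputation route is an implementation choice; published analyses
state only that FMI was approximated. A small pilot m makes the FMI
estimate noisy (B has roughly chi-square relative error `√(2/(m−1))`), so
pilot runs meant to be compared against a target need m of several dozen.

## Attrition weights

Per country, a maximum-likelihood logistic model predicts retention from
Wave-1 covariates (sampling weight, demographics, childhood health proxy;
absent or constant predictors dropped with a notice, mirroring
"when possible" availability). Retained respondents receive the
stabilized weight `p̄/p̂_i`; non-retained respondents receive none and are
excluded from the semi-complete-case analysis. Fitted probabilities below
0.01 are truncated with a logged warning — published procedure states no
truncation rule; the floor caps weights at `100·p̄` and protects small
countries from a handful of extreme weights. The attrition weight is
estimated on, and multiplied into, each imputed dataset's sampling
weight; the single descriptive weight is the per-case mean of the m
analysis weights.

## Confounder principal components

PCA is run on the correlation matrix of the confounder block — ordinal
confounders as numeric codes, binary as 0/1 — within country and within
each imputed dataset, with the focal exposure always excluded from the
block. The sign convention (largest-magnitude loading positive per
component) makes loadings reproducible across seeds and column orders.
Component count policies: fixed k (default 7) or smallest k reaching a
target cumulative variance. Whether published analyses ran PCA on
complete cases or per imputation, weighted or unweighted, is not stated;
here it is unweighted and per-imputation, which avoids leaking
information across imputations.

## Sensitivity analyses

*E-values.* `E = RR + √(RR(RR−1))` for RR ≥ 1, with RR inverted first
when below 1; the confidence-limit E-value uses the CI limit closest to
the null and is 1 when the interval spans it. Standardized differences
convert through `RR ≈ exp(0.91·d)` (0.91 = π/√3 divided into the
log-odds, the standard approximate conversion), with the CI limits
converted the same way; results carry an `approximate` flag.

*Calibration.* The benchmark ratios follow the published stepwise
definitions literally: `RR_GY` is the larger, over exposure strata, of
the (larger/smaller) outcome prevalence across benchmark levels, and
`RR_DG` is the larger, over benchmark levels, of
`Pr(D=1|G=g)/Pr(D=0|G=g)`. Continuous exposure and outcome are
dichotomized at the top and bottom weighted quintiles with the middle 60%
dropped; ties go to the lower bin. Note `RR_DG` as defined can fall below
1 when the exposure is rare in both benchmark levels; after
quintile dichotomization the kept sample is roughly balanced and the
ratio behaves like a risk ratio. Calibration is unconditional on
covariates by default; the conditional variant described verbally in
published procedure is not operationalized there and is left to the
caller's stratification.

*Reliability.* `b/λ` and `SE(b)/λ` with
`λ = √(λ_x λ_y)` ∈ {0.40, 0.55, 0.70}; the CI is rebuilt from the
corrected pieces, so its width scales by exactly 1/λ. Published tables of
this correction show corrected CI half-widths that do *not* scale by 1/λ
despite stating these formulas; this implementation follows the stated
formulas and documents the discrepancy rather than reverse-engineering an
unstated CI rule. For binary outcomes the correction applies on the
log-RR scale.

*Robustness values.* Partial R² `= t²/(t²+df)` and
`RV_q = ½(√(f_q⁴+4f_q²) − f_q²)` with `f_q = q·|t|/√df`; a test verifies
that confounder strength (RV, RV) exactly nullifies the estimate through
the omitted-variable-bias bound.

## HETOP DIF screening

A single ordinal item across G countries is modeled with common
thresholds and group-specific latent mean μ_g and SD σ_g,
`Pr(Y=k|g) = Φ((τ_k−μ_g)/σ_g) − Φ((τ_{k−1}−μ_g)/σ_g)`. Location
deviations are uniform DIF; discrimination is reported as proportional to
1/σ_g, so a large σ_g means the item separates latent levels poorly.
Estimation maximizes the multinomial log-likelihood minus a group-size-
weighted ridge `penalty·Σ_g n_g(μ_g² + log²σ_g)/n` on the deviations, via
L-BFGS-B on an unconstrained parameterization (first threshold plus log
threshold gaps; log σ). The exact penalty functional and
penalty-selection rule of published penalized-HETOP screens are not
available in their main texts; this ridge is an interpretation, and the
penalty path (warm-started over an increasing grid) is the primary
diagnostic rather than any single fit. A vanishing additional ridge
(1e-7) removes the location/scale indeterminacy at penalty zero; after
convergence the size-weighted means of μ_g and log σ_g are centered to
zero, a pure reparameterization.

Standard errors come from the observed information of the penalized
objective, propagated through the centering transform by the delta
method — centering annihilates the weakly identified common
location/scale direction, without which raw-parameter SEs would be
meaninglessly inflated. They are approximate (penalized, not sampling-
exact), flagged as such, and empirically calibrated on null fixtures in
the test suite. DIF flags compare |μ_g| (and |log σ_g|) to a z-threshold
times these SEs at a reference penalty. Because identification is
relative to the size-weighted center, one strongly shifted group also
moves every other group's deviation slightly; with many groups the
displacement is small, but flags should be read jointly with the
deviation magnitudes. With K = 3 categories and two groups the
unpenalized model is a reparameterization of the saturated multinomial,
which the tests exploit as an exact oracle.

## Synthetic cohorts

The generator emulates the *structure* of a multinational two-wave
flourishing panel, not any country's actual marginals: ~23 countries
(default 2000 respondents each), 4 strata per country with sampling
fractions spread over 0.05–0.5 (weights are true inverse inclusion
probabilities, giving the design variance a ground truth), 6 PSUs per
stratum, country effects θ_i drawn from N(μ=0.2, τ=0.09²), a
four-category exposure item cut from a latent normal at a 70%
often/always prevalence, and 79 confounders generated from 5 latent
factors with communality 0.45 — chosen so the first seven principal
components capture 40–60% of correlation variance, making the PC
reduction meaningful. Continuous outcomes are built with unit population
variance (the residual SD solves `1 = var(effect) + var(covariates) +
σ²`), so the standardized exposure contrast equals θ_i by construction;
they are then mapped to a 0–10 scale (mean 5, SD 1.4) with clipping
affecting well under 0.1% of draws. Binary outcomes use a log-link
Bernoulli model with base risk 0.2 and log-RR θ_i, with the linear
predictor clipped at log(0.95); a model that would clip more than 20% of
respondents is rejected as infeasible, naming the outcome. The ordinal
item is drawn from the same heteroskedastic ordered-probit measurement
model the DIF module fits, from a stored latent, so injected DIF shifts
are exactly recoverable in the model's own parameterization.

Attrition is logistic in standardized Wave-1 covariates with per-country
intercepts solved by root-finding so expected retention spans the target
range (default 0.23–0.90, matching the span seen in real multinational
panels); realized retention is within ±3 points of target for n ≥ 1000.
Item missingness is MCAR at a configurable rate on the exposure item,
confounders, and (among the retained) Wave-2 outcomes. Everything drawn
is recorded in a JSON-serializable truth record.

Not emulated: real per-country response distributions, translation or
mode effects, MNAR attrition, within-household clustering beyond the PSU,
and item-level missingness that depends on content. Passing tests
therefore certify the estimators under a correctly specified, MAR world
— they say nothing about robustness to misspecification beyond what the
sensitivity modules themselves quantify.

## Problem sizes in the test suite

Simulation-based tests use sizes chosen to make their Monte Carlo bands
decisive: end-to-end recovery runs 60 seeds of the full 23×2000 condition
(the 2-MC-SE criterion scales with the seed count); the cluster bootstrap
oracle uses 1000 replicates on a 2-stratum, 60-PSU fixture; null
calibration of the omnibus test uses 2000 direct fixtures; MI coverage
uses 400 replicates at n = 300, m = 10; HETOP power uses 40 seeds at
n = 2000 per group. Seeds are fixed throughout; `hypothesis` property
tests run derandomized.

## Known limitations

- The design variance supports one clustering stage (PSU within stratum);
  replicate-weight methods (BRR, jackknife) are not implemented.
- Imputation is single-level within country; no congenial joint model.
- The HETOP penalty is a ridge interpretation; its formal inferential
  properties (and those of any penalized DIF screen of this kind) are
  unknown, and the SEs are approximate.
- The E-value calibration treats the benchmark as binary and
  unconditional; conditioning on the full covariate set is left to the
  caller.
- `pm_random_effects` assumes independent country estimates; outcomes
  analyzed jointly share respondents, and no cross-outcome dependence is
  modeled.
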