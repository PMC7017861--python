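# Methods

## Model

A site in year t occupies one of three mutually exclusive latent states:
m = 0 (dry), m = 1 (wet without breeding), m = 2 (wet with breeding).
The initial distribution uses the conditional parameterization
φ₀ = [1−ψ, ψ(1−R), ψR], where ψ is the probability of holding water in the
first study year and R the probability of supporting breeding given wet.
Transitions from state m into year t+1 are parameterized by ψ^m(t)
(probability of being wet in t+1) and R^m(t) (probability of breeding in t+1
given wet in t+1), giving the row-stochastic matrix row
[1−ψ^m, ψ^m(1−R^m), ψ^m R^m]. Detection is state-dependent: water detection
is perfect (an observed dry site is truly dry, and a site-year can never mix
dry and wet observations), while breeding evidence at a state-2 site is
detected by each of the S replicate surveys independently with common
probability δ; false positives are not modelled. A year's observation
likelihood vector over the three states is therefore an indicator for states
0 and 1 and δ^{n₂}(1−δ)^{n₁} for state 2 (n₂, n₁ = surveys recording
breeding / wet-only); a year with no surveys contributes [1, 1, 1], which
encodes the assumption that unvisited sites share the transition model of
visited ones.

The site likelihood is the exact HMM marginal: α₁ = φ₀ ∘ D₁,
α_{t+1} = (α_t Φ_t) ∘ D_{t+1}, L = Σ α_T, computed with per-step rescaling so
a 10-year, several-hundred-site dataset never underflows. φ₀ applies at the
study's first calendar year; sites entering later are marginalized through
their missing years rather than conditioned on first detection.

## Linear predictors and parameter counting

All probabilities use the logit link. A model structure names one sub-model
per component in the grammar documented in `wetstate.model_spec`:

* ψ/R components: a partition of the prior state ({0},{1},{2}; {0},{1,2};
  {0,1},{2}), an optional year term `t`, and covariate terms. With `t` the
  component gets one intercept per (state-group × interval) plus one slope
  per (state-group × covariate) shared across years; without `t`, one
  intercept per state-group. Product terms (`RO*depth`) add one slope per
  state-group.
* δ: one intercept per year (with `t`) or a single intercept, plus one slope
  per covariate shared across years.
* Two further coefficients are always present: the scalar initial-year
  logit ψ and logit R (the initial state is not covariate-structured).

Total K = 2 + ψ columns + R columns + δ columns. These semantics are the
unique reading consistent with every published parameter count in the
source tables (e.g. 67 = 2 + 27 + 27 + 11 at T = 10), and the test suite
locks all fifteen printed counts.

Continuous covariates are standardized to zero mean and unit variance over
the records on which they enter the design (transition rows use the target
year t+1 for current-year covariates, hence the year-t value for one-year
lags; δ rows use the survey year). Fitted probabilities, deviance and AICc
are invariant to this affine choice (tested); standardization only
conditions the optimization. Decade-average covariates (`Precipave`,
`Vegave`, ...) are per-site means over years; depth is the ordinal
maximum-depth class 1–4 treated as a single numeric covariate, which is what
the published parameter counts imply.

## Estimation

The deviance −2 log L is minimized by L-BFGS-B over the coefficient vector,
restarted from `n_starts` jittered initializations (default 5; N(0, 0.5²)
jitter around zero logits, seeded). The gradient is analytic: a scaled
backward pass gives ∂log L/∂Φ_t[i,j] = α̂_t[i] D_{t+1}[j] β̂_{t+1}[j]/c_{t+1},
which is chained through the transition-row and logit derivatives into the
design tensors. This makes a K = 55, 500-site fit take well under a second,
and the gradient is verified against central finite differences in the
tests. The coefficient covariance is the inverse numerical Hessian obtained
as the (symmetrized) Jacobian of the analytic gradient. Coefficients with
|logit| > 10 are flagged as boundary estimates; their SEs — and delta-method
SEs computed through them — are marked unreliable, and non-converged fits
are excluded from model averaging by default.

Objective tolerance is 1e−8 (L-BFGS-B `ftol`), gradient tolerance 1e−6.
Degenerate inputs behave predictably: an all-dry dataset drives the initial
logit ψ to the boundary and is flagged; a parameter region assigning an
observed history zero probability returns −∞ log-likelihood and the
optimizer steps away from it.

## Model selection and averaging

AICc = deviance + 2K + 2K(K+1)/(n_eff − K − 1). The effective sample size
defaults to the number of completed site visits (site-years with ≥ 1
survey); this is the value (2,910 in the motivating study) that reproduces
the published AICc − deviance − 2K residuals. Akaike weights are normalized
exp(−ΔAICc/2); ties are broken by smaller K, then name. When the top weight
is ≤ 0.90, estimates are model averaged on the real (probability) scale —
structures differ, so coefficients are not averaged — with unconditional SE
√Σ wᵢ[varᵢ + (θ̂ᵢ − θ̄)²]. Published weight columns are reproduced with
largest-remainder rounding (floor at the printed precision, then assign the
remaining units to the largest remainders so the column sums to 1.00), which
is the convention the printed tables follow.

The three-stage workflow mirrors standard practice for this model family:
select δ under fully year- and state-specific ψ^m(t), R^m(t); select the ψ
structure holding the best δ; select the R structure holding both winners.

## Derived quantities

Annual state distributions propagate π₁ = φ₀, π_{t+1} = π_t Φ_t per site with
that site's covariates and average over sites (a representative-site option
evaluates the recursion at site-averaged transition probabilities instead).
SEs use the delta method through the full coefficient covariance, with the
Jacobian of the derived series computed by central finite differences
(step 1e−5·max(1,|β|)); a parametric bootstrap over the coefficient sampling
distribution is provided as a cross-check and agrees within 15% on
interior-parameter fits (tested; near-boundary coefficients void the
linearization, which is why such fits are flagged). Confidence intervals for
probabilities are normal on the logit scale and back-transformed, so they
always lie in [0, 1].

## Synthetic-data generator

The generator emulates the motivating study's shape: 290 sites × 10 years ×
2 surveys by default, 5% of site-years missing completely at random (an
optional late-entry pattern mimics catchments added mid-study), climate
covariates built as year effect + site effect + noise on a standardized
anomaly scale and mapped to plausible mm values (April–June precipitation
~220 ± 60 mm, April–June evapotranspiration ~170 ± 30 mm, annual runoff
~400 ± 110 mm), logistic-normal vegetation cover in [0, 100], and a
multinomial depth class. Wet years sit at year indices 2 and 5 and dry years
at 1 and 9, matching the 2008/2011 vs 2007/2015 pattern of the study decade.

`study_like_config()` sets the default truth to the study's top structure
family — ψ^m(Precipave+t), R^m(evap+depth+veg), δ(Vegave+t) — with
coefficients chosen once to realize the reported magnitudes: detection ≈ 0.8
with a markedly lower year 5 (≈ 0.6), breeding persistence R² ≈ 0.9, water
retention at occupied sites ψ² ≈ 0.95, climate-driven colonization R⁰
spanning ≈ 0.1–0.5 between dry and wet years, and an annual proportion of
dry wetlands ranging ≈ 3–30%. Truth coefficients are applied to the same
standardized design the fitting code builds, so real-scale recovery targets
(inverse-logit intercepts, initial ψ and R) are exactly comparable between
truth and fit.

What the generator deliberately omits — and what passing tests therefore do
not establish about real data: spatial autocorrelation among neighbouring
wetlands, observer heterogeneity and survey-specific detection, non-random
missingness tied to site condition, covariate measurement error, and any
selection effect from monitoring only sites known to have held water. The
recovery results show the estimator is correct under the model, not that the
model is correct for a given landscape.

## Problem sizes used in the checks

Parameter recovery runs 50 replicates at 500 sites × 10 years (enough for
Monte-Carlo SEs a few times smaller than the parameter SDs); selection
consistency runs 20 replicates at 1,000 sites over a four-candidate
detection set with the generating structure included; the forward/enumeration
oracle comparison uses ≥ 1,000 random instances with T ≤ 6 (3^T path
enumeration). The acceptance script uses slightly smaller replicate counts
for the same experiments and reports the measured values.

## Known limitations

* No goodness-of-fit or overdispersion (ĉ) machinery; AICc comparisons
  assume the model family is adequate.
* No Bayesian estimation; uncertainty is Wald/delta-method and degrades for
  boundary estimates (flagged rather than repaired).
* The multi-year-drought extension (several consecutive-dry-year states) is
  out of scope.
* Climate covariates are consumed as given; no gridded-data extraction or
  water-balance modelling.
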