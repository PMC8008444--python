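# Methods

This note documents the models, algorithms and numerical choices behind
`growthdesign`, and what the synthetic test conditions do and do not
establish about real data.

## 1. The BCCG distribution and centile precision

All distributional work uses the three-parameter Box-Cox Cole–Green
(BCCG) family, the distribution underlying the LMS method: median μ > 0,
generalised CV σ > 0 and Box-Cox power ν, with the z-score and centile
transforms given in the README.  The density is the normal density of
the z-score times the Jacobian y^(ν−1)/(μ^ν σ); the y > 0 truncation
correction is ignored, as is standard — its mass is negligible for the
σ·|ν| values seen in anthropometry (σ ≤ 0.2, |ν| ≤ 2).  The transforms
are computed through `log1p`/`expm1`, so they remain accurate as ν → 0
and join the lognormal branch continuously.

Single-age-group precision uses the normal-theory results: the SE of the
100α'th centile in z-score units is SE_z = √((1+z_α²/2)/n), independent
of μ and σ, with inverse n = (1+z_α²/2)/SE_z².  These are exact for the
two-parameter (μ, σ) normal model in which the centile is estimated as
mean + z·SD.  One consequence worth flagging: when the skewness ν is
*estimated* rather than known, the bootstrap SE of outer centiles
exceeds the normal-theory value (the z = ±2 to median SE ratio comes out
near 2.0 rather than √3 ≈ 1.73 in our single-age experiments).  Tests
that check the normal-theory limit therefore hold ν fixed at its normal
value (ν = 1), via `FitConfig(nu_value=...)` — the analogue of
`nu.fix = TRUE` in GAMLSS practice.

Conventional rounded centiles are used throughout: z = ±2 is called the
"2nd/98th" centile (exactly 2.28/97.72%), z = ±2.67 the "0.4th/99.6th".

## 2. Base models and synthetic fixtures

A base model (`MomentCurveSet`) is a triple of smooth curves μ(t), σ(t),
ν(t) over an age domain, evaluable anywhere inside it and never
extrapolated.  Models can be exchanged as standard LMS tables (CSV with
columns age, L, M, S, where L = ν, M = μ, S = σ); rows are interpolated
with monotone (PCHIP) cubics, because linear interpolation kinks the
centiles and unconstrained cubics can overshoot into M ≤ 0.  Tables are
written with 6 significant digits.

Four deterministic fixtures on [0, 20] years emulate the qualitative
shape of boys' references (no numerical claim to any published table):

| fixture  | median μ(t)                                   | CV σ(t)                                  | skewness ν(t)             |
|----------|-----------------------------------------------|------------------------------------------|---------------------------|
| height   | 51 + 27.5·t^0.50 + 5·logistic(13, 0.9)        | 0.037 + 0.008·e^(−t/3)                   | 1 − 0.02t                 |
| weight   | 3.5 + 7·t^0.70 + 2.5·logistic(13, 1.2)        | pchip: hump in infancy, dip, pubertal rise | pchip: +0.2 → −0.45 → −0.35 |
| bmi      | 13.2 + 2.5·t^0.31                             | 0.08 + 0.05·t/20                         | −0.3 − 1.0·t/20           |
| headcirc | 35 + 7.3·t^0.31                               | 0.031 − 0.004·t/20                       | 1 − 0.5·t/20              |

The dominant μ term is linear on an age^p scale, so each fixture's
median is closest to linear (least-squares curvature over a λ grid) near
the age power typical of its measurement: ≈0.76 weight, ≈0.56 height,
0.31 BMI and head circumference.  The weight CV uses anchor-point
interpolation because its *shape* matters for design: σ(t) divides the
SE_z curve, so an unrealistic monotone CV visibly shifts the
flat-composition λ.  A mild pubertal inflection is included for height
and weight only.

What the fixtures do not emulate: measurement error, digit preference,
sampling bias, kurtosis (heavy tails), seasonal effects, or sex
differences.  Passing tests therefore show that the *machinery* is
correct and calibrated under a BCCG world; they do not validate any
particular population's reference values.

## 3. Sample composition

Measurement ages are sampled uniformly on the age^λ scale, 0 < λ ≤ 1:
u ~ U(a^λ, b^λ), t = u^(1/λ), giving CDF (t^λ − a^λ)/(b^λ − a^λ).
λ = 1 is uniform; smaller λ over-samples infancy, where growth is
fastest and centiles are least precise.  a = 0 is handled exactly
(0^λ = 0).

For survey work the continuous composition is discretised into age
groups (`nagegp`): counts proportional to the group measure
b_i^λ − a_i^λ, integerised by largest-remainder rounding so they sum
exactly to n (the rounding rule is our choice; any total-preserving rule
would do).  Edge groups can be inflated by multipliers (≥ 1) applied
before renormalisation — a documented convention for counteracting
edge effects, for which no standard formula exists.  Within groups, ages
are uniform.  A 27-group "Cuban-style" plan (infant 4-month groups,
pubertal over-sampling bump) ships as an illustrative fixture; the
historical per-group targets are not public, so its counts are a
synthetic stand-in shape.

Datasets are simulated by drawing a uniform proportion per age and
pushing it through the base model's centile transform, so
generating-model z-scores are standard normal by construction.

## 4. Penalized BCCG fitting

The fitter estimates μ(t), σ(t), ν(t) by cyclic penalized IRLS
(RS-type backfitting):

* **Bases.**  Cubic B-splines with 20 equally spaced segments (basis
  dimension 23) and a 2nd-order difference penalty on the coefficients;
  alternatively `linear` or `constant` designs per moment.
* **Links.**  Identity for μ (with positivity safeguarding), log for σ,
  identity for ν.
* **Scores and weights.**  Analytic first derivatives of the BCCG
  log-likelihood with the standard approximate expected information:
  w_μ = (1+2σ²ν²)/(μ²σ²), w_logσ = 2, w_ν = 7σ²/4.
* **Updates.**  Each moment takes one penalized weighted least-squares
  step on the working response; step-halving guarantees the penalized
  log-likelihood never decreases at fixed smoothing.
* **Smoothing.**  Schall-type marginal-likelihood ratio updates per
  cycle (damped to a factor 10 per cycle), frozen once both the
  objective and the smoothing parameters stabilise; coefficients are
  then polished to a relative deviance change < 1e−6 (50-cycle cap,
  explicit non-convergence error).  `smoothing_selection="bic-grid"`
  additionally refines the μ and σ smoothing parameters over a
  ×(0.1…10) grid by full refits, keeping the BIC-best.
* **Degenerate input.**  Zero age spread falls back to constant curves
  (single-age-group mode); fewer than 50 observations is an error.

The ν curve class is selected among constant/linear/smooth by GAIC(3)
(ties broken toward fewer edf), mirroring the practice of keeping the
skewness curve as simple as the data allow; ν can instead be held at a
known value.  Model comparison uses BIC = −2ℓ + log(n)·edf and
GAIC(k) = −2ℓ + k·edf with edf the trace of the penalized hat matrix.

**Age-power hyperparameter ξ.**  The μ curve may be fitted against
age^ξ, 0 < ξ ≤ 1, which straightens the steep infancy rise; σ and ν are
always fitted against untransformed age, where transformation buys
little.  `select_xi` golden-sections ξ over (0.05, 1] minimising GAIC(3)
at approximately constant μ edf: a reference fit at ξ = 1 fixes a target
edf, and at each candidate the μ smoothing parameter is first solved (by
bisection on the hat-matrix trace, holding the reference weights) to hit
that target.  The result is reported to 2 decimals and never worse than
ξ = 1 by construction.  The lower limit 0.05 excludes the log-age
boundary for numerical range reasons.

**Median SE band.**  The SE of μ̂(t) comes from the sandwich covariance
A⁻¹(XᵀWX)A⁻¹ of the penalized system, and is converted to z-score units
by dividing by the fitted generalised SD μ̂(t)σ̂(t).  In the
single-age-group limit with ν fixed this reproduces 1/√n.

## 5. Bootstrap SE_z curves

For centiles other than the median: resample the dataset's rows with
replacement (unstratified by default, matching the plain bootstrap;
stratified-by-age-group resampling is available as an option), refit,
evaluate the requested centiles on a 0.1-year grid, convert them to
z-scores **under the original fit's moment curves**, and take the SD
over replicates.  Default B = 500; replicates that fail to converge are
skipped (more than 10% skipped is an error).  Refits hold the base
fit's hyperparameters fixed — knots, curve classes, smoothing parameters
and ξ — and warm-start from its coefficients.  Re-selecting them per
replicate would multiply the cost ~20-fold, and fixed-model resampling
is the standard choice for SE (not model-uncertainty) bands; it is the
package's documented convention.

SE_z curves are summarised by OLS of log SE_z on age over 2–18 years
(age centred at 10 y) to avoid edge effects; the slope per year is the
design signal, and a flat trend is the optimum.

## 6. The design layer

The shipped `DEFAULT_DESIGN_MODEL` carries the reference meta-regression
coefficients (constant −3.088; log(1+z²/2) 0.537; λ −0.283; age 0.0231;
age:log(1+z²/2) 0.0205; age:λ −0.0604; age centred at 10 y), the
reference size n = 6878 and the scaling exponent 1.85.  They are
immutable defaults; `fit_design_model` refits the same regression to
user-supplied SE_z surfaces and returns a new model, never mutating the
defaults.  Derived quantities:

* λ\*(z) = (0.0231 + 0.0205·log(1+z²/2)) / 0.0604 — the flatness
  condition (the three age terms sum to zero); 0.38 for the median
  rising to 0.90 for z = ±2.67.  Values outside (0, 1] raise a
  design-infeasible error.
* SE_z(z, λ, n) = exp(b₀ + b_z·log(1+z²/2) + b_λ·λ) · (6878/n)^(1/1.85).
* required n = 6878·(SE_z(n_ref)/target)^1.85, rounded up
  (conservative).
* 95% CIs for a centile: 100·Φ(z ± 2·SE_z) — the multiplier is exactly
  2, not 1.96, following the source convention.  Centiles above the
  median follow by symmetry (100 minus the mirrored interval).

The scaling law is stated with 1.85 as an *exponent* (n ∝ SE_z^−1.85);
the equivalent "multiplier" phrasing sometimes seen is not algebraically
interchangeable, and the exponent reading is the one consistent with the
worked sample-size examples.

**flatten_lambda** runs the full loop — simulate at λ, fit, bootstrap
the target centile's SE_z, measure the 2–18 y slope — and locates the
zero crossing of slope(λ).  Two numerical points: (i) the dominant noise
in a measured slope is the simulated dataset itself, not the bootstrap
stream (SD ≈ 0.009 vs ≈ 0.001 per year at n = 6878, B = 100), so the
`reps` argument averages slopes over independent datasets; (ii) near the
optimum the slope surface is shallow, so the root is found by local
linear regression of slope on λ over a 5-point grid (global fit, then
refit on the 3 nearest evaluations, then one confirmation run) rather
than bisection, which a single noisy sign flip would derail.  The
default slope tolerance is 0.005/year; with B = 100 the achieved slope
is statistical, and λ\* carries an uncertainty of roughly ±0.05–0.1.

## 7. Problem sizes used by the packaged checks

The simulation-based tests run at the reference conditions scaled to
single-machine sizes, chosen once as the smallest sizes at which the
targeted effects are comfortably resolved: parameter recovery at
n = 7000; bootstrap validity on a 1000-subject single age group with
B = 400; the scaling-law experiment at n = 1720/6878/27512 with 3
datasets per size; the flatten-λ loop at n = 6878 with B = 100 and 3
datasets per λ on the weight fixture.  The scaling-law experiment holds
model complexity fixed across sizes (per-observation penalty constant,
so edf ≈ constant), which isolates the n-dependence of the SE; under
that protocol the empirical exponent is ≈ 2.0.  With smoothing
re-selected at every size the selected edf grows with n and the apparent
exponent rises to ≈ 2.5; exponents below 2 arise under smoothing
selectors that stiffen the fit as n grows, a behaviour this package's
Schall-type selector does not reproduce.

## 8. Known limitations

* The fitter's smoothing selection is Schall/marginal-likelihood with a
  BIC-grid option; exact edf agreement with other P-spline software is
  not promised, and quantities that depend on how edf scales with n
  (notably the empirical scaling exponent) inherit that sensitivity.
* ν is weakly identified; its fitted curve is noisy and its class
  selection (constant/linear/smooth) is data-driven.  Outer-centile SEs
  include this uncertainty.
* No kurtosis modelling: distributions with heavy tails will show lack
  of fit beyond roughly the 1st/99th centiles.
* Monotone-μ constrained fitting is not implemented (not needed for the
  simulation designs packaged here).
* Longitudinal/repeated-measures designs are out of scope; all results
  assume one measurement per subject.
* Design-model defaults were estimated at n = 6878 over 0–21 y; using
  them far outside that range (short age spans, tiny n) extrapolates
  both the meta-regression and the scaling law, and edge effects grow as
  the age range shrinks.
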