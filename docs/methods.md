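# Methods

`stagesurv` estimates long-term, stage-specific *marginal relative survival*
for cancer registry cohorts whose historical stage-at-diagnosis recording is
poor, and stress-tests how sensitive those estimates are to the treatment of
the missing historical stage. This note documents the statistical model, the
synthetic registry that stands in for restricted-access data, the numerical
choices, and the limits of what the test suite demonstrates.

## Estimands and model

**Relative survival.** For a cancer cohort, the all-cause hazard of subject
*i* is decomposed additively as `h_i(t) = h*_i(t) + lambda_i(t)`, where `h*`
is the expected (population) mortality rate read from a lifetable stratified
by sex, calendar year and single year of age, and `lambda` is the excess
(cancer-attributable) hazard. Relative survival
`R(t) = exp(-integral of lambda)` estimates net survival — survival in the
hypothetical world where the cancer is the only cause of death — without
needing cause-of-death information.

**Flexible parametric excess-hazard model.** One model is fitted per stage on
the log cumulative-excess-hazard scale:

    ln Lambda(t | x) = s0(ln t) + beta' x + sum_k s_k(ln t) x_k

* `s0`: restricted cubic spline, 5 df (6 knots at the 0/20/40/60/80/100
  centiles of the uncensored log event times);
* `x`: restricted cubic spline in age (4 df) plus a sex indicator; age is
  winsorised at its 2nd/98th percentiles before spline evaluation, making the
  age effect exactly constant in the sparse tails;
* `s_k`: time-dependent effects, 2 df per covariate, applied to a reduced
  2-df age spline and to sex.

The likelihood handles delayed entry (period analysis):
`l_i = d_i ln(h*_i(t1) + lambda_i(t1)) - Lambda_i(t1) + Lambda_i(t0)`, with
`lambda = Lambda * s'(ln t)/t` via the analytic spline derivative. Expected
rates at attained ages of 99+ reuse the age-99 rate; calendar years beyond
the lifetable reuse its last year.

**Period window and pre-window.** Estimation is restricted to person-time in
2015–2017 via left truncation at `t0 = max(0, window_start - dx_date)`, exit
at `min(own follow-up, end of window, 10 years)`. The pre-window (2012–2015)
marks the span of recent calendar time whose stage recording is assumed
reliable: strong assumptions about missing stage are confined to diagnoses
before it.

**Multiple imputation.** Missing stage is imputed from a 3-category
multinomial logistic model fitted to the complete-stage rows of the period
frame, with covariates sex, age (linear), subsite, grade (unknown as a
level), calendar year of diagnosis (categorical), the event indicator, the
Nelson–Aalen cumulative hazard H at exit, its time-weighted companion
`H1(t) = sum_{t_j<=t} t_j d(t_j)/n(t_j)`, and the four interactions of
sex/age with H/H1. Imputation is *proper*: for each of the m data sets a
coefficient vector is drawn from the multivariate-normal approximation to the
sampling distribution of the MLE before category probabilities are computed.
H and H1 are computed on the delayed-entry risk sets of the period frame
(`Y(t) = 1{t0 < t <= t1}`); an option recomputes them on full follow-up for
sensitivity. m = 30 by default.

**Stress conditions.** With B the pre-window start (or the period-window
start when the pre-window is off), missing-stage subjects diagnosed before B
are (1) imputed as usual, (2) dropped, (3) assigned localised, or
(4) assigned distant; subjects diagnosed on/after B are always imputed.

**Standardisation and pooling.** Marginal relative survival averages the
conditional predictions over the empirical joint (age, sex) rows of all
subjects diagnosed in 2017, the same standard population for every stage so
curves are comparable. The marginal excess hazard is the survivor-weighted
average `sum w_i R_i lambda_i / sum w_i R_i`, which satisfies
`lbar = -(d/dt) ln Rbar`. Pointwise variances come from numerically
differentiating the standardised functional with respect to the model
coefficients and sandwiching with the coefficient covariance (inverse
observed information, itself obtained by finite differences of the analytic
gradient). Across imputations, curves are pooled with Rubin's rules on the
complementary log-log scale `g = ln(-ln R)` — total variance
`T = W + (1 + 1/m)B` — which keeps back-transformed confidence limits inside
[0, 1]. An identity-scale option exists for sensitivity.

**Pohar–Perme check.** As a model-free reference, net survival is estimated
with inverse-expected-survival weights `w_i(t) = 1/S*_i(t)` and delayed
entry, within the five ICSS age bands (<45, 45–54, 55–64, 65–74, 75+;
half-open, 45 belongs to 45–54), standardised with internal weights (the
ICSS distribution of the 2017 diagnoses). The expected-hazard correction
integral is accumulated on a configurable partition (daily by default; exact
when steps do not straddle age/year lattice boundaries, and in the null
lifetable case the estimator reduces *exactly* to `exp(-Nelson-Aalen)` on the
same risk sets).

## Synthetic registry generator

The generator emulates a 2005–2017 colon-cancer-like registry with known
truth so every estimator can be scored without restricted data:

* true stage mix 40.0/36.5/23.5% localised/regional/distant, sex 51% female,
  per-stage truncated-normal ages (means 68.3/68.6/66.8, sd ~14);
* excess-event times from per-stage Weibull hazards with shape < 1 (excess
  mortality front-loaded after diagnosis), proportional effects of age
  (+0.025 per year, centred at 70) and sex (-0.10 for women) on the excess
  hazard. Shapes and scales are calibrated so the baseline net survival at
  1 and 10 years tracks colon-like stage-specific relative survival:
  0.97/0.92 (localised, shape 0.45), 0.88/0.70 (regional, 0.45), 0.51/0.12
  (distant, 0.50);
* population death times sampled exactly from the lifetable's hazard taken
  piecewise constant on whole years since diagnosis; the latent death time is
  the minimum of the two components (additive hazards), followed by
  administrative censoring at 2017-12-31;
* grade strongly associated with true stage and subsite weakly so (declared
  conditional distributions, not estimates) so the imputation model has
  signal; ~3.5–4% baseline missing stage via a logistic-in-age draw, making
  missing-stage subjects older on average;
* the *injected* missingness mechanism is stage- and calendar-conditional:
  35% of regional diagnoses in 2011, +5 pp per earlier year (65% by 2005),
  distant +7 pp and localised −7 pp, and a flat 20% for 2012–2017
  irrespective of stage. Already-missing rows are never redrawn; true stage
  is always retained.

The default lifetable is a Gompertz form `rate = 1e-4 * exp(0.09 * age)`
(male rates 1.5x female), which matches general-population adult mortality to
the right order of magnitude.

What the generator does **not** emulate: cure-fraction plateaus (a single
Weibull cannot be front-loaded *and* flat at 8–10 years simultaneously),
month-resolution follow-up ties, subsite-specific biology, socio-economic or
regional structure, and real secular survival trends. Passing tests
therefore demonstrate internal correctness and the qualitative robustness
mechanism, not agreement with any particular registry's published figures.

## Numerical choices

* Spline basis: truncated-power restricted cubic basis with the
  `(k_max - k_min)^2` normalisation; analytic derivative; linear beyond the
  boundary knots by construction.
* Optimisation: L-BFGS-B with the analytic gradient from a null-model start
  (baseline spline regressed on the log Nelson–Aalen cumulative hazard),
  followed by a full-memory BFGS polish (gradient tolerance 1e-5). Design
  columns are centred (orthogonalised against the constant) during
  optimisation; coefficients are reported in the original basis.
* Overflow guard: `exp(eta)` is extended quadratically above eta = 50 so
  line searches cannot produce non-finite values; the extension is smooth and
  strictly increasing, so it only ever pushes the optimiser back.
* Total-hazard floor: `ln(h* + lambda)` is floored at 1e-10; if any *event*
  sits on the floor at convergence the fit is flagged unreliable.
* Lifetable cells are half-open `[a, a+1) x [y, y+1)` with floor mapping of
  fractional ages/years; the cumulative expected hazard integrates the exact
  cell crossings of the demographic diagonal.
* Ties: deaths at identical times are processed together; censorings at an
  event time leave the risk set after the event.
* Sub-seeds are derived by hashing (master seed, stage name) so adding a
  pipeline stage never perturbs earlier stages' draws; all seeds stay below
  2^31.

## Problem sizes used by the test suite

Chosen as this package's own simulation design: unit tests run on cohorts of
200–20,000 subjects; coverage of the generator truth is assessed over 20
replicates at n = 20,000 with m = 10 imputations; the condition-robustness
experiment runs once at registry scale (n = 100,000) with m = 5, where
Monte-Carlo noise in the 10-year estimates is a fraction of the effects being
tested for the regional and distant stages.

## Design choices where the design was open

* "30 iterations" of imputation is read as m = 30 imputed data sets (Rubin's
  rules operate across data sets).
* The uniform 20 pp for 2012–2017 is an absolute probability, not an
  addition to the pre-2012 formula (the recent mechanism is explicitly
  unconditional on stage and year). The stated ±7 pp stage offsets are taken
  as authoritative where quoted percentages conflict, since they reproduce
  every other stated value (65, 72, 28).
* Removal is Bernoulli per subject; an exact-count mode per
  (stage, year) cell is available.
* Age enters the imputation model linearly; the event indicator enters as a
  0/1 contrast; calendar year with all levels.
* Standardisation uses the joint (age, sex) 2017 rows; an age-only option
  marginalises sex at the 2017 sex mix.
* Pooling on the cloglog scale by default, identity as an option.
* Pohar–Perme uses continuous-time estimation with internal 2017 ICSS
  weights, not the published ICSS reference weights.

## Known limitations

* The localised stage's long-term excess hazard is an order of magnitude
  smaller than the background mortality of elderly subjects, so its 10-year
  estimates are weakly identified: point estimates swing by several
  percentage points between realisations while the delta-method/Rubin
  intervals remain honest (coverage is checked, point agreement is not
  guaranteed). This weak identification is a property of excess-hazard
  estimation for good-prognosis strata, not an implementation artefact.
* When a stage model is fitted to heavily contaminated data (condition 4's
  "assign everyone distant"), the single-stage spline model is misspecified
  — the data are a mixture of two proportional-hazards groups — and the
  fitted age profile can flatten, partially offsetting the expected inflation
  of the age-standardised 10-year estimate. The direction and size of the
  net effect then varies between data realisations; see the decisions the
  acceptance tests encode.
* Negative fitted excess hazards are possible (and flagged), as in any
  unconstrained excess-hazard spline model.
* No cure models, no loss-of-life-expectancy measures, no Ederer/Hakulinen
  comparators, no 5-year abridged lifetables, no MNAR sensitivity models.
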