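# stagesurv

Long-term, stage-specific relative survival for cancer registries whose
**historical stage at diagnosis is largely missing** — and a test bench for
how much the answer depends on what you assume about that missing stage.

## The problem

Cancer registries often recorded stage poorly in the past and well recently.
Long-term (10-year) stage-specific survival estimates need the old data, so
the usual fix is a *period analysis* — only person-time inside a recent
calendar window (2015–2017) contributes, with delayed entry at
`t0 = max(0, window_start − diagnosis date)` — combined with *multiple
imputation* of the missing historical stage. Because stage differences in
excess mortality are concentrated shortly after diagnosis, and a period
analysis takes its short-term information only from recently diagnosed
(well-staged) patients, the resulting estimates should be insensitive to how
the historical stage is imputed. This package implements that whole pipeline
and verifies the insensitivity claim on synthetic registries with known
truth.

## What is inside

| module | contents |
| --- | --- |
| `stagesurv.lifetable` | population expected-mortality rates by sex × year × age 0–99, age-99 carry-over, exact diagonal cumulative hazard, CSV I/O, Gompertz synthesiser |
| `stagesurv.cohort` | synthetic SEER-like registry generator: additive Weibull excess + lifetable background hazards, stage/grade/subsite covariates, known truth retained |
| `stagesurv.missingness` | the calendar- and stage-conditional stage-removal mechanism (35% regional 2011, +5 pp per earlier year, ±7 pp by stage, flat 20% for 2012–2017) |
| `stagesurv.period` | period-analysis frame: delayed entry, 10-year cap, pre-window era labels |
| `stagesurv.imputation` | Nelson–Aalen `H` and time-weighted `H1` risk-set statistics, the multinomial `StageImputer` (proper MI, m = 30), the four stress conditions |
| `stagesurv.fpm` | `ExcessHazardModel`: flexible parametric (restricted-cubic-spline) excess-hazard model on the log cumulative-hazard scale, 5 df baseline, 4 df age, 2 df time-dependent effects, delayed entry, analytic gradient |
| `stagesurv.marginal` | age-standardisation to the 2017 diagnosis distribution, delta-method variances, Rubin's-rules pooling on the cloglog scale |
| `stagesurv.pohar_perme` | Pohar–Perme net survival with ICSS age-standardisation — the model-free cross-check |
| `stagesurv.pipeline` / `stagesurv.cli` | one-command experiments: simulate → mask → period → impute per condition → fit per stage → standardise → pool → compare to truth |

The model core is written as scikit-learn-style estimators
(`ExcessHazardModel`, `StageImputer`, `PoharPerme`: `fit`/`transform`/
`predict`, `get_params`, fitted attributes with trailing underscores).

## Worked example

```python
import numpy as np
import stagesurv as sg

lt = sg.synth_lifetable()                                  # Gompertz background mortality
spec = sg.CohortSpec(n=20_000, seed=11)
cohort = sg.generate_cohort(spec, lt)                      # registry with known truth
masked = sg.apply_missingness(cohort, sg.MissingnessSpec(seed=12))
frame = sg.apply_period(masked)                            # delayed entry into 2015-2017

# impute missing stage (condition 1: impute everyone), fit the distant-stage
# model per imputation, standardise to the 2017 age/sex mix, pool
sp = sg.build_standard_population(cohort, year=2017)
frames = sg.complete_frames(frame, sg.ConditionSpec(1, True), sg.PeriodSpec(),
                            m=10, random_state=13)
curves = []
for fr in frames:
    model = sg.ExcessHazardModel().fit(fr[fr["stage"] == "distant"], lt)
    curves.append(sg.marginal_rs(model, sp, [1.0, 5.0, 10.0]))
pooled = sg.rubin_combine(curves)
lo, hi = pooled.ci()
for t, est, l, h in zip(pooled.t, pooled.estimate, lo, hi):
    truth = sg.true_net_survival(spec, "distant", t, sp.age, sp.female)
    print(f"t={t:4.0f}y  RS={est:.3f}  95% CI [{l:.3f}, {h:.3f}]  truth={truth:.3f}")
```

prints

```
t=   1y  RS=0.573  95% CI [0.540, 0.604]  truth=0.547
t=   5y  RS=0.279  95% CI [0.245, 0.315]  truth=0.274
t=  10y  RS=0.133  95% CI [0.101, 0.170]  truth=0.169
```

The pooled 10-year marginal relative survival of distant-stage patients is
13.3% (CI 10.1–17.0%), against a generator truth of 16.9% — the 1- and
5-year values are recovered tightly and the 10-year value within its (wide)
interval, even though roughly a third of the period cohort had its stage
masked. The same numbers for the model-free route:

```python
pp = sg.pohar_perme(frame[frame["stage_true"] == "distant"], lt, tgrid=(1, 5, 10))
print(np.round(pp.standardised, 3))   # [0.572 0.266 0.14 ]
```

A full stress-test over all four imputation conditions, with and without the
pre-window, is one call (or `stagesurv run-all --seed 1 --outdir out/` from
the shell):

```python
res = sg.run_experiment(sg.ExperimentConfig(cohort=spec, m=10, seed=1))
print(res.summary_frame())             # estimate/CI/truth per condition x stage x {1,5,10}y
print(sg.compare_to_truth(res))        # signed deviations from the truth-stage reference
```

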