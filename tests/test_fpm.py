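import warnings

import numpy as np
import pandas as pd
import pytest

import stagesurv as sg
from stagesurv.fpm import ExcessHazardModel, default_knots, rcs, rcs_deriv


def weibull_frame(n, shape, scale, seed=0, cens=(3.0, 13.0)):
    """All-cause Weibull data with uniform administrative censoring."""
    rng = np.random.default_rng(seed)
    te = scale * rng.exponential(size=n) ** (1 / shape)
    tc = rng.uniform(*cens, n)
    time = np.minimum(te, tc)
    return pd.DataFrame(
        {
            "t0": 0.0,
            "t1": time,
            "d": (te <= tc).astype(int),
            "age_at_dx": 70.0,
            "sex": "male",
            "dx_date": pd.Timestamp("2008-01-01"),
        }
    )


class TestSplineBasis:
    def test_two_knots_is_linear(self):
        x = np.linspace(-2, 3, 50)
        B = rcs(x, [0.0, 1.0])
        assert B.shape == (50, 1)
        np.testing.assert_allclose(B[:, 0], x)

    def test_linear_beyond_boundary_knots(self):
        knots = np.array([0.0, 0.7, 1.3, 2.0])
        for x0 in (2.5, 4.0, -1.0):
            # second differences vanish outside the boundary
            xs = np.array([x0 - 0.01, x0, x0 + 0.01])
            B = rcs(xs, knots)
            second = B[0] - 2 * B[1] + B[2]
            np.testing.assert_allclose(second, 0.0, atol=1e-9)

    def test_derivative_matches_finite_differences(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            knots = np.sort(rng.uniform(-1, 2, size=rng.integers(2, 7)))
            if np.min(np.diff(knots)) < 1e-3:
                continue
            x = rng.uniform(-2, 3, size=30)
            h = 1e-6
            fd = (rcs(x + h, knots) - rcs(x - h, knots)) / (2 * h)
            np.testing.assert_allclose(rcs_deriv(x, knots), fd, atol=1e-6)

    def test_non_increasing_knots_rejected(self):
        with pytest.raises(ValueError):
            rcs(np.array([0.5]), [1.0, 1.0, 2.0])


class TestDefaultKnots:
    def test_df1_boundary_only(self):
        t = np.exp(np.linspace(-1, 1, 100))
        knots = default_knots(t, 1)
        np.testing.assert_allclose(knots, [np.log(t.min()), np.log(t.max())])

    def test_df2_median_interior(self):
        rng = np.random.default_rng(0)
        t = rng.lognormal(size=501)
        knots = default_knots(t, 2)
        assert knots[1] == pytest.approx(np.median(np.log(t)))

    def test_df5_centiles_match_quantile_oracle(self):
        rng = np.random.default_rng(1)
        t = rng.weibull(0.8, size=1000)
        knots = default_knots(t, 5)
        logt = np.log(t[t > 0])
        want = np.quantile(logt, [0, 0.2, 0.4, 0.6, 0.8, 1.0])
        np.testing.assert_allclose(knots, want)

    def test_too_few_event_times(self):
        with pytest.raises(ValueError, match="distinct"):
            default_knots([1.0, 1.0, 2.0], 5)


class TestFitting:
    def test_weibull_shape_recovery_null_expected_hazard(self, null_lifetable):
        """With no background mortality the log cumulative hazard is linear in
        log time; the fitted slope matches the Weibull shape within 3 SE."""
        a, b = 0.7, 8.0
        frame = weibull_frame(10_000, a, b, seed=11)
        model = ExcessHazardModel(include_age=False, include_sex=False, td_df=0).fit(frame, null_lifetable)
        # slope of eta in log t between interior quantiles, plus its SE
        t_lo, t_hi = 1.0, 5.0
        eta = np.log(model.predict_cumhaz(np.array([t_lo, t_hi]), 70.0, 0.0))
        slope = (eta[1] - eta[0]) / (np.log(t_hi) - np.log(t_lo))
        # delta-method SE of the slope from the coefficient covariance
        from stagesurv.fpm import rcs as _rcs

        D = (
            model._design(np.log(np.array([t_lo, t_hi])), np.array([70.0, 70.0]), np.array([0.0, 0.0]))[0]
        )
        c = (D[1] - D[0]) / (np.log(t_hi) - np.log(t_lo))
        se = float(np.sqrt(c @ model.cov_ @ c))
        assert slope == pytest.approx(a, abs=3 * se)
        assert se < 0.05

    def test_null_excess_fits_relative_survival_one(self, lifetable):
        """When the lifetable carries the whole hazard, fitted relative
        survival stays near 1 across the time range."""
        from stagesurv.cohort import STAGES, CohortSpec, WeibullExcess, generate_cohort

        spec = CohortSpec(n=15_000, seed=16, excess={s: WeibullExcess(shape=0.9, scale=1e9) for s in STAGES})
        cohort = generate_cohort(spec, lifetable)
        frame = cohort.assign(t0=0.0, t1=np.minimum(cohort["time"], 10.0), d=((cohort["event"] == 1) & (cohort["time"] <= 10)).astype(int))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = ExcessHazardModel().fit(frame, lifetable)
        R = model.predict_survival(np.array([1.0, 5.0, 10.0]), 70.0, 0.0)
        np.testing.assert_allclose(R, 1.0, atol=0.02)

    def test_synthetic_stage_recovery_within_mc_tolerance(self, lifetable):
        """Known Weibull excess + lifetable background: the 5-year marginal
        relative survival prediction lands within Monte-Carlo tolerance of the
        generating truth."""
        spec = sg.CohortSpec(n=20_000, seed=17)
        cohort = sg.generate_cohort(spec, lifetable)
        frame = cohort[cohort["stage_true"] == "distant"].assign(
            t0=0.0
        )
        frame = frame.assign(t1=np.minimum(frame["time"], 10.0), d=((frame["event"] == 1) & (frame["time"] <= 10)).astype(int))
        model = ExcessHazardModel().fit(frame, lifetable)
        sp = sg.build_standard_population(cohort)
        est = sg.marginal_rs(model, sp, [5.0])
        truth = sg.true_net_survival(spec, "distant", 5.0, sp.age, sp.female)
        assert est["estimate"][0] == pytest.approx(truth, abs=3 * np.sqrt(est["var"][0]) + 0.01)

    def test_loglik_not_below_initialisation(self, null_lifetable):
        frame = weibull_frame(2_000, 0.8, 5.0, seed=12)
        model = ExcessHazardModel(include_age=False, include_sex=False, td_df=0).fit(frame, null_lifetable)
        lik = model._build_likdata(frame, null_lifetable)
        theta0 = np.zeros(model.coef_.size)
        f0, _, _ = model._nll_grad(theta0, lik)
        assert model.loglik_ >= -f0

    def test_analytic_gradient_matches_numeric(self, lifetable):
        """Random parameter points on small data: analytic vs central FD."""
        cohort = sg.fixture_cohort(n=300, seed=31, lt=lifetable)
        frame = cohort.assign(t0=0.0, t1=cohort["time"].clip(upper=10), d=((cohort["event"] == 1) & (cohort["time"] <= 10)).astype(int))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = ExcessHazardModel(baseline_df=3, age_df=2).fit(frame, lifetable)
        lik = model._build_likdata(frame, lifetable)
        rng = np.random.default_rng(32)
        for _ in range(5):
            theta = model.coef_ + 0.2 * rng.standard_normal(model.coef_.size)
            _, g, _ = model._nll_grad(theta, lik)
            num = np.empty_like(g)
            for j in range(theta.size):
                h = 1e-6 * max(1.0, abs(theta[j]))
                tp, tm = theta.copy(), theta.copy()
                tp[j] += h
                tm[j] -= h
                num[j] = (model._nll_grad(tp, lik)[0] - model._nll_grad(tm, lik)[0]) / (2 * h)
            np.testing.assert_allclose(g, num, rtol=1e-5, atol=1e-5 * (1 + np.abs(num).max()))

    def test_episode_splitting_leaves_likelihood_unchanged(self, lifetable):
        """Splitting every subject into abutting (t0, s], (s, t1] episodes
        leaves the likelihood identical at any parameter value, hence also at
        the maximum."""
        cohort = sg.fixture_cohort(n=400, seed=33, lt=lifetable)
        pf = sg.apply_period(cohort)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = ExcessHazardModel(baseline_df=3, age_df=2).fit(pf, lifetable)
        split_rows = []
        for _, row in pf.iterrows():
            s = 0.5 * (row["t0"] + row["t1"])
            first = row.copy()
            first["t1"], first["d"] = s, 0
            second = row.copy()
            second["t0"] = s
            split_rows.extend([first, second])
        split = pd.DataFrame(split_rows).reset_index(drop=True)
        ll_orig = model.log_likelihood(pf, lifetable)
        ll_split = model.log_likelihood(split, lifetable)
        assert ll_split == pytest.approx(ll_orig, abs=1e-6)

    def test_cumhaz_monotone_over_fitted_range(self, lifetable):
        cohort = sg.fixture_cohort(n=500, seed=34, lt=lifetable)
        pf = sg.apply_period(cohort)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = ExcessHazardModel(baseline_df=3, age_df=2).fit(pf, lifetable)
        t = np.linspace(0.05, 10, 400)
        for age, fem in [(55, 0.0), (75, 1.0)]:
            lam = model.predict_cumhaz(t, float(age), fem)
            assert np.all(np.diff(lam) > -1e-10)


@pytest.fixture(scope="module")
def fitted(null_lifetable):
    frame = weibull_frame(4_000, 0.8, 6.0, seed=13)
    rng = np.random.default_rng(13)
    frame["age_at_dx"] = rng.uniform(40, 90, len(frame))
    frame["sex"] = np.where(rng.random(len(frame)) < 0.5, "female", "male")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return ExcessHazardModel(baseline_df=4).fit(frame, null_lifetable)


class TestPrediction:

    def test_survival_tends_to_one_at_zero(self, fitted):
        R = fitted.predict_survival(np.array([1e-8]), 70.0, 0.0)
        assert R[0] > 0.999

    def test_continuity_at_knots(self, fitted):
        for k in fitted.baseline_knots_[1:-1]:
            t = float(np.exp(k))
            lo, hi = fitted.predict_survival(np.array([t * (1 - 1e-9), t * (1 + 1e-9)]), 70.0, 0.0)
            assert lo == pytest.approx(hi, rel=1e-6)

    def test_hazard_is_negative_log_derivative_of_survival(self, fitted):
        t = np.linspace(0.5, 8, 30)
        lam = fitted.predict_excess_hazard(t, 65.0, 1.0)
        h = 1e-5
        R_plus = fitted.predict_survival(t + h, 65.0, 1.0)
        R_minus = fitted.predict_survival(t - h, 65.0, 1.0)
        fd = -(np.log(R_plus) - np.log(R_minus)) / (2 * h)
        np.testing.assert_allclose(lam, fd, rtol=1e-5, atol=1e-6)

    def test_nonpositive_time_rejected(self, fitted):
        with pytest.raises(ValueError):
            fitted.predict_survival(np.array([0.0]), 70.0, 0.0)

    def test_round_trip_serialisation(self, fitted):
        clone = ExcessHazardModel.from_dict(fitted.to_dict())
        t = np.array([0.5, 2.0, 7.0])
        np.testing.assert_allclose(
            clone.predict_survival(t, 70.0, 1.0), fitted.predict_survival(t, 70.0, 1.0)
        )
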