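import numpy as np
import pandas as pd
import pytest

import stagesurv as sg
from stagesurv.cohort import MISSING, STAGES
from stagesurv.imputation import (
    ConditionSpec,
    StageImputer,
    apply_condition,
    build_imputation_design,
    h1_statistic,
    nelson_aalen,
)
from stagesurv.period import PeriodSpec

from conftest import random_period_frame


def brute_force_H(frame, weighted):
    """Independent oracle: explicit double loop over subjects x event times."""
    t0 = frame["t0"].to_numpy()
    t1 = frame["t1"].to_numpy()
    d = frame["d"].to_numpy()
    out = np.zeros(len(frame))
    event_times = sorted(set(t1[d == 1]))
    for i in range(len(frame)):
        acc = 0.0
        for tj in event_times:
            if tj > t1[i]:
                continue
            deaths = sum(1 for k in range(len(frame)) if d[k] == 1 and t1[k] == tj)
            at_risk = sum(1 for k in range(len(frame)) if t0[k] < tj <= t1[k])
            acc += (tj if weighted else 1.0) * (deaths / at_risk)
        out[i] = acc
    return out


class TestRiskSetStatistics:
    def test_worked_four_subject_example(self):
        """Four subjects, deaths at t=1 (4 at risk) and t=3 (3 at risk):
        H(3) = 1/4 + 1/3 = 7/12 and H1(3) = 1*(1/4) + 3*(1/3) = 5/4."""
        frame = pd.DataFrame(
            {"t0": [0.0, 0.0, 0.0, 0.0], "t1": [1.0, 3.0, 4.0, 5.0], "d": [1, 1, 0, 0]}
        )
        H = nelson_aalen(frame)
        H1 = h1_statistic(frame)
        assert H[1] == pytest.approx(7 / 12, abs=1e-15)
        assert H1[1] == pytest.approx(5 / 4, abs=1e-15)
        # the t=1 death saw only itself-era risk set of 4
        assert H[0] == pytest.approx(1 / 4, abs=1e-15)
        assert H1[0] == pytest.approx(1 / 4, abs=1e-15)

    def test_no_events_gives_zero(self):
        frame = pd.DataFrame({"t0": [0.0, 1.0], "t1": [2.0, 3.0], "d": [0, 0]})
        assert nelson_aalen(frame).tolist() == [0.0, 0.0]
        assert h1_statistic(frame).tolist() == [0.0, 0.0]

    def test_single_subject_death(self):
        frame = pd.DataFrame({"t0": [0.0], "t1": [2.5], "d": [1]})
        assert nelson_aalen(frame)[0] == 1.0
        assert h1_statistic(frame)[0] == 2.5

    def test_all_events_at_unit_time_makes_h1_equal_h(self):
        frame = pd.DataFrame({"t0": [0.0] * 5, "t1": [1.0] * 3 + [2.0, 4.0], "d": [1, 1, 1, 0, 0]})
        np.testing.assert_array_equal(nelson_aalen(frame), h1_statistic(frame))

    def test_matches_brute_force_oracle_exactly(self):
        """1,000 random small frames with delayed entry and tied times."""
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            frame = random_period_frame(rng, int(rng.integers(2, 51)))
            np.testing.assert_array_equal(nelson_aalen(frame), brute_force_H(frame, False))
            np.testing.assert_array_equal(h1_statistic(frame), brute_force_H(frame, True))

    def test_matches_lifelines_nelson_aalen_without_truncation(self):
        """Cross-check against an independent implementation on a frame
        without delayed entry."""
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(5)
        frame = random_period_frame(rng, 300)
        frame["t0"] = 0.0
        naf = lifelines.NelsonAalenFitter(nelson_aalen_smoothing=False)
        naf.fit(frame["t1"], frame["d"])
        ours = nelson_aalen(frame)
        theirs = naf.cumulative_hazard_at_times(frame["t1"]).to_numpy()
        np.testing.assert_allclose(ours, theirs, atol=1e-12)


class TestImputationDesign:
    def test_no_missing_cells_and_interactions(self, period_frame):
        pf, _ = period_frame
        X = build_imputation_design(pf)
        assert not X.isna().any().any()
        female = (pf["sex"] == "female").to_numpy(float)
        np.testing.assert_allclose(X["female_x_H"], female * X["H"])
        np.testing.assert_allclose(X["age_x_H1"], pf["age_at_dx"].to_numpy(float) * X["H1"])
        assert any(c.startswith("grade_") for c in X.columns)
        assert any(c.startswith("dx_year_") for c in X.columns)

    def test_grade_missing_is_a_level_not_a_gap(self, period_frame):
        pf, _ = period_frame
        assert (pf["grade"] == "missing").any()
        X = build_imputation_design(pf)
        assert not X.isna().any().any()


class TestStageImputer:
    def test_no_missing_rows_returns_copies(self, period_frame):
        pf, _ = period_frame
        complete = pf[pf["stage_obs"] != MISSING].reset_index(drop=True)
        frames = StageImputer(m=3, random_state=0).fit(complete).transform(complete)
        assert len(frames) == 3
        for fr in frames:
            np.testing.assert_array_equal(fr["stage"], complete["stage_obs"])

    def test_non_stage_columns_preserved_bitwise(self, period_frame):
        pf, _ = period_frame
        frames = StageImputer(m=2, random_state=1).fit_transform(pf)
        for fr in frames:
            pd.testing.assert_frame_equal(fr.drop(columns="stage"), pf)

    def test_imputed_values_are_valid_stages(self, period_frame):
        pf, _ = period_frame
        frames = StageImputer(m=2, random_state=2).fit_transform(pf)
        for fr in frames:
            assert fr["stage"].isin(STAGES).all()

    def test_deterministic_given_seed(self, period_frame):
        pf, _ = period_frame
        a = StageImputer(m=2, random_state=7).fit_transform(pf)
        b = StageImputer(m=2, random_state=7).fit_transform(pf)
        for fa, fb in zip(a, b):
            pd.testing.assert_frame_equal(fa, fb)

    def test_degenerate_pattern_imputes_its_only_stage(self):
        """With draws disabled and a covariate pattern whose complete cases
        are all distant, missing rows with that pattern come back distant."""
        rng = np.random.default_rng(0)
        n = 400
        flag = rng.random(n) < 0.5
        stage = np.where(flag, "distant", rng.choice(["localised", "regional"], n))
        obs = stage.astype(object).copy()
        miss = (rng.random(n) < 0.2) & flag
        obs[miss] = MISSING
        frame = pd.DataFrame(
            {
                "t0": 0.0,
                "t1": rng.uniform(0.5, 5, n),
                "d": rng.integers(0, 2, n),
                "sex": np.where(flag, "male", "female"),
                "age_at_dx": np.where(flag, 80.0, 55.0),
                "grade": np.where(flag, "IV", "I"),
                "subsite": np.where(flag, "C18.9", "C18.2"),
                "dx_year": 2015,
                "stage_obs": obs,
            }
        )
        frames = StageImputer(m=2, draw_params=False, random_state=0).fit_transform(frame)
        for fr in frames:
            assert (fr.loc[miss, "stage"] == "distant").all()

    def test_mar_masking_recovers_stage_distribution(self, lifetable):
        """Stage imputed under covariate-driven (MAR) masking reproduces the
        true stage distribution of the masked rows within 2 pp."""
        cohort = sg.generate_cohort(sg.CohortSpec(n=20000, seed=21), lifetable)
        pf = sg.apply_period(cohort, PeriodSpec())
        rng = np.random.default_rng(22)
        from scipy.special import expit

        p = expit(-3.0 + 0.03 * pf["age_at_dx"].to_numpy(float))
        mask = rng.random(len(pf)) < p
        pf = pf.copy()
        pf.loc[mask, "stage_obs"] = MISSING
        masked_idx = pf["stage_obs"] == MISSING
        frames = StageImputer(m=10, random_state=23).fit_transform(pf)
        imputed = pd.concat([fr.loc[masked_idx, "stage"] for fr in frames])
        true = pf.loc[masked_idx, "stage_true"]
        for st in STAGES:
            assert abs((imputed == st).mean() - (true == st).mean()) < 0.02

    def test_absent_category_raises(self):
        frame = pd.DataFrame(
            {
                "t0": 0.0,
                "t1": np.linspace(0.5, 3, 40),
                "d": [0, 1] * 20,
                "sex": ["male", "female"] * 20,
                "age_at_dx": 60.0,
                "grade": "II",
                "subsite": "C18.2",
                "dx_year": 2015,
                "stage_obs": ["localised"] * 20 + ["regional"] * 10 + [MISSING] * 10,
            }
        )
        with pytest.raises(ValueError, match="absent"):
            StageImputer(m=1).fit(frame)


class TestConditions:
    def make_frame(self):
        rows = []
        for dx, stage_obs in [
            ("2016-06-01", MISSING),  # in window
            ("2013-06-01", MISSING),  # pre-window
            ("2008-06-01", MISSING),  # before pre-window
            ("2016-01-01", "regional"),
        ]:
            rows.append({"dx_date": pd.Timestamp(dx), "stage_obs": stage_obs})
        return pd.DataFrame(rows)

    @pytest.mark.parametrize("cond", [1, 2, 3, 4])
    @pytest.mark.parametrize("pw", [True, False])
    def test_in_window_subject_always_imputed(self, cond, pw):
        parts = apply_condition(self.make_frame(), ConditionSpec(cond, pw))
        assert parts["to_impute"][0]

    def test_prewindow_subject_depends_on_prewindow_flag(self):
        frame = self.make_frame()
        with_pw = apply_condition(frame, ConditionSpec(2, True))
        assert with_pw["to_impute"][1] and not with_pw["to_exclude"][1]
        without = apply_condition(frame, ConditionSpec(2, False))
        assert without["to_exclude"][1] and not without["to_impute"][1]
        assert apply_condition(frame, ConditionSpec(3, False))["to_assign_localised"][1]
        assert apply_condition(frame, ConditionSpec(4, False))["to_assign_distant"][1]

    @pytest.mark.parametrize("pw", [True, False])
    def test_early_subject_under_each_condition(self, pw):
        frame = self.make_frame()
        assert apply_condition(frame, ConditionSpec(1, pw))["to_impute"][2]
        assert apply_condition(frame, ConditionSpec(2, pw))["to_exclude"][2]
        assert apply_condition(frame, ConditionSpec(3, pw))["to_assign_localised"][2]
        assert apply_condition(frame, ConditionSpec(4, pw))["to_assign_distant"][2]

    @pytest.mark.parametrize("cond", [1, 2, 3, 4])
    def test_partition_disjoint_and_exhaustive(self, cond):
        frame = self.make_frame()
        parts = apply_condition(frame, ConditionSpec(cond, True))
        stacked = np.stack(list(parts.values()))
        missing = (frame["stage_obs"] == MISSING).to_numpy()
        assert (stacked.sum(axis=0) == missing.astype(int)).all()
        assert not parts["to_impute"][3], "observed-stage rows never partitioned"
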