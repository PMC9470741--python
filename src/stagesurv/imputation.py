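"""Multiple imputation of missing stage within the period analysis.

Missing stage is filled in by a 3-category multinomial logistic model fitted to
the complete-stage subjects of the period frame.  The model follows the
survival-aware design recommended for imputing covariates in time-to-event
settings: sex, age, subsite, grade (with unknown as its own level), calendar
year of diagnosis (categorical), the event indicator, the Nelson-Aalen
cumulative-hazard estimate H at the subject's exit time, its time-weighted
companion H1(t) = sum_{t_j <= t} t_j d(t_j)/n(t_j), and the interactions of
sex and age with both H and H1 (an approximation that lets the imputation
model track time-varying covariate effects).

Proper multiple imputation: for each of the m data sets a coefficient vector
is drawn from the asymptotic normal sampling distribution of the fitted model
before category probabilities are computed, so between-imputation variance
reflects estimation uncertainty in the imputation model itself.

Four stress conditions control what happens to missing-stage subjects
diagnosed before a calendar boundary B (the pre-window start, or the period
window start when the pre-window is switched off):

1. impute everyone;
2. complete-case: drop them;
3. assign localised;
4. assign distant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .cohort import MISSING, STAGES
from .period import PeriodSpec

__all__ = [
    "nelson_aalen",
    "h1_statistic",
    "risk_sets",
    "build_imputation_design",
    "StageImputer",
    "ConditionSpec",
    "apply_condition",
]


def risk_sets(frame: pd.DataFrame):
    """Distinct event times with death counts and numbers at risk.

    Delayed entry: a subject is at risk at time t iff ``t0 < t <= t1``; in
    particular each subject is at risk at their own death time.
    """
    t0 = frame["t0"].to_numpy(float)
    t1 = frame["t1"].to_numpy(float)
    d = frame["d"].to_numpy(int)
    tj, dj = np.unique(t1[d == 1], return_counts=True)
    t0s = np.sort(t0)
    t1s = np.sort(t1)
    nj = np.searchsorted(t0s, tj, side="left") - np.searchsorted(t1s, tj, side="left")
    if np.any(nj < 1):
        raise ValueError("empty risk set at an event time")
    return tj, dj, nj


def _cum_at_exit(frame: pd.DataFrame, weights_by_time: bool):
    tj, dj, nj = risk_sets(frame)
    if tj.size == 0:
        return np.zeros(len(frame))
    inc = dj / nj
    if weights_by_time:
        inc = tj * inc
    csum = np.concatenate([[0.0], np.cumsum(inc)])
    idx = np.searchsorted(tj, frame["t1"].to_numpy(float), side="right")
    return csum[idx]


def nelson_aalen(frame: pd.DataFrame) -> np.ndarray:
    """Nelson-Aalen cumulative hazard H = sum d(t_j)/n(t_j) at each subject's exit."""
    if frame.empty:
        raise ValueError("empty frame")
    return _cum_at_exit(frame, weights_by_time=False)


def h1_statistic(frame: pd.DataFrame) -> np.ndarray:
    """Time-weighted companion H1 = sum t_j d(t_j)/n(t_j) at each subject's exit."""
    if frame.empty:
        raise ValueError("empty frame")
    return _cum_at_exit(frame, weights_by_time=True)


def build_imputation_design(frame: pd.DataFrame, use_full_followup: bool = False) -> pd.DataFrame:
    """Design matrix of the multinomial imputation model (no missing cells).

    By default H and H1 are computed on the period frame's delayed-entry risk
    sets over time since diagnosis, keeping the imputation model internal to
    the analysed sample; ``use_full_followup`` recomputes them on the
    subjects' full follow-up instead (sensitivity option).
    """
    if use_full_followup:
        aux = frame.assign(t0=0.0, t1=frame["time"], d=frame["event"])
        H = nelson_aalen(aux)
        H1 = h1_statistic(aux)
    else:
        H = nelson_aalen(frame)
        H1 = h1_statistic(frame)
    female = (frame["sex"] == "female").astype(float).to_numpy()
    age = frame["age_at_dx"].to_numpy(float)
    X = pd.DataFrame(
        {
            "const": 1.0,
            "female": female,
            "age": age,
            "event": frame["d"].to_numpy(float),
            "H": H,
            "H1": H1,
            "female_x_H": female * H,
            "age_x_H": age * H,
            "female_x_H1": female * H1,
            "age_x_H1": age * H1,
        },
        index=frame.index,
    )
    for col in ("subsite", "grade", "dx_year"):
        dummies = pd.get_dummies(frame[col].astype(str), prefix=col, drop_first=True, dtype=float)
        X = pd.concat([X, dummies], axis=1)
    if X.isna().any().any():
        bad = X.columns[X.isna().any()].tolist()
        raise ValueError(f"imputation design contains missing values in {bad}")
    return X


class StageImputer(BaseEstimator):
    """Proper multiple imputation of stage via multinomial logistic regression.

    Parameters
    ----------
    m : int
        Number of imputed data sets (default 30).
    draw_params : bool
        Draw coefficients from their asymptotic normal sampling distribution
        for each imputation (proper MI).  With ``False`` the MLE is reused for
        every imputation (improper MI; mainly for degenerate-case testing).
    use_full_followup : bool
        Compute H and H1 on full follow-up rather than the period risk sets.
    random_state : int
        Seed for both the coefficient draws and the category draws.
    """

    def __init__(self, m: int = 30, draw_params: bool = True, use_full_followup: bool = False, random_state: int = 0):
        self.m = m
        self.draw_params = draw_params
        self.use_full_followup = use_full_followup
        self.random_state = random_state

    def fit(self, frame: pd.DataFrame, y=None):
        """Fit the multinomial model of observed stage on the complete-stage rows."""
        from statsmodels.api import MNLogit

        X = build_imputation_design(frame, self.use_full_followup)
        complete = frame["stage_obs"].isin(STAGES).to_numpy()
        seen = set(frame.loc[complete, "stage_obs"])
        absent = [s for s in STAGES if s not in seen]
        if absent:
            raise ValueError(f"stage categories {absent} absent from complete cases; cannot impute")
        codes = frame.loc[complete, "stage_obs"].map({s: i for i, s in enumerate(STAGES)}).to_numpy()
        Xc = X.loc[complete]
        # Drop constant columns (e.g. a dx_year level unused after subsetting).
        keep = Xc.std().to_numpy() > 0
        keep[Xc.columns.get_loc("const")] = True
        self.columns_ = Xc.columns[keep]
        Xc = Xc.loc[:, self.columns_]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = MNLogit(codes, Xc.to_numpy()).fit(method="newton", maxiter=100, disp=False)
            except np.linalg.LinAlgError as exc:
                raise ValueError(
                    f"multinomial imputation model failed (singular information); columns: {list(self.columns_)}"
                ) from exc
            if not np.all(np.isfinite(np.asarray(res.params))):
                # Quasi-separated designs send Newton through a singular
                # Hessian; a gradient method walks to large finite
                # coefficients instead, which is the right degenerate limit
                # (category probabilities ~1 for the separated pattern).
                res = MNLogit(codes, Xc.to_numpy()).fit(method="bfgs", maxiter=300, disp=False)
        params = np.asarray(res.params)  # shape (k, J-1)
        if not np.all(np.isfinite(params)):
            bad = self.columns_[np.flatnonzero(~np.isfinite(params).all(axis=1))].tolist()
            raise ValueError(f"non-finite imputation coefficients (perfect separation?) in {bad}")
        if not res.mle_retvals.get("converged", True):
            warnings.warn("imputation model did not fully converge; using last iterate", stacklevel=2)
        self.params_ = params
        try:
            cov = np.asarray(res.cov_params())
        except (ValueError, np.linalg.LinAlgError):
            cov = np.full((params.size, params.size), np.nan)
        # cov_params orders the stacked vector equation-by-equation (Fortran ravel).
        if not np.all(np.isfinite(cov)):
            cov = np.zeros((params.size, params.size))
            warnings.warn("imputation coefficient covariance unavailable; parameter draws disabled", stacklevel=2)
        self.cov_params_ = cov
        self.n_complete_ = int(complete.sum())
        return self

    def _probs(self, X: np.ndarray, params: np.ndarray) -> np.ndarray:
        eta = np.zeros((X.shape[0], len(STAGES)))
        eta[:, 1:] = X @ params
        eta -= eta.max(axis=1, keepdims=True)
        p = np.exp(eta)
        return p / p.sum(axis=1, keepdims=True)

    def transform(self, frame: pd.DataFrame) -> list[pd.DataFrame]:
        """Return m completed copies of ``frame`` with a filled ``stage`` column.

        Rows whose ``stage_obs`` is observed keep it; missing rows receive a
        category drawn from the (possibly parameter-drawn) model probabilities.
        Every non-stage column is preserved unchanged.
        """
        if not hasattr(self, "params_"):
            raise ValueError("StageImputer must be fitted before transform")
        rng = np.random.default_rng(self.random_state)
        X = build_imputation_design(frame, self.use_full_followup)
        X = X.reindex(columns=self.columns_, fill_value=0.0)
        miss = (frame["stage_obs"] == MISSING).to_numpy()
        Xm = X.to_numpy()[miss]
        frames = []
        flat = self.params_.ravel(order="F")
        for _ in range(self.m):
            out = frame.copy()
            stage = frame["stage_obs"].to_numpy(object).copy()
            if miss.any():
                if self.draw_params and self.cov_params_.any():
                    draw = rng.multivariate_normal(flat, self.cov_params_, method="cholesky")
                    params = draw.reshape(self.params_.shape, order="F")
                else:
                    params = self.params_
                p = self._probs(Xm, params)
                u = rng.random(p.shape[0])
                idx = (u[:, None] > np.cumsum(p, axis=1)).sum(axis=1)
                stage[miss] = np.array(STAGES, dtype=object)[idx]
            out["stage"] = stage
            frames.append(out)
        return frames

    def fit_transform(self, frame: pd.DataFrame, y=None) -> list[pd.DataFrame]:
        return self.fit(frame).transform(frame)


@dataclass(frozen=True)
class ConditionSpec:
    """One of the four imputation stress conditions, with/without pre-window."""

    condition: int = 1
    use_prewindow: bool = True

    def __post_init__(self):
        if self.condition not in (1, 2, 3, 4):
            raise ValueError("condition must be 1-4")


def apply_condition(frame: pd.DataFrame, cond: ConditionSpec, pspec: PeriodSpec = PeriodSpec()) -> dict[str, np.ndarray]:
    """Partition the missing-stage rows of a period frame for one condition.

    Returns boolean masks ``to_impute``, ``to_exclude``, ``to_assign_localised``
    and ``to_assign_distant`` over ``frame``'s rows.  The calendar boundary is
    the pre-window start (or the period-window start when the pre-window is
    off); under condition 1 every missing-stage subject is imputed regardless.
    """
    missing = (frame["stage_obs"] == MISSING).to_numpy()
    boundary = pd.Timestamp(pspec.prewindow_start if cond.use_prewindow else pspec.window_start)
    before = (pd.to_datetime(frame["dx_date"]) < boundary).to_numpy()
    zeros = np.zeros(len(frame), dtype=bool)
    if cond.condition == 1:
        return {
            "to_impute": missing,
            "to_exclude": zeros.copy(),
            "to_assign_localised": zeros.copy(),
            "to_assign_distant": zeros.copy(),
        }
    early = missing & before
    parts = {
        "to_impute": missing & ~before,
        "to_exclude": early if cond.condition == 2 else zeros.copy(),
        "to_assign_localised": early if cond.condition == 3 else zeros.copy(),
        "to_assign_distant": early if cond.condition == 4 else zeros.copy(),
    }
    return parts


def complete_frames(
    frame: pd.DataFrame,
    cond: ConditionSpec,
    pspec: PeriodSpec,
    m: int = 30,
    random_state: int = 0,
    use_full_followup: bool = False,
    draw_params: bool = True,
) -> list[pd.DataFrame]:
    """Apply a condition end-to-end: exclude/assign, impute the rest, return m frames."""
    parts = apply_condition(frame, cond, pspec)
    work = frame.copy()
    work["stage"] = work["stage_obs"]
    work.loc[parts["to_assign_localised"], "stage"] = "localised"
    work.loc[parts["to_assign_distant"], "stage"] = "distant"
    work = work.loc[~parts["to_exclude"]].reset_index(drop=True)
    # Assigned rows are no longer "missing" for the imputer.
    work_obs = work.copy()
    work_obs["stage_obs"] = work["stage"]
    if (work_obs["stage_obs"] == MISSING).any():
        imputer = StageImputer(m=m, random_state=random_state, use_full_followup=use_full_followup, draw_params=draw_params)
        return imputer.fit_transform(work_obs)
    return [work_obs.assign(stage=work_obs["stage_obs"]) for _ in range(m)]
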