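"""Flexible parametric excess-hazard models on the log cumulative-hazard scale.

The model places restricted cubic splines on the log *cumulative excess
hazard* as a function of log time since diagnosis:

    ln Lambda(t | x) = s0(ln t; gamma) + beta' x + sum_k s_k(ln t; alpha_k) x_k

where ``s0`` is the baseline spline (default 5 df), ``x`` holds an age spline
(default 4 df, with the age effect held constant beyond the 2nd/98th age
percentiles) and a sex indicator, and the ``s_k`` are lower-dimensional
splines (default 2 df) carrying time-dependent effects for each covariate.
The excess hazard is ``lambda(t|x) = Lambda(t|x) * s'(ln t)/t`` via the
analytic spline derivative, and the likelihood combines it additively with
the expected population hazard ``h*`` from a lifetable:

    l_i = d_i ln(h*_i(t1_i) + lambda_i(t1_i)) - Lambda_i(t1_i) + Lambda_i(t0_i)

with delayed entry at ``t0`` (period analysis).  Relative survival is
``R(t|x) = exp(-Lambda(t|x))``.

One model is fitted per cancer stage, so every covariate effect — and its
time-dependence — is free to differ across stages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

from .lifetable import LifeTable
from .period import DAYS_PER_YEAR

FLOOR = 1e-10

__all__ = ["rcs", "rcs_deriv", "default_knots", "ExcessHazardModel"]


def rcs(x, knots) -> np.ndarray:
    """Restricted (natural) cubic spline basis; ``len(knots) - 1`` columns.

    Standard truncated-power construction with the usual ``(k_K - k_1)**2``
    normalisation: column 1 is ``x`` itself, and each interior-knot column is a
    combination of truncated cubics constrained so the function is linear
    beyond the boundary knots.
    """
    knots = np.asarray(knots, dtype=float)
    if knots.ndim != 1 or knots.size < 2 or np.any(np.diff(knots) <= 0):
        raise ValueError("knots must be strictly increasing with at least 2 entries")
    x = np.asarray(x, dtype=float)
    k1, kK = knots[0], knots[-1]
    out = np.empty(x.shape + (knots.size - 1,))
    out[..., 0] = x
    norm = (kK - k1) ** 2
    for j, kj in enumerate(knots[1:-1], start=1):
        lam = (kK - kj) / (kK - k1)
        out[..., j] = (
            np.clip(x - kj, 0, None) ** 3
            - lam * np.clip(x - k1, 0, None) ** 3
            - (1 - lam) * np.clip(x - kK, 0, None) ** 3
        ) / norm
    return out


def rcs_deriv(x, knots) -> np.ndarray:
    """Analytic first derivative of :func:`rcs` with respect to ``x``."""
    knots = np.asarray(knots, dtype=float)
    x = np.asarray(x, dtype=float)
    k1, kK = knots[0], knots[-1]
    out = np.empty(x.shape + (knots.size - 1,))
    out[..., 0] = 1.0
    norm = (kK - k1) ** 2
    for j, kj in enumerate(knots[1:-1], start=1):
        lam = (kK - kj) / (kK - k1)
        out[..., j] = (
            3 * np.clip(x - kj, 0, None) ** 2
            - 3 * lam * np.clip(x - k1, 0, None) ** 2
            - 3 * (1 - lam) * np.clip(x - kK, 0, None) ** 2
        ) / norm
    return out


def default_knots(event_times, df: int) -> np.ndarray:
    """Knots on the log-time axis: boundaries at the extremes of the
    uncensored log event times, interior knots at equally spaced centiles
    (df = 5 -> centiles 20/40/60/80; df = 2 -> the median; df = 1 -> none)."""
    t = np.asarray(event_times, dtype=float)
    t = t[t > 0]
    logt = np.log(t)
    if np.unique(logt).size < df + 1:
        raise ValueError(f"need at least {df + 1} distinct uncensored event times for df={df}")
    qs = np.linspace(0, 1, df + 1)
    knots = np.quantile(logt, qs)
    if np.any(np.diff(knots) <= 0):
        knots = np.unique(knots)
        if knots.size < 2:
            raise ValueError("degenerate knot set")
    return knots


def _quantile_knots(values, df: int) -> np.ndarray:
    """Covariate-scale knots: boundary at min/max, interior at equal centiles."""
    v = np.asarray(values, dtype=float)
    knots = np.quantile(v, np.linspace(0, 1, df + 1))
    return np.unique(knots)


def _attained_year(dx_date: pd.Series, t: np.ndarray) -> np.ndarray:
    dx = pd.to_datetime(dx_date)
    frac = dx.dt.year.to_numpy() + (dx.dt.dayofyear.to_numpy() - 1) / DAYS_PER_YEAR
    return np.floor(frac + t).astype(int)


@dataclass
class _LikData:
    D1: np.ndarray  # design at exit (eta)
    G1: np.ndarray  # derivative design at exit (d eta / d ln t)
    D0: np.ndarray  # design at entry, rows with t0 > 0
    idx0: np.ndarray
    t1: np.ndarray
    d: np.ndarray
    hstar: np.ndarray


class ExcessHazardModel(BaseEstimator):
    """Stage-specific flexible parametric excess-hazard (relative survival) model.

    Parameters
    ----------
    baseline_df : int
        Degrees of freedom of the baseline log-cumulative-excess-hazard spline.
    age_df : int
        Degrees of freedom of the age spline main effect.
    age_tail_percentiles : tuple
        Age is winsorised at these percentiles before spline evaluation, so
        the age effect is exactly constant in the tails where data are sparse.
    td_df : int
        Degrees of freedom of the time-dependent-effect splines; 0 disables
        time-dependent effects.
    include_age, include_sex : bool
        Covariate switches (both off gives a pure baseline model).
    age_td_df : int
        Degrees of freedom of the reduced age spline whose columns carry the
        time-dependent age effect.
    """

    def __init__(
        self,
        baseline_df: int = 5,
        age_df: int = 4,
        age_tail_percentiles: tuple = (2.0, 98.0),
        td_df: int = 2,
        age_td_df: int = 2,
        include_age: bool = True,
        include_sex: bool = True,
        tol: float = 1e-8,
        grad_tol: float = 1e-5,
        max_iter: int = 500,
    ):
        self.baseline_df = baseline_df
        self.age_df = age_df
        self.age_tail_percentiles = age_tail_percentiles
        self.td_df = td_df
        self.age_td_df = age_td_df
        self.include_age = include_age
        self.include_sex = include_sex
        self.tol = tol
        self.grad_tol = grad_tol
        self.max_iter = max_iter

    # ------------------------------------------------------------------ design

    def _winsorise_age(self, age):
        lo, hi = self.age_bounds_
        return np.clip(np.asarray(age, dtype=float), lo, hi)

    def _covariate_rows(self, age, female):
        """(X_main, X_td): main-effect and time-dependent covariate columns."""
        n = np.broadcast(np.asarray(age), np.asarray(female)).shape[0]
        main_cols, td_cols = [], []
        if self.include_age:
            aw = self._winsorise_age(age)
            main_cols.append(rcs(aw, self.age_knots_))
            if self.td_df > 0:
                td_cols.append(rcs(aw, self.age_td_knots_))
        if self.include_sex:
            f = np.asarray(female, dtype=float).reshape(-1, 1)
            main_cols.append(f)
            if self.td_df > 0:
                td_cols.append(f)
        X = np.hstack(main_cols) if main_cols else np.empty((n, 0))
        Xtd = np.hstack(td_cols) if td_cols else np.empty((n, 0))
        return X, Xtd

    def _design(self, logt, age, female):
        """Full design and its log-time derivative at (t, x)."""
        B0 = rcs(logt, self.baseline_knots_)
        B0d = rcs_deriv(logt, self.baseline_knots_)
        X, Xtd = self._covariate_rows(age, female)
        n = B0.shape[0]
        cols = [np.ones((n, 1)), B0, X]
        dcols = [np.zeros((n, 1)), B0d, np.zeros_like(X)]
        if self.td_df > 0 and Xtd.shape[1] > 0:
            Bt = rcs(logt, self.td_knots_)
            Btd = rcs_deriv(logt, self.td_knots_)
            for c in range(Xtd.shape[1]):
                cols.append(Xtd[:, c : c + 1] * Bt)
                dcols.append(Xtd[:, c : c + 1] * Btd)
        return np.hstack(cols), np.hstack(dcols)

    # ------------------------------------------------------------------ likelihood

    def _build_likdata(self, frame: pd.DataFrame, lt: LifeTable) -> _LikData:
        t0 = frame["t0"].to_numpy(float)
        t1 = frame["t1"].to_numpy(float)
        d = frame["d"].to_numpy(float)
        age = frame["age_at_dx"].to_numpy(float)
        female = (frame["sex"] == "female").to_numpy(float)

        hstar = np.zeros(len(frame))
        years = _attained_year(frame["dx_date"], t1)
        for sx in ("female", "male"):
            m = (frame["sex"] == sx).to_numpy()
            if m.any():
                hstar[m] = lt.expected_rate(sx, age[m] + t1[m], years[m])

        D1, G1 = self._design(np.log(t1), age, female)
        idx0 = np.flatnonzero(t0 > 0)
        if idx0.size:
            D0, _ = self._design(np.log(t0[idx0]), age[idx0], female[idx0])
        else:
            D0 = np.empty((0, D1.shape[1]))
        return _LikData(D1=D1, G1=G1, D0=D0, idx0=idx0, t1=t1, d=d, hstar=hstar)

    @staticmethod
    def _safe_exp(eta, cap: float = 50.0):
        """exp with a smooth quadratic extension above ``cap``.

        Keeps the likelihood finite (and strictly increasing in eta) when the
        optimiser's line search wanders into absurd parameter regions, instead
        of overflowing to inf/nan.  Returns (value, d value / d eta).
        """
        over = eta > cap
        e = np.exp(np.where(over, cap, eta))
        x = np.where(over, eta - cap, 0.0)
        val = e * (1.0 + x + 0.5 * x**2)
        dval = np.where(over, e * (1.0 + x), val)
        return val, dval

    @staticmethod
    def _nll_grad(theta: np.ndarray, lik: _LikData):
        eta1 = lik.D1 @ theta
        ds1 = lik.G1 @ theta  # d eta / d ln t at exit
        Lam1, dLam1 = ExcessHazardModel._safe_exp(eta1)
        lam1 = Lam1 * ds1 / lik.t1
        htot = lik.hstar + lam1
        floored = htot < FLOOR
        htot_safe = np.where(floored, FLOOR, htot)

        ll = -np.sum(Lam1)
        grad = -(dLam1[:, None] * lik.D1).sum(axis=0)
        if lik.idx0.size:
            Lam0, dLam0 = ExcessHazardModel._safe_exp(lik.D0 @ theta)
            ll += np.sum(Lam0)
            grad += (dLam0[:, None] * lik.D0).sum(axis=0)
        ev = lik.d > 0
        ll += np.sum(lik.d[ev] * np.log(htot_safe[ev]))
        w = np.where(floored, 0.0, lik.d / htot_safe)  # zero gradient on the floor
        dlam = (dLam1 * ds1 / lik.t1)[:, None] * lik.D1 + (Lam1 / lik.t1)[:, None] * lik.G1
        grad += (w[:, None] * dlam).sum(axis=0)
        return -ll, -grad, int(np.sum(floored & ev))

    # ------------------------------------------------------------------ fitting

    def fit(
        self,
        frame: pd.DataFrame,
        lifetable: LifeTable,
        baseline_knots=None,
        td_knots=None,
        age_knots=None,
        age_td_knots=None,
        age_bounds=None,
    ):
        """Maximise the delayed-entry excess-hazard likelihood on one stage's frame.

        ``frame`` needs columns t0, t1, d, age_at_dx, sex, dx_date.  Knot sets
        and age winsorisation bounds default to data-driven placement but can
        be pinned explicitly (e.g. to evaluate the same model on a transformed
        frame).
        """
        frame = frame.reset_index(drop=True)
        if (frame["t1"] <= frame["t0"]).any() or (frame["t0"] < 0).any():
            raise ValueError("need 0 <= t0 < t1 for every row")
        ev_times = frame.loc[frame["d"] == 1, "t1"].to_numpy(float)
        self.baseline_knots_ = (
            np.asarray(baseline_knots, float) if baseline_knots is not None else default_knots(ev_times, self.baseline_df)
        )
        if self.td_df > 0:
            self.td_knots_ = (
                np.asarray(td_knots, float) if td_knots is not None else default_knots(ev_times, self.td_df)
            )
        age = frame["age_at_dx"].to_numpy(float)
        lo_p, hi_p = self.age_tail_percentiles
        self.age_bounds_ = (
            tuple(age_bounds) if age_bounds is not None else (float(np.percentile(age, lo_p)), float(np.percentile(age, hi_p)))
        )
        if self.include_age:
            aw = self._winsorise_age(age)
            self.age_knots_ = (
                np.asarray(age_knots, float) if age_knots is not None else _quantile_knots(aw, self.age_df)
            )
            if self.td_df > 0:
                self.age_td_knots_ = (
                    np.asarray(age_td_knots, float) if age_td_knots is not None else _quantile_knots(aw, self.age_td_df)
                )

        lik = self._build_likdata(frame, lifetable)
        p = lik.D1.shape[1]

        # Column centring (orthogonalisation against the constant) for stable
        # optimisation; coefficients are reported in the original basis.
        means = lik.D1.mean(axis=0)
        means[0] = 0.0
        likc = _LikData(
            D1=lik.D1 - means,
            G1=lik.G1,
            D0=lik.D0 - means if lik.D0.size else lik.D0,
            idx0=lik.idx0,
            t1=lik.t1,
            d=lik.d,
            hstar=lik.hstar,
        )

        theta0 = np.zeros(p)
        # Initialise the baseline spline from a crude regression of the
        # log Nelson-Aalen all-cause cumulative hazard on the basis.
        from .imputation import nelson_aalen

        try:
            H = nelson_aalen(frame)
            ev = (lik.d > 0) & (H > 0)
            if ev.sum() > p:
                A = likc.D1[ev][:, : self.baseline_df + 1]
                y = np.log(H[ev])
                coef, *_ = np.linalg.lstsq(A, y, rcond=None)
                theta0[: self.baseline_df + 1] = coef
        except Exception:  # pragma: no cover - initialisation is best-effort
            pass

        def fun(th):
            f, g, _ = self._nll_grad(th, likc)
            return f, g

        res = minimize(
            fun,
            theta0,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": self.max_iter, "ftol": self.tol, "gtol": self.grad_tol},
        )
        # Polish with full-memory BFGS: L-BFGS-B's curvature memory is short
        # and its stopping rule loose relative to the precision the delta
        # method and likelihood-invariance checks need.
        polish = minimize(
            fun,
            res.x,
            jac=True,
            method="BFGS",
            options={"maxiter": self.max_iter, "gtol": self.grad_tol},
        )
        if polish.fun <= res.fun:
            res = polish
        f_opt, g_opt, n_floored = self._nll_grad(res.x, likc)
        f_init, _, _ = self._nll_grad(theta0, likc)
        if f_opt > f_init + 1e-8:  # should never decrease below the start
            res.x, f_opt = theta0, f_init
            warnings.warn("optimiser failed to improve on initial point", stacklevel=2)

        self.converged_ = bool(res.success)
        self.n_iter_ = int(res.nit)
        self.grad_norm_ = float(np.max(np.abs(g_opt)))
        self.n_floored_events_ = n_floored
        self.reliable_ = n_floored == 0
        if not self.reliable_:
            warnings.warn(
                f"{n_floored} event(s) sit on the total-hazard floor; fit flagged unreliable",
                stacklevel=2,
            )
        self.loglik_ = -float(f_opt)

        # Back-transform the centring: theta_orig = A theta_c with A the
        # identity apart from row 0 subtracting the column means.
        A = np.eye(p)
        A[0, :] = -means
        A[0, 0] = 1.0
        self.coef_ = A @ res.x  # equals res.x with intercept shifted
        self._theta_centred_ = res.x
        self._means_ = means
        self._lik_ = lik

        hess = self._numeric_hessian(res.x, likc)
        try:
            cov_c = np.linalg.inv(hess)
        except np.linalg.LinAlgError as exc:
            raise ValueError("singular observed information; model not identified") from exc
        self.cov_ = A @ cov_c @ A.T
        return self

    @staticmethod
    def _numeric_hessian(theta, lik, eps: float = 1e-5):
        p = theta.size
        H = np.empty((p, p))
        for j in range(p):
            h = eps * max(1.0, abs(theta[j]))
            tp, tm = theta.copy(), theta.copy()
            tp[j] += h
            tm[j] -= h
            _, gp, _ = ExcessHazardModel._nll_grad(tp, lik)
            _, gm, _ = ExcessHazardModel._nll_grad(tm, lik)
            H[:, j] = (gp - gm) / (2 * h)
        return (H + H.T) / 2

    # ------------------------------------------------------------------ evaluation

    def log_likelihood(self, frame: pd.DataFrame, lifetable: LifeTable, theta=None) -> float:
        """Evaluate the excess-hazard log-likelihood of ``frame`` at ``theta``
        (default: the fitted coefficients) using the fitted knots/bounds."""
        theta = self.coef_ if theta is None else np.asarray(theta, float)
        lik = self._build_likdata(frame.reset_index(drop=True), lifetable)
        f, _, _ = self._nll_grad(theta, lik)
        return -f

    def linear_predictor(self, t, age, female, theta=None):
        t = np.asarray(t, dtype=float)
        if np.any(t <= 0):
            raise ValueError("t must be positive")
        theta = self.coef_ if theta is None else np.asarray(theta, float)
        n = t.shape[0]
        D, G = self._design(np.log(t), np.broadcast_to(np.asarray(age, float), (n,)), np.broadcast_to(np.asarray(female, float), (n,)))
        return D @ theta, G @ theta

    def predict_cumhaz(self, t, age, female, theta=None):
        eta, _ = self.linear_predictor(t, age, female, theta)
        return np.exp(eta)

    def predict_survival(self, t, age, female, theta=None):
        """Relative survival R(t | x) = exp(-Lambda)."""
        return np.exp(-self.predict_cumhaz(t, age, female, theta))

    def predict_excess_hazard(self, t, age, female, theta=None):
        """Excess hazard lambda(t | x); may be negative if the fit permits (flagged)."""
        eta, ds = self.linear_predictor(t, age, female, theta)
        lam = np.exp(eta) * ds / np.asarray(t, dtype=float)
        if np.any(lam < 0):
            warnings.warn("negative fitted excess hazard at some times", stacklevel=2)
        return lam

    def predict(self, t, age, female):
        """Convenience: dict with relative survival and excess hazard."""
        return {
            "relative_survival": self.predict_survival(t, age, female),
            "excess_hazard": self.predict_excess_hazard(t, age, female),
        }

    # ------------------------------------------------------------------ persistence

    def to_dict(self) -> dict:
        out = {
            "params": self.get_params(),
            "coef": self.coef_.tolist(),
            "cov": self.cov_.tolist(),
            "baseline_knots": self.baseline_knots_.tolist(),
            "age_bounds": list(self.age_bounds_),
            "loglik": self.loglik_,
            "converged": self.converged_,
            "grad_norm": self.grad_norm_,
            "n_floored_events": self.n_floored_events_,
        }
        for name in ("td_knots_", "age_knots_", "age_td_knots_"):
            if hasattr(self, name):
                out[name.rstrip("_")] = getattr(self, name).tolist()
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "ExcessHazardModel":
        model = cls(**d["params"])
        model.coef_ = np.asarray(d["coef"])
        model.cov_ = np.asarray(d["cov"])
        model.baseline_knots_ = np.asarray(d["baseline_knots"])
        model.age_bounds_ = tuple(d["age_bounds"])
        model.loglik_ = d["loglik"]
        model.converged_ = d["converged"]
        model.grad_norm_ = d["grad_norm"]
        model.n_floored_events_ = d["n_floored_events"]
        for name in ("td_knots", "age_knots", "age_td_knots"):
            if name in d:
                setattr(model, name + "_", np.asarray(d[name]))
        return model
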