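"""Regression-standardised marginal relative survival and excess hazard.

A fitted stage-specific model predicts conditional relative survival
``R(t | x)``; the marginal (age-standardised) quantity averages those
predictions over a *standard population* — here the empirical (age, sex) rows
of subjects diagnosed in a reference year (2017 by default), shared across
stages so stage curves are comparable:

    Rbar(t) = sum_i w_i R(t | x_i)
    lbar(t) = sum_i w_i R(t | x_i) l(t | x_i) / sum_i w_i R(t | x_i)

(the survivor-weighted mean excess hazard among those still alive in the
standardised population, so that lbar = -d/dt ln Rbar).  Pointwise variances
come from the delta method: the standardised functional is differentiated
numerically with respect to the model coefficients and sandwiched with their
covariance.

Across multiply imputed data sets, curves are pooled with Rubin's rules on the
complementary log-log scale g(R) = ln(-ln R) (which keeps back-transformed
confidence limits inside [0, 1]): pooled g is the mean, total variance
``T = W + (1 + 1/m) B`` with W the mean within-imputation variance and B the
between-imputation sample variance of g.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "StandardPopulation",
    "build_standard_population",
    "marginal_rs",
    "marginal_eh",
    "rubin_combine",
    "MarginalCurve",
]


@dataclass(frozen=True)
class StandardPopulation:
    """Covariate rows (age, female flag) with normalised non-negative weights."""

    age: np.ndarray
    female: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.weights, float)
        if np.any(w < 0) or not np.isclose(w.sum(), 1.0, atol=1e-12):
            raise ValueError("weights must be non-negative and sum to 1")

    def __len__(self):
        return self.age.shape[0]


def build_standard_population(cohort: pd.DataFrame, year: int = 2017, age_only: bool = False) -> StandardPopulation:
    """Empirical standard population from the subjects diagnosed in ``year``.

    One row per subject with equal weights, standardising age and sex jointly.
    With ``age_only`` the same ages are used but sex is marginalised at the
    reference year's overall sex mix (each age row split into a female and a
    male row with the corresponding sub-weights).
    """
    years = cohort["dx_year"] if "dx_year" in cohort else pd.to_datetime(cohort["dx_date"]).dt.year
    sel = cohort.loc[years.to_numpy() == year]
    if sel.empty:
        raise ValueError(f"no subjects diagnosed in {year}")
    age = sel["age_at_dx"].to_numpy(float)
    female = (sel["sex"] == "female").to_numpy(float)
    n = len(sel)
    if not age_only:
        return StandardPopulation(age=age, female=female, weights=np.full(n, 1.0 / n))
    pf = float(female.mean())
    age2 = np.concatenate([age, age])
    fem2 = np.concatenate([np.ones(n), np.zeros(n)])
    w2 = np.concatenate([np.full(n, pf / n), np.full(n, (1 - pf) / n)])
    return StandardPopulation(age=age2, female=fem2, weights=w2)


def _marginal_point(fit, sp: StandardPopulation, t: float, theta=None, what: str = "rs") -> float:
    tt = np.full(len(sp), float(t))
    R = fit.predict_survival(tt, sp.age, sp.female, theta=theta)
    if what == "rs":
        return float(np.sum(sp.weights * R))
    lam = fit.predict_excess_hazard(tt, sp.age, sp.female, theta=theta)
    wr = sp.weights * R
    return float(np.sum(wr * lam) / np.sum(wr))


def _delta_var(fit, sp, t, what, eps: float = 1e-6) -> float:
    """Delta-method variance: numerical Jacobian of the standardised functional."""
    theta = fit.coef_
    grad = np.empty(theta.size)
    for j in range(theta.size):
        h = eps * max(1.0, abs(theta[j]))
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        grad[j] = (_marginal_point(fit, sp, t, tp, what) - _marginal_point(fit, sp, t, tm, what)) / (2 * h)
    return float(grad @ fit.cov_ @ grad)


def marginal_rs(fit, sp: StandardPopulation, tgrid, variance: bool = True):
    """Marginal relative survival on ``tgrid`` with delta-method variances.

    Returns a DataFrame with columns t, estimate, var.
    """
    tgrid = np.asarray(tgrid, float)
    est = np.array([_marginal_point(fit, sp, t, what="rs") for t in tgrid])
    var = (
        np.array([_delta_var(fit, sp, t, "rs") for t in tgrid]) if variance else np.zeros_like(est)
    )
    return pd.DataFrame({"t": tgrid, "estimate": est, "var": var})


def marginal_eh(fit, sp: StandardPopulation, tgrid, variance: bool = True):
    """Marginal excess hazard (survivor-weighted) on ``tgrid``."""
    tgrid = np.asarray(tgrid, float)
    est = np.array([_marginal_point(fit, sp, t, what="eh") for t in tgrid])
    var = (
        np.array([_delta_var(fit, sp, t, "eh") for t in tgrid]) if variance else np.zeros_like(est)
    )
    return pd.DataFrame({"t": tgrid, "estimate": est, "var": var})


@dataclass
class MarginalCurve:
    """Rubin-pooled marginal curve with within/between variance decomposition."""

    t: np.ndarray
    estimate: np.ndarray  # survival scale
    W: np.ndarray
    B: np.ndarray
    T: np.ndarray
    m: int
    scale: str = "cloglog"

    def ci(self, level: float = 0.95):
        """Confidence limits, computed on the pooling scale and back-transformed."""
        z = norm.ppf(0.5 + level / 2)
        if self.scale == "cloglog":
            g = np.log(-np.log(np.clip(self.estimate, 1e-15, 1 - 1e-15)))
            lo = np.exp(-np.exp(g + z * np.sqrt(self.T)))
            hi = np.exp(-np.exp(g - z * np.sqrt(self.T)))
        else:
            lo = self.estimate - z * np.sqrt(self.T)
            hi = self.estimate + z * np.sqrt(self.T)
        return lo, hi

    def to_frame(self) -> pd.DataFrame:
        lo, hi = self.ci()
        return pd.DataFrame(
            {"t": self.t, "estimate": self.estimate, "W": self.W, "B": self.B, "T": self.T, "lo": lo, "hi": hi}
        )


def _cloglog(r):
    return np.log(-np.log(np.clip(r, 1e-15, 1 - 1e-15)))


def rubin_combine(curves: list[pd.DataFrame], m: int | None = None, scale: str = "cloglog") -> MarginalCurve:
    """Pool per-imputation marginal curves with Rubin's rules.

    ``curves`` are DataFrames from :func:`marginal_rs` on identical time
    grids.  On the cloglog scale the per-imputation delta-method variances are
    transformed with ``dg/dR = 1 / (R ln R)`` before averaging.
    """
    if not curves:
        raise ValueError("no curves to pool")
    m = len(curves) if m is None else m
    if m != len(curves):
        raise ValueError(f"m={m} but {len(curves)} curves supplied")
    t = curves[0]["t"].to_numpy()
    for c in curves[1:]:
        if not np.array_equal(c["t"].to_numpy(), t):
            raise ValueError("curves must share an identical time grid")
    est = np.stack([c["estimate"].to_numpy() for c in curves])
    var = np.stack([c["var"].to_numpy() for c in curves])
    if not (np.all(np.isfinite(est)) and np.all(np.isfinite(var))):
        raise ValueError("non-finite inputs to Rubin pooling")

    if scale == "cloglog":
        g = _cloglog(est)
        dg = 1.0 / (np.clip(est, 1e-15, None) * np.abs(np.log(np.clip(est, 1e-15, 1 - 1e-15))))
        gvar = var * dg**2
    else:
        g, gvar = est, var

    gbar = g.mean(axis=0)
    W = gvar.mean(axis=0)
    B = g.var(axis=0, ddof=1) if m >= 2 else np.zeros_like(gbar)
    T = W + (1 + 1 / m) * B
    point = np.exp(-np.exp(gbar)) if scale == "cloglog" else gbar
    return MarginalCurve(t=t, estimate=point, W=W, B=B, T=T, m=m, scale=scale)
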