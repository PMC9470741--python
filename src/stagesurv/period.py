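"""Period analysis: delayed entry into a recent calendar window.

A period analysis keeps only the person-time falling inside a recent calendar
window (here 2015-2017 by default), so that short-term survival reflects
recently diagnosed patients and long-term survival reflects earlier diagnoses
that are still under follow-up.  Subjects enter the risk set at
``t0 = max(0, window_start - dx_date)`` years after diagnosis (left
truncation), exit at the earliest of their own follow-up, the end of the
window and a follow-up cap, and are retained only if ``t1 > t0``.

Each retained subject is also labelled with the era of their diagnosis
relative to the *pre-window* (the span of calendar time immediately before the
window in which stage recording is assumed sufficiently complete); the
imputation conditions act on these labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DAYS_PER_YEAR = 365.25

__all__ = ["PeriodSpec", "apply_period"]


@dataclass(frozen=True)
class PeriodSpec:
    window_start: str = "2015-01-01"
    window_end: str = "2017-12-31"  # inclusive
    prewindow_start: str = "2012-01-01"
    max_followup: float = 10.0

    def __post_init__(self):
        if not (pd.Timestamp(self.prewindow_start) <= pd.Timestamp(self.window_start) < pd.Timestamp(self.window_end)):
            raise ValueError("need prewindow_start <= window_start < window_end")
        if self.max_followup <= 0:
            raise ValueError("max_followup must be positive")


def apply_period(cohort: pd.DataFrame, spec: PeriodSpec = PeriodSpec()) -> pd.DataFrame:
    """Build the period frame: columns t0, t1, d, era appended; non-contributing rows dropped.

    Years are day counts divided by 365.25.  Deaths after the (inclusive)
    window end or after the follow-up cap are censored at the boundary; deaths
    exactly at the cap count as events.
    """
    if (cohort["time"] <= 0).any():
        raise ValueError("follow-up times must be positive")
    ws = pd.Timestamp(spec.window_start)
    we_excl = pd.Timestamp(spec.window_end) + pd.Timedelta(days=1)
    pws = pd.Timestamp(spec.prewindow_start)

    dx = pd.to_datetime(cohort["dx_date"])
    t0 = np.maximum(0.0, (ws - dx).dt.days.to_numpy() / DAYS_PER_YEAR)
    t_window = (we_excl - dx).dt.days.to_numpy() / DAYS_PER_YEAR
    time = cohort["time"].to_numpy(float)
    t1 = np.minimum.reduce([time, t_window, np.full(len(cohort), float(spec.max_followup))])
    # Event only if the subject's own death time survives the truncation.
    d = ((cohort["event"].to_numpy() == 1) & (time <= t_window) & (time <= spec.max_followup)).astype(int)

    keep = t1 > t0
    out = cohort.loc[keep].copy()
    out["t0"] = t0[keep]
    out["t1"] = t1[keep]
    out["d"] = d[keep]
    era = np.where(
        dx >= ws, "in_window", np.where(dx >= pws, "pre_window", "pre_prewindow")
    )
    out["era"] = era[keep]
    return out.reset_index(drop=True)
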