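"""Calendar- and stage-conditional removal of observed stage.

To emulate registries whose historical stage recording is poor, observed stage
is set to missing with a probability that depends on true stage and calendar
year of diagnosis:

* anchored at 35% for regional cancers diagnosed in 2011, increasing by
  5 percentage points per earlier calendar year (65% by 2005);
* distant cancers 7 percentage points more likely, localised 7 points less
  likely, than regional cancers diagnosed in the same year;
* diagnoses in 2012 and later lose stage with a flat 20% probability,
  independent of stage and year (recent recording is more complete, so only a
  uniform degradation is applied there).

True stage is never touched, so imputation quality can be scored against the
retained truth.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import MISSING, STAGES

logger = logging.getLogger(__name__)

__all__ = ["MissingnessSpec", "removal_probability", "apply_missingness"]


@dataclass(frozen=True)
class MissingnessSpec:
    """Parameters of the stage-removal mechanism."""

    regional_base: float = 0.35
    anchor_year: int = 2011
    increment: float = 0.05
    earliest_year: int = 2005
    stage_offsets: tuple[float, float, float] = (-0.07, 0.0, 0.07)  # localised, regional, distant
    recent_addition: float = 0.20
    recent_from_year: int = 2012
    seed: int = 0
    exact_counts: bool = False

    def __post_init__(self):
        if self.increment < 0:
            raise ValueError("increment must be non-negative")
        if not 0 <= self.recent_addition <= 1:
            raise ValueError("recent_addition must be a probability")

    def offset(self, stage: str) -> float:
        return dict(zip(STAGES, self.stage_offsets))[stage]


def removal_probability(spec: MissingnessSpec, stage_true, dx_year):
    """Probability that a subject's observed stage is set to missing.

    Vectorised over ``stage_true`` / ``dx_year``.  Diagnoses in
    ``spec.recent_from_year`` or later get the flat recent probability
    regardless of stage; earlier diagnoses get the anchored arithmetic
    sequence plus the stage offset.  Probabilities outside [0, 1] are clamped
    with a warning.
    """
    stage = np.asarray(stage_true, dtype=object)
    year = np.asarray(dx_year, dtype=int)
    offsets = np.zeros(stage.shape)
    for st, off in zip(STAGES, spec.stage_offsets):
        offsets[stage == st] = off
    early = spec.regional_base + spec.increment * (spec.anchor_year - year) + offsets
    p = np.where(year >= spec.recent_from_year, spec.recent_addition, early)
    if np.any((p < 0) | (p > 1)):
        warnings.warn("removal probabilities clamped to [0, 1]", stacklevel=2)
        p = np.clip(p, 0.0, 1.0)
    if np.isscalar(dx_year) and isinstance(stage_true, str):
        return float(p)
    return p


def apply_missingness(cohort: pd.DataFrame, spec: MissingnessSpec) -> pd.DataFrame:
    """Return a copy of ``cohort`` with extra stage_obs entries set to missing.

    Each currently non-missing subject is independently masked with probability
    ``removal_probability(spec, stage_true, dx_year)`` (already-missing rows
    are never re-drawn and never resurrected).  With ``spec.exact_counts`` the
    mechanism instead masks ``round(p * n_cell)`` subjects per
    (stage, year) cell, chosen uniformly.  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    out = cohort.copy()
    dx_year = out["dx_year"].to_numpy() if "dx_year" in out else pd.to_datetime(out["dx_date"]).dt.year.to_numpy()
    eligible = (out["stage_obs"] != MISSING).to_numpy()
    p = removal_probability(spec, out["stage_true"].to_numpy(), dx_year)

    if spec.exact_counts:
        mask = np.zeros(len(out), dtype=bool)
        for (st, yr), idx in pd.DataFrame({"s": out["stage_true"], "y": dx_year}).groupby(["s", "y"]).groups.items():
            idx = np.asarray(idx)
            idx = idx[eligible[idx]]
            k = int(round(removal_probability(spec, st, int(yr)) * idx.size))
            if k > 0:
                mask[rng.choice(idx, size=k, replace=False)] = True
    else:
        mask = eligible & (rng.random(len(out)) < p)

    out.loc[mask, "stage_obs"] = MISSING
    n_masked = int(mask.sum())
    logger.info("masked stage for %d of %d eligible subjects", n_masked, int(eligible.sum()))
    return out
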