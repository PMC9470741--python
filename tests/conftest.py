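import numpy as np
import pandas as pd
import pytest

import stagesurv as sg


@pytest.fixture(scope="session")
def lifetable():
    return sg.synth_lifetable()


@pytest.fixture(scope="session")
def null_lifetable():
    """All-zero expected mortality: net survival equals observed survival."""
    zero = np.zeros((25, 100))
    return sg.LifeTable(rates={"female": zero.copy(), "male": zero.copy()}, year_min=2005)


@pytest.fixture(scope="session")
def small_cohort(lifetable):
    return sg.fixture_cohort(n=200, seed=12345, lt=lifetable)


@pytest.fixture(scope="session")
def period_frame(lifetable):
    """Medium period frame with injected missingness, shared across tests."""
    cohort = sg.generate_cohort(sg.CohortSpec(n=12000, seed=99), lifetable)
    masked = sg.apply_missingness(cohort, sg.MissingnessSpec(seed=100))
    return sg.apply_period(masked, sg.PeriodSpec()), cohort


def random_period_frame(rng, n):
    """Small random frame with delayed entry and ties, for oracle checks."""
    t0 = np.where(rng.random(n) < 0.5, 0.0, rng.uniform(0, 3, n))
    gap = rng.choice([0.25, 0.5, 1.0, 1.7], size=n) * rng.integers(1, 5, n)
    t1 = t0 + gap
    d = (rng.random(n) < 0.6).astype(int)
    return pd.DataFrame({"t0": t0, "t1": t1, "d": d})
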