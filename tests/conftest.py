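import numpy as np
import pytest

from cmskinetics import (
    ConcentrationSeries,
    ReversibleRateParams,
    StudyDesign,
    closed_form_remaining,
    hydrolysis_sampling_schedule,
)

#: Published fitted forward rate constants (min^-1) at the accelerated
#: temperatures, used throughout as the canonical worked example.
RATES_BY_TEMP = {40.0: 0.0146, 50.0: 0.0709, 60.0: 0.4485}
REVERSE_BY_TEMP = {40.0: 2.2e-3, 50.0: 3.54e-3, 60.0: 2.11e-3}


@pytest.fixture
def schedule():
    return hydrolysis_sampling_schedule(130.0)


@pytest.fixture
def noiseless_design():
    return StudyDesign(noise_cv=0.0, seed=0)


@pytest.fixture
def noiseless_series_50C(schedule):
    """Exact reversible trajectory at the published 50 C rate constants."""
    params = ReversibleRateParams(RATES_BY_TEMP[50.0], REVERSE_BY_TEMP[50.0])
    return ConcentrationSeries(
        times=schedule,
        values=closed_form_remaining(100.0, params, schedule),
        temperature_C=50.0,
    ), params


def noisy_series(params, noise_cv, seed, schedule=None):
    if schedule is None:
        schedule = hydrolysis_sampling_schedule(130.0)
    clean = closed_form_remaining(100.0, params, schedule)
    rng = np.random.default_rng(seed)
    vals = clean * (1.0 + rng.normal(0.0, noise_cv, schedule.size))
    vals[0] = 100.0
    return ConcentrationSeries(times=schedule, values=np.clip(vals, 0.0, None))
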