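import numpy as np
import pytest

from acylnmr import (
    AcquisitionSchedule,
    LaggedMonoExpParams,
    ProgressCurve,
    SiteRateProfile,
    aggregate_curve,
    eval_lagged_mono_exp,
)
from acylnmr import constants as C


@pytest.fixture
def schedule():
    """Default serial-HSQC schedule: deadtime 5 min, 3.6 min/experiment, ~4 h."""
    return AcquisitionSchedule()


@pytest.fixture
def short_schedule():
    return AcquisitionSchedule(deadtime=5.0, experiment_length=3.6, n_experiments=20)


@pytest.fixture
def two_class_profile():
    """3 fast + 2 slow sites at the p300Δ bi-exponential acetylation rates."""
    k1, k2 = C.ACETYL_BI_K["p300d"]
    return SiteRateProfile.two_class(k1, k2)


@pytest.fixture
def equal_rate_profile():
    """Five equivalent sites at the wild-type mono-exponential acetylation rate."""
    return SiteRateProfile(site_rates=(C.ACETYL_MONO_K["p300"],) * 5)


@pytest.fixture
def biexp_curve(two_class_profile, schedule):
    return aggregate_curve(two_class_profile, schedule, label="p300d-acetyl")


@pytest.fixture
def lagged_curve(schedule):
    """Noiseless lag-phase curve with the wild-type propionylation parameters."""
    k, t0 = C.PROPIONYL_LAGGED["p300"]
    params = LaggedMonoExpParams(a=1.0, k=k, t0=t0, alpha=0.5, c=0.0)
    t = schedule.times()
    return ProgressCurve(
        times=t,
        intensities=eval_lagged_mono_exp(params, t),
        label="p300-propionyl",
        deadtime=schedule.deadtime,
        experiment_length=schedule.experiment_length,
    ), params
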