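import numpy as np
import pytest

from sfrtkit import (
    MBRT_GEOMETRY,
    MRT_GEOMETRY,
    A549_LQ,
    RegrowthParams,
)
from sfrtkit.cohort import measurement_schedule

# Reference treated kinetics: 60% killed fraction shrinking at 0.15/day and
# regrowth rates placing the tripling time at 33 + {11.1, 20.2, 34.9} days.
TREATED_ALPHA2 = {"CRT": 0.045683, "MBRT": 0.037873, "MRT": 0.029674}
CONTROL_ALPHA2 = 0.0332913
TRUE_DELAYS = {"CRT": 11.1, "MBRT": 20.2, "MRT": 34.9}


@pytest.fixture(scope="session")
def mrt_geometry():
    return MRT_GEOMETRY


@pytest.fixture(scope="session")
def mbrt_geometry():
    return MBRT_GEOMETRY


@pytest.fixture(scope="session")
def a549_lq():
    return A549_LQ


@pytest.fixture(scope="session")
def control_params():
    return RegrowthParams.pure_exponential(CONTROL_ALPHA2)


@pytest.fixture(scope="session")
def crt_params():
    return RegrowthParams.from_free(0.6, 0.15, TREATED_ALPHA2["CRT"])


@pytest.fixture(scope="session")
def schedule_90d():
    """Mon/Wed/Fri measurement days over a 90-day follow-up."""
    return measurement_schedule(90.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260101)
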