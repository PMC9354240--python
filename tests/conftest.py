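import numpy as np
import pytest

from guvmotors.params import (
    AcquisitionParams,
    CompartmentParams,
    MotorParams,
    Trajectory,
    bulk_compartment,
)


@pytest.fixture
def motor():
    return MotorParams()


@pytest.fixture
def clean_acq():
    """Default video acquisition but with the localization error off, for
    tests that check the physical core against closed-form laws."""
    return AcquisitionParams(localization_sd=0.0)


@pytest.fixture
def short_acq():
    """Short noise-free acquisition for cheap tests."""
    return AcquisitionParams(duration=10.0, localization_sd=0.0)


@pytest.fixture
def bulk():
    return bulk_compartment()


@pytest.fixture
def small_guv():
    return CompartmentParams(R_guv=7.0)


def make_trajectory(xy, dt=1.0, particle_id=0):
    xy = np.asarray(xy, dtype=float)
    return Trajectory(particle_id=particle_id,
                      times=np.arange(len(xy)) * dt, xy=xy)


@pytest.fixture
def toy_trajectory():
    """Hand-checkable 5-frame staircase path at 1 s spacing."""
    return make_trajectory([(0, 0), (1, 0), (1, 1), (2, 1), (2, 2)])
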