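import numpy as np
import pytest

from pirogue.hmm_core import StateEmission
from pirogue.synthetic_data import GearProfile, simulate_trip
from pirogue.trackio import Trip


def make_trip(coords, t0="2014-03-01T06:00:00", dt=5, trip_id="t1", gear=None, interval_s=None):
    """Trip from a list of (lat, lon), fixed spacing dt seconds."""
    lat, lon = zip(*coords)
    times = np.datetime64(t0) + (np.arange(len(coords)) * dt).astype("timedelta64[s]")
    return Trip(trip_id=trip_id, times=times, lat=np.array(lat), lon=np.array(lon),
                gear=gear, interval_s=interval_s)


@pytest.fixture
def separated_profile():
    """Well-separated 2-state profile (step-mean ratio 10, diagonal A 0.95)."""
    return GearProfile(
        gear="PS",
        emissions=(
            StateEmission(step_mean=4.0, step_sd=2.0, angle_mean=0.0, angle_concentration=0.5),
            StateEmission(step_mean=40.0, step_sd=12.0, angle_mean=0.0, angle_concentration=10.0),
        ),
        A=np.array([[0.95, 0.05], [0.05, 0.95]]),
        trip_duration_h=(2.5, 2.5),
        min_fishing_event_s=5.0,
        start_area=((-0.5, 0.5), (9.0, 9.6)),
        heading_persistence=10.0,
    )


@pytest.fixture
def small_sim(separated_profile):
    """One simulated trip of 500 intervals."""
    return simulate_trip(separated_profile, seed=42, duration_h=500 * 5 / 3600.0)
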