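import numpy as np
import pytest

from sealscape.simulate import (
    SeascapeSpec,
    TripSpec,
    generate_seascape,
    generate_trip,
)

SHORT_RANGE = (0.5, 7.0)


@pytest.fixture(scope="session")
def seascape():
    return generate_seascape(SeascapeSpec(n_rows=120, n_cols=120), seed=1)


@pytest.fixture(scope="session")
def neutral_trip(seascape):
    spec = TripSpec(
        duration_d=1.0, duration_range=SHORT_RANGE, seed=11, attraction_strength=0.0
    )
    return generate_trip(seascape, spec)


@pytest.fixture(scope="session")
def attraction_trip(seascape):
    spec = TripSpec(
        duration_d=1.0, duration_range=SHORT_RANGE, seed=11, attraction_strength=5.0
    )
    return generate_trip(seascape, spec)


@pytest.fixture(scope="session")
def processed_trip(seascape, attraction_trip):
    """Attraction trip run through dive and track processing."""
    from sealscape import dives, tracks

    series = dives.zero_offset_correct(attraction_trip.depth)
    dive_list = dives.detect_dives(series)
    dive_list, nadir = dives.classify_dives(dive_list)
    traj = tracks.Trajectory(
        times=attraction_trip.fixes["time"].to_numpy(),
        x=attraction_trip.fixes["x"].to_numpy(),
        y=attraction_trip.fixes["y"].to_numpy(),
    )
    traj = tracks.interpolate_track(tracks.speed_filter(traj), 600.0)
    located, _ = tracks.merge_dives(traj, dive_list)
    return {
        "dives": dive_list,
        "nadir": nadir,
        "traj": traj,
        "located": located,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
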