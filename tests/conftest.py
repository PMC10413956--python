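import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from foragepath.data import Dataset, Fix, Observation
from foragepath.simulate import SimulationConfig, generate_dataset, preset

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
    max_examples=50,
)
settings.load_profile("ci")


def make_observation(coords, obs_id="obs1", lizard_id="liz1", species="visual",
                     habitat=None, visible=None, temp=None, wind=None,
                     sex="F", svl=100.0):
    """Observation from a coordinate list, with optional per-fix extras."""
    fixes = []
    for i, (x, y) in enumerate(coords):
        hab = habitat[i] if habitat else "open"
        fixes.append(
            Fix(
                t=i, x=float(x), y=float(y), habitat=hab,
                plant_species="sage" if hab == "vegetation" else None,
                visible_from_previous=None if i == 0 else (visible[i] if visible else None),
                air_temp_c=temp[i] if temp else None,
                wind_speed_ms=wind[i] if wind else None,
            )
        )
    return Observation(observation_id=obs_id, lizard_id=lizard_id,
                       species=species, sex=sex, svl_mm=svl, mass_g=20.0,
                       fixes=fixes)


@pytest.fixture
def straight_obs():
    """31 fixes marching east at 1 m/min."""
    return make_observation([(float(i), 0.0) for i in range(31)])


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def field_scale_dataset():
    """Two-preset dataset at the field sample sizes (61 + 51 follows)."""
    config = SimulationConfig(
        n_per_species={"visual": 61, "chemosensory": 51}, master_seed=7)
    return generate_dataset(config, [preset("visual"), preset("chemosensory")])


def random_walk_observation(rng, n_fixes=31, p_move=0.7, obs_id="w", species="visual"):
    pos = rng.uniform(0, 50, size=2)
    coords = [tuple(pos)]
    heading = rng.uniform(-np.pi, np.pi)
    for _ in range(n_fixes - 1):
        if rng.random() < p_move:
            heading += rng.vonmises(0.0, 1.0)
            step = rng.lognormal(0.5, 0.8)
            pos = pos + step * np.array([np.cos(heading), np.sin(heading)])
        coords.append(tuple(pos))
    return make_observation(coords, obs_id=obs_id, lizard_id=obs_id, species=species)
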