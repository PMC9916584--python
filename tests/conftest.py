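import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pointback.geometry import PathSpec, build_path
from pointback.synth import make_study_paths

settings.register_profile(
    "default", deadline=None, max_examples=50, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def crossed_spec():
    return PathSpec((3.0, 2.0, 1.5, 3.0), path_id="cross-ex")


@pytest.fixture(scope="session")
def short_l4_spec():
    return PathSpec((3.0, 2.0, 1.5, 1.0), path_id="short-ex")


@pytest.fixture(scope="session")
def long_l3_spec():
    return PathSpec((3.0, 2.0, 4.0, 3.0), path_id="long-ex", arena_bound=4.0)


@pytest.fixture(scope="session")
def crossed_geom(crossed_spec):
    return build_path(crossed_spec)


@pytest.fixture(scope="session")
def short_l4_geom(short_l4_spec):
    return build_path(short_l4_spec)


@pytest.fixture(scope="session")
def long_l3_geom(long_l3_spec):
    return build_path(long_l3_spec)


@pytest.fixture(scope="session")
def fixture_geoms(crossed_geom, short_l4_geom, long_l3_geom):
    """Canonical example paths plus both seeded synthetic path families."""
    geoms = [crossed_geom, short_l4_geom, long_l3_geom]
    for exp, seed in ((1, 11), (2, 12)):
        geoms.extend(build_path(s) for s in make_study_paths(exp, seed=seed))
    return geoms


@pytest.fixture()
def rng():
    return np.random.default_rng(20230210)
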