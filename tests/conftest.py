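import warnings

import numpy as np
import pytest

from wormsim.body import BodySpec, build_worm_body
from wormsim.fixtures import make_fluid_scene


@pytest.fixture(scope="session")
def default_body():
    """One canonical worm body shared by read-only tests."""
    return build_worm_body(BodySpec())


@pytest.fixture()
def fresh_body():
    return build_worm_body(BodySpec())


@pytest.fixture()
def droplet():
    sys_, _ = make_fluid_scene("DROPLET", n_particles=150, seed=0)
    return sys_


@pytest.fixture()
def dam_break():
    return make_fluid_scene("DAM_BREAK", n_particles=300, seed=0)


@pytest.fixture(autouse=True)
def _no_cfl_warnings_noise():
    """Keep CFL advisories from failing -W error configurations."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        yield


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
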