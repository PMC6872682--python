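import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from rootaxis.mesh import Region, extract_region
from rootaxis.synth import Jaw, ToothParams, ToothType, generate_tooth

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def canine():
    """A canonical labeled mandibular canine with its true root axis."""
    params = ToothParams.for_type(ToothType.CANINE, Jaw.MANDIBLE)
    mesh, axis = generate_tooth(params, seed=1)
    return params, mesh, axis


@pytest.fixture(scope="session")
def canine_root(canine):
    _, mesh, _ = canine
    return extract_region(mesh, Region.ROOT)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
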