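import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20240416)


@pytest.fixture(scope="session")
def small_demo():
    """A small multi-lesion study volume shared across end-to-end tests."""
    from wmh_morph import synthetic_fixtures as synth

    return synth.make_demo_volume(
        seed=3,
        n_per_family=2,
        grid=(120, 120, 9),
        size_range=(14, 20),
        edge_width_range=(2, 4),
    )


def make_lesion(intensities, gmin=None, gmax=None):
    """Minimal stand-in for a 3D-linked lesion (synthetic, single component)."""
    from types import SimpleNamespace

    arr = np.asarray(intensities, dtype=float)
    return SimpleNamespace(
        intensities=arr,
        component_intensities=[arr],
        gmin=float(arr.min() if gmin is None else gmin),
        gmax=float(arr.max() if gmax is None else gmax),
    )
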