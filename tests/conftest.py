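import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cmrpump.phantom import LVGeometry, Motion, PhantomSpec, Sampling, generate_phantom

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def square(cx: float, cy: float, side: float) -> np.ndarray:
    h = side / 2.0
    return np.array(
        [[cx - h, cy - h], [cx + h, cy - h], [cx + h, cy + h], [cx - h, cy + h]]
    )


@pytest.fixture(scope="session")
def default_phantom():
    """Healthy-motion mixed phantom (20 slices x 128 vertices)."""
    spec = PhantomSpec()
    bundle, truth = generate_phantom(spec)
    return bundle, truth


@pytest.fixture(scope="session")
def pure_translation_phantom():
    spec = PhantomSpec(
        motion=Motion(
            avpd_lv=15.0,
            avpd_rv=15.0,
            radial_fraction_lv=0.0,
            radial_fraction_rv=0.0,
            septal_shift=0.0,
        )
    )
    bundle, truth = generate_phantom(spec)
    return bundle, truth


@pytest.fixture(scope="session")
def pure_radial_phantom():
    spec = PhantomSpec(
        motion=Motion(
            avpd_lv=0.0,
            avpd_rv=0.0,
            radial_fraction_lv=0.1,
            radial_fraction_rv=0.05,
            septal_shift=0.0,
        )
    )
    bundle, truth = generate_phantom(spec)
    return bundle, truth


@pytest.fixture(scope="session")
def small_phantom():
    """Coarse phantom for IO/CLI tests: 4 slices x 32 vertices."""
    spec = PhantomSpec(sampling=Sampling(n_slices=4, n_vertices=32, thickness=25.0))
    bundle, truth = generate_phantom(spec)
    return bundle, truth
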