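import numpy as np
import pytest

from ldq.geometry import Geometry
from ldq.phantom import PhantomSpec, generate_phantom

#: Small grid with the same 128 x 128 x 96 mm field of view as the default
#: phantom, so all anatomy definitions (in mm) stay valid.
SMALL_GEOM = Geometry((32, 32, 16), (4.0, 4.0, 6.0))

#: Even smaller grid for network plumbing tests.
TINY_GEOM = Geometry((16, 16, 8), (8.0, 8.0, 12.0))


def small_spec(**kw) -> PhantomSpec:
    kw.setdefault("geometry", SMALL_GEOM)
    return PhantomSpec(**kw)


@pytest.fixture(scope="session")
def clean_phantom():
    """Noiseless, undeformed phantom: exact ground truth everywhere."""
    spec = small_spec(noise_sd=0.0, deformation_mm=0.0, seed=11, subject_id="clean")
    return (*generate_phantom(spec), spec)


@pytest.fixture(scope="session")
def noisy_phantom():
    """Phantom under the default study conditions (noise + deformation)."""
    spec = small_spec(seed=12, subject_id="noisy")
    return (*generate_phantom(spec), spec)


@pytest.fixture(scope="session")
def phantom_set():
    """Six deformed phantoms on the small grid, distinct seeds."""
    out = []
    for i in range(6):
        spec = small_spec(seed=100 + i, subject_id=f"s{i:02d}")
        vol, lmap, _ = generate_phantom(spec)
        out.append((vol, lmap))
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
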