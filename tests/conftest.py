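import numpy as np
import pytest

from liverseg.phantom import PhantomSpec, make_phantom_pair
from liverseg.registration import BoundaryPointSet


@pytest.fixture(scope="session")
def small_phantom():
    """64³ phantom pair shared by module tests (cheap, seeded)."""
    spec = PhantomSpec(shape=(64, 64, 64), organ_radii=(20.0, 18.0, 16.0), seed=7)
    return make_phantom_pair(spec)


@pytest.fixture(scope="session")
def default_phantom():
    """The standard 96³ phantom the pipeline-level checks are stated for."""
    return make_phantom_pair(PhantomSpec(seed=0))


def sphere_cloud(radius=20.0, n=56, npts=8000, cap_deg=None, seed=0):
    """Point cloud sampled on a sphere, optionally with a polar cap deleted."""
    rng = np.random.default_rng(seed)
    pts = rng.standard_normal((npts, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    if cap_deg is not None:
        pts = pts[pts[:, 2] < np.cos(np.radians(cap_deg))]
    vox = np.unique(np.round(pts * radius + n / 2).astype(int), axis=0)
    return BoundaryPointSet(points=vox, source="predicted")


@pytest.fixture(scope="session")
def sphere_points():
    return sphere_cloud()


@pytest.fixture(scope="session")
def capped_sphere_points():
    return sphere_cloud(cap_deg=30)
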