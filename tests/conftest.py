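import numpy as np
import pytest
import trimesh

from aerolung.io_core import SurfaceMesh
from aerolung.ssam import LandmarkSet


@pytest.fixture(scope="session")
def unit_sphere_mesh() -> SurfaceMesh:
    return SurfaceMesh.from_trimesh(trimesh.creation.icosphere(subdivisions=3))


@pytest.fixture()
def small_landmarks() -> LandmarkSet:
    rng = np.random.default_rng(7)
    return LandmarkSet(points=rng.normal(size=(12, 3)),
                       gray=rng.normal(size=(12, 2)))


def make_toy_cohort(n_samples=6, n_landmarks=5, n_projections=1, seed=0,
                    spread=0.1):
    """Small random cohort with consistent correspondence for PCA tests."""
    rng = np.random.default_rng(seed)
    base_pts = rng.normal(size=(n_landmarks, 3)) * 10
    base_gray = rng.normal(size=(n_landmarks, n_projections))
    cohort = []
    for _ in range(n_samples):
        cohort.append(LandmarkSet(
            points=base_pts + rng.normal(scale=spread,
                                         size=base_pts.shape) * 10,
            gray=base_gray + rng.normal(scale=spread, size=base_gray.shape)))
    return cohort
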