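"""Seeded generators of synthetic inputs with known ground truth.

Every stage of the pipeline is testable without clinical data: ellipsoidal
lung phantoms with an attached trachea stand in for CT labelmaps, landmark
populations with prescribed orthonormal variation modes stand in for a
corresponded training cohort, and surface point clouds with controllable
hotspots stand in for deposition records.  All generators are pure
functions of their arguments plus one explicit integer seed; there is no
global random state.

What the phantoms do NOT emulate: lobar fissures (invisible on a chest
radiograph and deliberately absent from the landmarking), rib cage and
soft-tissue clutter, and cartilaginous airway wall detail.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import trimesh

from .airway import AirwayTree
from .deposition import DepositionRecord
from .io_core import SurfaceMesh, VolumeImage
from .ssam import LandmarkSet

logger = logging.getLogger("aerolung")

__all__ = [
    "PopulationSpec",
    "LungPhantom",
    "make_lung_phantom",
    "make_population",
    "make_deposition_fixture",
    "ellipsoid_landmarks",
    "fibonacci_sphere",
]


class ResolutionError(ValueError):
    """Voxel spacing too coarse for the requested geometry."""


# ---------------------------------------------------------------------------
# lung labelmap phantom


@dataclass
class LungPhantom:
    labelmap: VolumeImage          # 0 bg, 1 left lung, 2 right lung, 3 airway
    lungs_mesh: SurfaceMesh
    tree: AirwayTree
    analytic_volumes: dict[str, float]
    lung_centers: np.ndarray
    half_axes: np.ndarray


def _segment_distance(points: np.ndarray, a: np.ndarray,
                      b: np.ndarray) -> np.ndarray:
    ab = b - a
    t = np.clip((points - a) @ ab / (ab @ ab), 0.0, 1.0)
    return np.linalg.norm(points - (a + t[:, None] * ab), axis=1)


def make_lung_phantom(half_axes=(60.0, 40.0, 90.0), spacing=2.0,
                      lung_gap: float = 20.0, trachea_diameter: float = 16.0,
                      bronchus_diameter: float = 12.0,
                      margin: float = 6.0,
                      include_airway: bool = True) -> LungPhantom:
    """Two ellipsoidal lungs with a cylindrical trachea and main bronchi.

    Lungs (labels 1 and 2) are ellipsoids with the given half-axes (mm),
    centred at ``x = -(a + gap/2)`` and ``+(a + gap/2)``; the airway (label
    3, overwriting lung labels) is a vertical trachea entering at the top
    midline plus two straight main bronchi angled into each lung.  The
    analytic lung volume 4/3 pi a b c is returned for convergence checks.
    """
    half_axes = np.asarray(half_axes, dtype=float)
    spacing = np.full(3, float(spacing)) if np.ndim(spacing) == 0 \
        else np.asarray(spacing, dtype=float)
    if np.any(half_axes <= 0) or np.any(spacing <= 0):
        raise ValueError("half-axes and spacing must be positive")
    if spacing.max() > half_axes.min():
        raise ResolutionError(
            f"voxel spacing {spacing.max()} mm exceeds the smallest half-axis "
            f"{half_axes.min()} mm")
    a, b, c = half_axes
    cx = a + lung_gap / 2
    centers = np.array([[-cx, 0.0, 0.0], [cx, 0.0, 0.0]])

    lo = np.array([-(2 * a + lung_gap / 2) - margin, -b - margin, -c - margin])
    hi = np.array([(2 * a + lung_gap / 2) + margin, b + margin,
                   c + 30.0 + margin])
    shape = np.ceil((hi - lo) / spacing).astype(int) + 1
    ax = [lo[d] + np.arange(shape[d]) * spacing[d] for d in range(3)]
    gx, gy, gz = np.meshgrid(*ax, indexing="ij")

    labels = np.zeros(tuple(shape), dtype=np.uint8)
    for lab, ctr in ((1, centers[0]), (2, centers[1])):
        inside = (((gx - ctr[0]) / a) ** 2 + ((gy - ctr[1]) / b) ** 2
                  + ((gz - ctr[2]) / c) ** 2) <= 1.0
        labels[inside] = lab

    # trachea: vertical cylinder on the midline, entering above the lungs
    carina = np.array([0.0, 0.0, c - 25.0])
    top = np.array([0.0, 0.0, c + 25.0])
    bronchus_ends = centers + np.array([[0.0, 0.0, c * 0.45],
                                        [0.0, 0.0, c * 0.45]])
    if include_airway:
        rt = trachea_diameter / 2
        in_trachea = (gx ** 2 + gy ** 2 <= rt ** 2) & (gz >= carina[2]) \
            & (gz <= top[2])
        labels[in_trachea] = 3
        # main bronchi: straight segments from the carina into each lung apex
        pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
        rb = bronchus_diameter / 2
        for end in bronchus_ends:
            d = _segment_distance(pts, carina, end).reshape(labels.shape)
            labels[d <= rb] = 3

    volume = VolumeImage(voxels=labels, spacing=spacing, origin=lo)

    sphere = trimesh.creation.icosphere(subdivisions=3)
    lung_meshes = []
    for ctr in centers:
        m = sphere.copy()
        m.apply_scale(half_axes)
        m.apply_translation(ctr)
        lung_meshes.append(m)
    lungs_mesh = SurfaceMesh.from_trimesh(trimesh.util.concatenate(lung_meshes))

    tree = AirwayTree()
    n_top = tree.add_node(top)
    n_car = tree.add_node(carina)
    trachea = tree.add_branch(parent=None, start=n_top, end=n_car, generation=0,
                              diameter=trachea_diameter)
    for end in bronchus_ends:
        n_end = tree.add_node(end)
        tree.add_branch(parent=trachea, start=n_car, end=n_end, generation=1,
                        diameter=bronchus_diameter)

    v_lung = 4.0 / 3.0 * np.pi * a * b * c
    return LungPhantom(labelmap=volume, lungs_mesh=lungs_mesh, tree=tree,
                       analytic_volumes={"left": v_lung, "right": v_lung},
                       lung_centers=centers, half_axes=half_axes)


# ---------------------------------------------------------------------------
# landmark populations


def fibonacci_sphere(n: int) -> np.ndarray:
    """n near-uniform unit-sphere directions (golden-angle spiral)."""
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(1.0 - z ** 2)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def ellipsoid_landmarks(half_axes, center, n: int) -> np.ndarray:
    """Landmarks on an ellipsoid surface with fixed correspondence order."""
    return fibonacci_sphere(n) * np.asarray(half_axes, dtype=float) \
        + np.asarray(center, dtype=float)


@dataclass
class PopulationSpec:
    """Recipe for a synthetic corresponded landmark cohort.

    Each sample is ``base + sum_m c_m direction_m + noise`` with
    ``c_m ~ N(0, sd_m^2)`` and isotropic entry-wise noise; directions are
    mutually orthogonal unit vectors over the flattened state.
    """

    n_samples: int
    base_landmarks: LandmarkSet
    modes: list = field(default_factory=list)  # (direction, sd) pairs
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 2:
            raise ValueError("need n_samples >= 2")
        dim = self.base_landmarks.state.size
        dirs = []
        for d, sd in self.modes:
            d = np.asarray(d, dtype=float)
            if d.size != dim:
                raise ValueError("mode direction length must match the state")
            if abs(np.linalg.norm(d) - 1.0) > 1e-8:
                raise ValueError("mode directions must be unit norm")
            dirs.append(d)
        for i in range(len(dirs)):
            for j in range(i + 1, len(dirs)):
                if abs(dirs[i] @ dirs[j]) > 1e-8:
                    raise ValueError("mode directions must be orthogonal")


def make_population(spec: PopulationSpec) -> list[LandmarkSet]:
    """Draw a reproducible cohort of landmark sets from a population spec."""
    rng = np.random.default_rng(spec.seed)
    base = spec.base_landmarks
    base_state = base.state
    samples = []
    for _ in range(spec.n_samples):
        state = base_state.copy()
        for direction, sd in spec.modes:
            state = state + rng.normal(0.0, sd) * np.asarray(direction)
        if spec.noise_sd > 0:
            state = state + rng.normal(0.0, spec.noise_sd, size=state.shape)
        samples.append(LandmarkSet.from_state(state, base.n_landmarks,
                                              base.n_projections,
                                              groups=base.groups))
    return samples


# ---------------------------------------------------------------------------
# deposition fixtures


def _sample_on_faces(tm: trimesh.Trimesh, face_idx: np.ndarray,
                     rng: np.random.Generator) -> np.ndarray:
    """Uniform barycentric point on each requested triangle."""
    tri = tm.triangles[face_idx]
    r1 = np.sqrt(rng.random(len(face_idx)))
    r2 = rng.random(len(face_idx))
    w = np.column_stack([1 - r1, r1 * (1 - r2), r1 * r2])
    return (w[:, :, None] * tri).sum(axis=1)


def _sample_surface(tm: trimesh.Trimesh, n: int, rng: np.random.Generator,
                    face_subset=None) -> np.ndarray:
    """Area-weighted uniform sampling over (a subset of) the surface."""
    faces = np.arange(len(tm.faces)) if face_subset is None \
        else np.asarray(face_subset)
    areas = tm.area_faces[faces]
    probs = areas / areas.sum()
    chosen = rng.choice(faces, size=n, p=probs)
    return _sample_on_faces(tm, chosen, rng)


def make_deposition_fixture(mesh: SurfaceMesh, hotspots=(),
                            background_count: int = 0,
                            seed: int = 0,
                            region_label: str = "wall") -> DepositionRecord:
    """Surface point cloud: uniform background plus concentrated hotspots.

    Background particles are uniform over the surface (area-weighted
    triangle choice, then barycentric); each hotspot ``(center, radius,
    count)`` draws its particles uniformly from the surface patch within
    ``radius`` of the centre.  Counts are exact and the point set is a pure
    function of the seed.
    """
    rng = np.random.default_rng(seed)
    tm = mesh.as_trimesh()
    points = []
    if background_count:
        points.append(_sample_surface(tm, background_count, rng))
    for center, radius, count in hotspots:
        if radius <= 0:
            raise ValueError("hotspot radius must be positive")
        center = np.asarray(center, dtype=float)
        reach = radius + tm.edges_unique_length.max()
        near = np.flatnonzero(
            np.linalg.norm(tm.triangles_center - center, axis=1) <= reach)
        if near.size == 0:
            raise ValueError("hotspot centre is not near the surface")
        got = []
        guard = 0
        while sum(len(g) for g in got) < count:
            guard += 1
            if guard > 1000:
                raise RuntimeError("hotspot sampling failed to converge")
            cand = _sample_surface(tm, max(4 * count, 64), rng,
                                   face_subset=near)
            keep = cand[np.linalg.norm(cand - center, axis=1) <= radius]
            got.append(keep)
        points.append(np.concatenate(got)[:count])
    all_pts = np.concatenate(points) if points else np.empty((0, 3))
    regions = np.full(len(all_pts), region_label)
    return DepositionRecord(positions=all_pts, regions=regions,
                            n_released=len(all_pts))
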