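"""Readers and writers for the external formats the framework touches.

Conventions
-----------
* Volumes are stored in (x, y, z) axis order; the y axis points
  anterior->posterior so a frontal radiograph integrates along axis 1.
* Voxel indices are 0-based; world coordinates are millimetres with the
  affine ``world = origin + index * spacing``.
* Landmark CSV files carry correspondence by row order, not by id matching:
  shuffling rows silently breaks correspondence and is NOT detected.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
import SimpleITK as sitk
import trimesh

from .ssam import LandmarkSet

logger = logging.getLogger("aerolung")

__all__ = [
    "FormatError",
    "SchemaError",
    "VolumeImage",
    "SurfaceMesh",
    "read_volume",
    "write_volume",
    "read_mesh",
    "write_mesh",
    "read_landmarks",
    "write_landmarks",
]

VOLUME_SUFFIXES = (".nii", ".nii.gz", ".mhd")


class FormatError(ValueError):
    """File payload does not match its declared format."""


class SchemaError(ValueError):
    """Tabular file is missing required columns or has bad cells."""


@dataclass
class VolumeImage:
    """A 3D scalar volume (Hounsfield units or integer labels).

    ``voxels`` has shape (nx, ny, nz); ``spacing`` and ``origin`` are
    millimetres per axis.
    """

    voxels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray | None = None

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or min(self.voxels.shape) < 1:
            raise ValueError("voxels must be a 3D array of shape >= (1,1,1)")
        self.spacing = np.asarray(self.spacing, dtype=float)
        if self.spacing.shape == ():
            self.spacing = np.full(3, float(self.spacing))
        if self.spacing.shape != (3,) or np.any(self.spacing <= 0):
            raise ValueError("spacing must be 3 positive values")
        if self.origin is None:
            self.origin = np.zeros(3)
        self.origin = np.asarray(self.origin, dtype=float)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def world_from_index(self, index) -> np.ndarray:
        return self.origin + np.asarray(index, dtype=float) * self.spacing

    def index_from_world(self, world) -> np.ndarray:
        return (np.asarray(world, dtype=float) - self.origin) / self.spacing


@dataclass
class SurfaceMesh:
    """Triangle surface mesh in millimetres with outward unit face normals."""

    vertices: np.ndarray
    faces: np.ndarray
    face_normals: np.ndarray | None = None

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.faces.size and (self.faces.min() < 0
                                or self.faces.max() >= len(self.vertices)):
            raise ValueError("face indices out of range")
        if self.face_normals is None and len(self.faces):
            self.face_normals = self.as_trimesh().face_normals.copy()
        if self.face_normals is not None and len(self.face_normals):
            norms = np.linalg.norm(self.face_normals, axis=1)
            bad = np.abs(norms - 1.0) > 1e-6
            if np.any(bad & (norms > 0)):
                self.face_normals = self.face_normals / norms[:, None]

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces,
                               process=False)

    @classmethod
    def from_trimesh(cls, tm: trimesh.Trimesh) -> "SurfaceMesh":
        return cls(vertices=np.asarray(tm.vertices, dtype=float),
                   faces=np.asarray(tm.faces, dtype=np.int64),
                   face_normals=np.asarray(tm.face_normals, dtype=float))

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)


def _volume_suffix(path: str) -> str:
    for suf in VOLUME_SUFFIXES:
        if path.endswith(suf):
            return suf
    raise FormatError(f"unsupported volume extension for {path!r} "
                      f"(expected one of {VOLUME_SUFFIXES})")


def read_volume(path) -> VolumeImage:
    """Read a NIfTI (.nii/.nii.gz) or MetaImage (.mhd + .raw) volume."""
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FormatError(f"volume file not found: {path}")
    _volume_suffix(path)
    try:
        img = sitk.ReadImage(path)
    except RuntimeError as exc:  # truncated payload, missing .raw companion...
        raise FormatError(f"could not read volume {path}: {exc}") from exc
    arr = sitk.GetArrayFromImage(img)  # (z, y, x)
    return VolumeImage(voxels=np.ascontiguousarray(arr.T),
                       spacing=np.asarray(img.GetSpacing()),
                       origin=np.asarray(img.GetOrigin()))


def write_volume(path, volume: VolumeImage) -> None:
    path = os.fspath(path)
    _volume_suffix(path)
    img = sitk.GetImageFromArray(np.ascontiguousarray(volume.voxels.T))
    img.SetSpacing(tuple(float(s) for s in volume.spacing))
    img.SetOrigin(tuple(float(o) for o in volume.origin))
    sitk.WriteImage(img, path)


def read_mesh(path) -> SurfaceMesh:
    """Read an STL surface (ASCII or binary dialect)."""
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FormatError(f"mesh file not found: {path}")
    try:
        tm = trimesh.load(path, file_type="stl", process=False)
    except Exception as exc:
        raise FormatError(f"could not read STL {path}: {exc}") from exc
    if not isinstance(tm, trimesh.Trimesh) or len(tm.faces) == 0:
        raise FormatError(f"no triangle data in {path}")
    tm.merge_vertices()  # STL stores a triangle soup; weld shared vertices
    n_degenerate = int((tm.area_faces <= 0).sum())
    if n_degenerate:
        logger.warning("%s: %d zero-area faces", path, n_degenerate)
    return SurfaceMesh.from_trimesh(tm)


def write_mesh(path, mesh: SurfaceMesh, binary: bool = True) -> None:
    path = os.fspath(path)
    tm = mesh.as_trimesh()  # SurfaceMesh already validated face indices
    if (tm.area_faces <= 0).any():
        logger.warning("%s: writing mesh with zero-area faces", path)
    tm.export(path, file_type="stl" if binary else "stl_ascii")


_LANDMARK_REQUIRED = ("id", "x", "y", "z")


def read_landmarks(path) -> LandmarkSet:
    """Read a landmark CSV with header ``id,x,y,z[,gray1[,gray2]]``.

    Row order defines correspondence across samples (the contract): two
    files whose rows were shuffled differently describe different shapes and
    no error is raised.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FormatError(f"landmark file not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in _LANDMARK_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    gray_cols = sorted(c for c in df.columns if c.startswith("gray"))
    numeric_cols = list(_LANDMARK_REQUIRED) + gray_cols
    for col in numeric_cols:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # 1-based, plus header line
            raise SchemaError(
                f"{path}: non-numeric value in column {col!r} at line {row}")
        df[col] = vals
    if df[numeric_cols].isna().any().any():
        raise SchemaError(f"{path}: empty cell in required column")
    pts = df[["x", "y", "z"]].to_numpy(dtype=float)
    gray = df[gray_cols].to_numpy(dtype=float) if gray_cols else None
    groups = df["group"].to_numpy() if "group" in df.columns else None
    return LandmarkSet(points=pts, gray=gray, groups=groups)


def write_landmarks(path, landmarks: LandmarkSet) -> None:
    data = {"id": np.arange(landmarks.n_landmarks),
            "x": landmarks.points[:, 0],
            "y": landmarks.points[:, 1],
            "z": landmarks.points[:, 2]}
    for j in range(landmarks.n_projections):
        data[f"gray{j + 1}"] = landmarks.gray[:, j]
    if landmarks.groups is not None:
        data["group"] = landmarks.groups
    pd.DataFrame(data).to_csv(os.fspath(path), index=False)
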