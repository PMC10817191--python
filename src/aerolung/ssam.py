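"""Statistical shape-and-appearance modelling of corresponded landmarks.

A cohort of corresponded landmark sets (each landmark carries its 3D
position and, optionally, the gray value sampled from one or two projection
radiographs) is aligned to zero mean and unit scale, stacked into state
vectors and decomposed by PCA.  The resulting linear generative model

    z ~= z_bar + sum_m Phi_m (b_m w_m)

produces new anatomies from a low-dimensional weight vector ``b``.  By
default ``b`` is expressed in standard-deviation units (``w_m = sigma_m``),
so the conventional fitting bound |b_m| <= 3 spans three SDs of the training
population; ``mode_weighting="variance"`` switches to ``w_m = sigma_m**2``.

State vector layout is block-wise: all landmark coordinates first
(x1,y1,z1,x2,...), then the gray-value block ``gray.ravel()`` (landmark-major,
projections contiguous per landmark).  Any fixed permutation of the
interleaved per-landmark layout spans the same linear space; the block layout
is simply easier to slice.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("aerolung")

__all__ = [
    "LandmarkSet",
    "AlignmentRecord",
    "ShapeAppearanceModel",
    "ZeroVarianceError",
    "CorrespondenceError",
    "DegenerateCohortError",
    "align_landmarks",
    "select_mode_count",
    "build_model",
    "reconstruct",
    "project",
    "assess_errors",
    "save_model",
    "load_model",
]


class ZeroVarianceError(ValueError):
    """All landmark coordinates identical; alignment scale undefined."""


class CorrespondenceError(ValueError):
    """Cohort members disagree on landmark count or projection count."""


class DegenerateCohortError(ValueError):
    """Cohort carries no variance; PCA is undefined."""


@dataclass
class LandmarkSet:
    """Ordered 3D landmarks with optional per-projection gray values.

    Order is the correspondence contract: landmark ``i`` refers to the same
    anatomical location in every member of a cohort.  ``groups`` optionally
    tags landmarks (e.g. ``"lung"`` / ``"airway"``) so that downstream steps
    can exclude airway landmarks from silhouette fitting.
    """

    points: np.ndarray
    gray: np.ndarray | None = None
    groups: np.ndarray | None = None

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must have shape (N, 3)")
        if self.gray is not None:
            self.gray = np.asarray(self.gray, dtype=float)
            if self.gray.ndim == 1:
                self.gray = self.gray[:, None]
            if self.gray.shape[0] != self.points.shape[0]:
                raise ValueError("gray must have one row per landmark")
            if not np.all(np.isfinite(self.gray)):
                raise ValueError("gray values must be finite")
        if self.groups is not None:
            self.groups = np.asarray(self.groups)
            if self.groups.shape[0] != self.points.shape[0]:
                raise ValueError("groups must have one entry per landmark")

    @property
    def n_landmarks(self) -> int:
        return self.points.shape[0]

    @property
    def n_projections(self) -> int:
        return 0 if self.gray is None else self.gray.shape[1]

    @property
    def state(self) -> np.ndarray:
        """Flattened state vector (coordinates block, then gray block)."""
        if self.gray is None:
            return self.points.ravel().copy()
        return np.concatenate([self.points.ravel(), self.gray.ravel()])

    @classmethod
    def from_state(cls, state, n_landmarks: int, n_projections: int = 0,
                   groups=None) -> "LandmarkSet":
        state = np.asarray(state, dtype=float)
        expected = (3 + n_projections) * n_landmarks
        if state.size != expected:
            raise ValueError(
                f"state length {state.size} != (3+{n_projections})*{n_landmarks}")
        pts = state[: 3 * n_landmarks].reshape(n_landmarks, 3)
        gray = None
        if n_projections:
            gray = state[3 * n_landmarks:].reshape(n_landmarks, n_projections)
        return cls(points=pts, gray=gray, groups=groups)


@dataclass
class AlignmentRecord:
    """Similarity transform removed from one sample during alignment.

    ``world = aligned * scale + translation`` restores the original frame.
    Gray normalisation statistics are stored per projection.
    """

    translation: np.ndarray
    scale: float
    gray_mean: np.ndarray | None = None
    gray_sd: np.ndarray | None = None

    def to_world(self, aligned_points: np.ndarray) -> np.ndarray:
        return aligned_points * self.scale + self.translation


def align_landmarks(landmarks: LandmarkSet) -> tuple[LandmarkSet, AlignmentRecord]:
    """Remove translation and isotropic scale; normalise gray per sample.

    Coordinates get zero mean and unit standard deviation, with the SD taken
    over all 3N flattened coordinate entries (population convention,
    ``ddof=0``).  Gray values are normalised to zero mean and unit SD per
    projection column of this sample.
    """
    pts = landmarks.points
    if pts.shape[0] < 2 or np.allclose(pts, pts[0]):
        raise ZeroVarianceError("need >= 2 distinct landmarks to align")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    scale = centered.std()  # over all 3N entries
    if scale <= 0 or not np.isfinite(scale):
        raise ZeroVarianceError("landmark coordinates have zero variance")
    aligned_pts = centered / scale

    gray = landmarks.gray
    gray_mean = gray_sd = None
    aligned_gray = None
    if gray is not None:
        gray_mean = gray.mean(axis=0)
        gray_sd = gray.std(axis=0)
        safe_sd = np.where(gray_sd > 0, gray_sd, 1.0)
        if np.any(gray_sd <= 0):
            logger.warning("constant gray column(s) left at zero after centering")
        aligned_gray = (gray - gray_mean) / safe_sd

    aligned = LandmarkSet(points=aligned_pts, gray=aligned_gray,
                          groups=landmarks.groups)
    record = AlignmentRecord(translation=centroid, scale=float(scale),
                             gray_mean=gray_mean, gray_sd=gray_sd)
    return aligned, record


@dataclass
class ShapeAppearanceModel:
    """PCA model of aligned shape (+ appearance) state vectors.

    ``modes`` stores every non-null principal direction found in the cohort
    as orthonormal columns; ``n_modes`` marks how many are retained to reach
    ``variance_target``.  Generation and fitting use the retained block by
    default, while error assessment may slice deeper.
    """

    mean_state: np.ndarray
    modes: np.ndarray          # (D, rank) orthonormal columns
    variances: np.ndarray      # (rank,) descending
    n_modes: int               # retained count
    n_landmarks: int
    n_projections: int
    explained_fraction: float  # cumulative fraction at n_modes
    variance_target: float
    mode_weighting: str = "std"
    alignment_records: list[AlignmentRecord] = field(default_factory=list)
    groups: np.ndarray | None = None

    @property
    def mode_sd(self) -> np.ndarray:
        return np.sqrt(self.variances)

    @property
    def mode_weights(self) -> np.ndarray:
        """Per-mode factor w_m multiplying b_m in the generative sum."""
        if self.mode_weighting == "std":
            return self.mode_sd
        if self.mode_weighting == "variance":
            return self.variances
        raise ValueError(f"unknown mode_weighting {self.mode_weighting!r}")

    @property
    def mean_scale(self) -> float:
        if not self.alignment_records:
            return 1.0
        return float(np.mean([r.scale for r in self.alignment_records]))

    @property
    def mean_translation(self) -> np.ndarray:
        if not self.alignment_records:
            return np.zeros(3)
        return np.mean([r.translation for r in self.alignment_records], axis=0)


def select_mode_count(variances, target: float) -> int:
    """Smallest mode count whose cumulative explained variance >= target."""
    variances = np.asarray(variances, dtype=float)
    total = variances.sum()
    if total <= 0:
        raise DegenerateCohortError("total variance is zero")
    frac = np.cumsum(variances) / total
    return int(np.searchsorted(frac, target - 1e-12) + 1)


def build_model(cohort, variance_target: float = 0.90,
                mode_weighting: str = "std") -> ShapeAppearanceModel:
    """Align a cohort and build the PCA shape-appearance model.

    PCA runs through the SVD of the centered data matrix, which avoids
    forming the (3+N_XR)N_L covariance explicitly.  Retains the smallest
    number of modes explaining ``variance_target`` of total variance.
    """
    cohort = list(cohort)
    if len(cohort) < 2:
        raise CorrespondenceError("need >= 2 samples")
    n_l = cohort[0].n_landmarks
    n_xr = cohort[0].n_projections
    for s in cohort:
        if s.n_landmarks != n_l or s.n_projections != n_xr:
            raise CorrespondenceError(
                "all cohort members must share landmark and projection counts")

    records = []
    states = []
    for s in cohort:
        aligned, rec = align_landmarks(s)
        records.append(rec)
        states.append(aligned.state)
    X = np.asarray(states)
    mean_state = X.mean(axis=0)
    Xc = X - mean_state
    # economy SVD: rank <= n_samples - 1
    _, svals, vt = np.linalg.svd(Xc, full_matrices=False)
    variances = svals ** 2 / (len(cohort) - 1)
    keep = variances > max(variances[0], 1.0) * 1e-14 if variances.size else []
    variances = variances[keep]
    vt = vt[keep]
    if variances.size == 0:
        raise DegenerateCohortError("cohort has zero total variance")
    n_m = select_mode_count(variances, variance_target)
    explained = float(np.cumsum(variances)[n_m - 1] / variances.sum())
    return ShapeAppearanceModel(
        mean_state=mean_state,
        modes=vt.T.copy(),
        variances=variances,
        n_modes=n_m,
        n_landmarks=n_l,
        n_projections=n_xr,
        explained_fraction=explained,
        variance_target=variance_target,
        mode_weighting=mode_weighting,
        alignment_records=records,
        groups=cohort[0].groups,
    )


def reconstruct(model: ShapeAppearanceModel, weights) -> LandmarkSet:
    """Generate the aligned-space landmark set for mode weights ``b``.

    ``state = mean + sum_m Phi_m (b_m w_m)`` using the first ``len(b)``
    modes; ``b = 0`` returns the mean shape exactly.
    """
    b = np.atleast_1d(np.asarray(weights, dtype=float))
    if b.size > model.modes.shape[1]:
        raise ValueError(f"got {b.size} weights but model has "
                         f"{model.modes.shape[1]} modes")
    w = model.mode_weights[: b.size]
    state = model.mean_state + model.modes[:, : b.size] @ (b * w)
    return LandmarkSet.from_state(state, model.n_landmarks,
                                  model.n_projections, groups=model.groups)


def project(model: ShapeAppearanceModel, state, n_modes: int | None = None) -> np.ndarray:
    """Least-squares optimal mode weights for an aligned state vector.

    ``b_m = Phi_m^T (z - z_bar) / w_m``; exact left inverse of
    :func:`reconstruct` on the retained subspace.
    """
    if isinstance(state, LandmarkSet):
        state = state.state
    state = np.asarray(state, dtype=float)
    if state.size != model.mean_state.size:
        raise ValueError("state length does not match model")
    k = model.n_modes if n_modes is None else int(n_modes)
    return (model.modes[:, :k].T @ (state - model.mean_state)) / model.mode_weights[:k]


def _bbox_diagonal(points: np.ndarray) -> float:
    ext = points.max(axis=0) - points.min(axis=0)
    return float(np.linalg.norm(ext))


def _landmark_error_pct(truth_pts: np.ndarray, recon_pts: np.ndarray) -> float:
    """Mean landmark distance as a percentage of the truth bounding-box diagonal."""
    err = np.linalg.norm(truth_pts - recon_pts, axis=1).mean()
    return 100.0 * err / _bbox_diagonal(truth_pts)


def assess_errors(cohort, variance_target: float = 0.90,
                  mode_weighting: str = "std") -> dict:
    """Explained-variance, reconstruction-error and generalisation curves.

    For each candidate mode count the training samples are projected and
    reconstructed (reconstruction error) and, separately, each sample is
    reconstructed by a model built without it (leave-one-out generalisation
    error).  Errors are mean absolute landmark distances as a percentage of
    each sample's bounding-box diagonal, evaluated in aligned space.
    """
    cohort = list(cohort)
    if len(cohort) < 3:
        raise CorrespondenceError("error assessment needs >= 3 samples")
    full = build_model(cohort, variance_target=1.0, mode_weighting=mode_weighting)
    rank = full.variances.size
    n_l = full.n_landmarks

    aligned = [align_landmarks(s)[0] for s in cohort]
    explained = np.cumsum(full.variances) / full.variances.sum()

    recon_err = np.zeros(rank)
    for k in range(1, rank + 1):
        errs = []
        for a in aligned:
            b = project(full, a.state, n_modes=k)
            r = reconstruct(full, b)
            errs.append(_landmark_error_pct(a.points, r.points))
        recon_err[k - 1] = np.mean(errs)

    # leave-one-out: rank drops by one when a sample is held out
    loo_rank = max(rank - 1, 1)
    gen_err = np.zeros(loo_rank)
    for i in range(len(cohort)):
        sub = cohort[:i] + cohort[i + 1:]
        m_i = build_model(sub, variance_target=1.0, mode_weighting=mode_weighting)
        a_i = aligned[i]
        kmax = min(loo_rank, m_i.variances.size)
        for k in range(1, kmax + 1):
            b = project(m_i, a_i.state, n_modes=k)
            r = reconstruct(m_i, b)
            gen_err[k - 1] += _landmark_error_pct(a_i.points, r.points)
        for k in range(kmax + 1, loo_rank + 1):
            gen_err[k - 1] += gen_err[kmax - 1] if kmax else 0.0
    gen_err /= len(cohort)

    return {
        "mode_counts": np.arange(1, rank + 1),
        "explained_variance": explained,
        "reconstruction_error_pct": recon_err,
        "generalisation_mode_counts": np.arange(1, loo_rank + 1),
        "generalisation_error_pct": gen_err,
        "retained_modes": select_mode_count(full.variances, variance_target),
    }


# ---------------------------------------------------------------------------
# persistence

_FORMAT_VERSION = 1


def save_model(path, model: ShapeAppearanceModel) -> None:
    """Persist a model as a single ``.npz`` archive."""
    meta = {
        "format_version": _FORMAT_VERSION,
        "n_modes": model.n_modes,
        "n_landmarks": model.n_landmarks,
        "n_projections": model.n_projections,
        "explained_fraction": model.explained_fraction,
        "variance_target": model.variance_target,
        "mode_weighting": model.mode_weighting,
        "alignment": "zero-mean, unit-SD over flattened coordinates",
    }
    arrays = {
        "mean_state": model.mean_state,
        "modes": model.modes,
        "variances": model.variances,
        "meta_json": np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        "align_translation": np.array(
            [r.translation for r in model.alignment_records]),
        "align_scale": np.array([r.scale for r in model.alignment_records]),
    }
    if model.groups is not None:
        arrays["groups"] = model.groups.astype(str)
    np.savez(path, **arrays)


def load_model(path) -> ShapeAppearanceModel:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(bytes(z["meta_json"]).decode())
        if meta["format_version"] != _FORMAT_VERSION:
            raise ValueError(f"unsupported model format {meta['format_version']}")
        records = [AlignmentRecord(translation=t, scale=float(s))
                   for t, s in zip(z["align_translation"], z["align_scale"])]
        groups = z["groups"] if "groups" in z else None
        return ShapeAppearanceModel(
            mean_state=z["mean_state"],
            modes=z["modes"],
            variances=z["variances"],
            n_modes=int(meta["n_modes"]),
            n_landmarks=int(meta["n_landmarks"]),
            n_projections=int(meta["n_projections"]),
            explained_fraction=float(meta["explained_fraction"]),
            variance_target=float(meta["variance_target"]),
            mode_weighting=meta["mode_weighting"],
            alignment_records=records,
            groups=groups,
        )
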