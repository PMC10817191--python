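"""Volume-filling generation of the distal conducting airway tree.

The lung volume is discretised into seed points on a uniform cubic grid of
spacing ``Delta = (V_lung / N_T)^(1/3)`` (N_T terminal branches, 30,000 for
a full adult conducting tree).  Starting from the imaged central airways,
seeds are repeatedly clustered around the growing terminal branches, each
cluster is split by a plane through its centroid, and a child branch grows
toward each sub-cluster centroid by 40% of the distance.  Branches whose
cluster collapses to a single seed, or whose candidate length falls below
2 mm, close as terminal bifurcations and consume their nearest seed.
Diameters follow a per-generation geometric reduction and per-generation
morphometry tables summarise the result.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.spatial.distance import cdist

from .io_core import SurfaceMesh, VolumeImage

logger = logging.getLogger("aerolung")

__all__ = [
    "Branch",
    "AirwayTree",
    "SeedCloud",
    "ResidualSeedError",
    "seed_points",
    "grow_tree",
    "assign_diameters",
    "morphometry",
    "tube_surface",
]


class ResidualSeedError(RuntimeError):
    """Seeds remained that no growing branch could reach."""


@dataclass
class Branch:
    parent: int | None
    start: int              # node id
    end: int                # node id
    generation: int
    length: float = 0.0
    diameter: float = 0.0
    terminal: bool = False  # closed terminal bifurcation: grows no further


@dataclass
class AirwayTree:
    """Node/branch graph of the airway tree.

    ``nodes`` maps node id -> 3D point (mm); ``branches`` maps branch id ->
    :class:`Branch`.  Binary branching: every branch has at most two
    children; the generation index increments by one per bifurcation
    (trachea = generation 0).
    """

    nodes: dict = field(default_factory=dict)
    branches: dict = field(default_factory=dict)

    def add_node(self, point) -> int:
        nid = len(self.nodes)
        self.nodes[nid] = np.asarray(point, dtype=float)
        return nid

    def add_branch(self, parent: int | None, start: int, end: int,
                   generation: int, terminal: bool = False,
                   diameter: float = 0.0) -> int:
        bid = len(self.branches)
        length = float(np.linalg.norm(self.nodes[end] - self.nodes[start]))
        self.branches[bid] = Branch(parent=parent, start=start, end=end,
                                    generation=generation, length=length,
                                    diameter=diameter, terminal=terminal)
        return bid

    def children(self, bid: int) -> list[int]:
        return [b for b, br in self.branches.items() if br.parent == bid]

    def growing_tips(self) -> list[int]:
        """Branches that may still extend: leaves not flagged terminal."""
        has_child = {br.parent for br in self.branches.values()
                     if br.parent is not None}
        return sorted(b for b, br in self.branches.items()
                      if b not in has_child and not br.terminal)

    def leaves(self) -> list[int]:
        has_child = {br.parent for br in self.branches.values()
                     if br.parent is not None}
        return sorted(b for b in self.branches if b not in has_child)

    def validate(self) -> None:
        """Check the structural invariants; raise ValueError on violation."""
        for bid, br in self.branches.items():
            if br.parent is not None:
                p = self.branches[br.parent]
                if br.generation != p.generation + 1:
                    raise ValueError(f"branch {bid}: generation not parent+1")
            expected = float(np.linalg.norm(self.nodes[br.end]
                                            - self.nodes[br.start]))
            if abs(br.length - expected) > 1e-9 * max(1.0, expected):
                raise ValueError(f"branch {bid}: stored length inconsistent")
            n_children = len(self.children(bid))
            if n_children > 2:
                raise ValueError(f"branch {bid}: {n_children} children (> 2)")
        # acyclicity: walking parents must terminate
        for bid in self.branches:
            seen = set()
            cur = bid
            while cur is not None:
                if cur in seen:
                    raise ValueError("cycle in branch parents")
                seen.add(cur)
                cur = self.branches[cur].parent

    # -- serialisation (JSON schema: nodes + branches) --

    def to_json(self) -> dict:
        return {
            "nodes": [{"id": int(i), "x": float(p[0]), "y": float(p[1]),
                       "z": float(p[2])} for i, p in sorted(self.nodes.items())],
            "branches": [{"id": int(b), "parent": br.parent,
                          "start": int(br.start), "end": int(br.end),
                          "generation": int(br.generation),
                          "diameter_mm": float(br.diameter),
                          "terminal": bool(br.terminal)}
                         for b, br in sorted(self.branches.items())],
        }

    @classmethod
    def from_json(cls, payload: dict) -> "AirwayTree":
        tree = cls()
        for n in payload["nodes"]:
            tree.nodes[int(n["id"])] = np.array([n["x"], n["y"], n["z"]])
        for b in payload["branches"]:
            start, end = int(b["start"]), int(b["end"])
            parent = None if b["parent"] is None else int(b["parent"])
            length = float(np.linalg.norm(tree.nodes[end] - tree.nodes[start]))
            tree.branches[int(b["id"])] = Branch(
                parent=parent, start=start, end=end,
                generation=int(b["generation"]), length=length,
                diameter=float(b.get("diameter_mm", 0.0)),
                terminal=bool(b.get("terminal", False)))
        return tree

    def save(self, path) -> None:
        with open(os.fspath(path), "w") as fh:
            json.dump(self.to_json(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "AirwayTree":
        with open(os.fspath(path)) as fh:
            return cls.from_json(json.load(fh))


@dataclass
class SeedCloud:
    """Uniform-grid seed points inside the lung mask, spacing Delta (mm)."""

    points: np.ndarray
    spacing: float

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)


def seed_points(mask: VolumeImage, n_terminal: int = 30000,
                labels=None) -> SeedCloud:
    """Discretise the lung volume into uniformly spaced seed points.

    ``Delta = (V_lung / N_T)^(1/3)`` with the lung volume from the voxel
    count; a regular cubic grid of that spacing is clipped to the mask.
    """
    vox = mask.voxels
    inside = np.isin(vox, labels) if labels is not None else vox > 0
    n_vox = int(inside.sum())
    if n_vox == 0:
        raise ValueError("mask is empty")
    v_lung = n_vox * mask.voxel_volume
    delta = float((v_lung / n_terminal) ** (1.0 / 3.0))
    if delta < mask.spacing.min():
        logger.warning("seed spacing %.3f mm below voxel spacing; seeds will "
                       "oversample the mask", delta)
    lo = mask.origin
    hi = mask.origin + (np.array(vox.shape) - 1) * mask.spacing
    axes = [np.arange(lo[a] + delta / 2, hi[a] + 1e-9, delta) for a in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    idx = np.rint(mask.index_from_world(pts)).astype(int)
    ok = np.all((idx >= 0) & (idx < np.array(vox.shape)), axis=1)
    keep = np.zeros(len(pts), dtype=bool)
    keep[ok] = inside[idx[ok, 0], idx[ok, 1], idx[ok, 2]]
    return SeedCloud(points=pts[keep], spacing=delta)


def _split_normal(parent_dir: np.ndarray, offset: np.ndarray) -> np.ndarray:
    """Splitting-plane normal: component of the centroid offset
    perpendicular to the parent direction (plane contains the parent
    direction and passes through the centroid)."""
    d = parent_dir / (np.linalg.norm(parent_dir) or 1.0)
    n = offset - (offset @ d) * d
    nn = np.linalg.norm(n)
    if nn < 1e-12:
        # centroid on the parent axis: any perpendicular direction works
        helper = np.array([1.0, 0.0, 0.0])
        if abs(d[0]) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        n = np.cross(d, helper)
        nn = np.linalg.norm(n)
    return n / nn


def grow_tree(tree: AirwayTree, seeds: SeedCloud,
              extension_fraction: float = 0.4,
              min_length: float = 2.0) -> AirwayTree:
    """Grow the distal tree until every seed point is consumed.

    Each iteration assigns the remaining seeds to their nearest growing
    terminal branch (by branch end node; ties go to the lowest branch id),
    splits each cluster across a plane through its centroid, and extends a
    child toward each sub-cluster centroid by ``extension_fraction`` of the
    distance.  Single-seed clusters and candidate branches shorter than
    ``min_length`` close as terminals and delete their nearest seed.

    If seeds remain when no branch can grow (possible under the printed
    rules when the last growing branch closes with several seeds left), a
    resolution pass gives each leftover seed one terminal child from the
    nearest branch end, preserving the one-terminal-per-seed accounting.
    """
    tree = AirwayTree(nodes=dict(tree.nodes),
                      branches={b: Branch(**vars(br))
                                for b, br in tree.branches.items()})
    remaining = seeds.points.copy()
    if len(remaining) == 0:
        return tree
    if not tree.growing_tips():
        raise ResidualSeedError(
            f"{len(remaining)} seeds but the initial tree has no growing tips")

    max_iter = 4 * len(remaining)
    iteration = 0
    while len(remaining):
        tips = tree.growing_tips()
        if not tips:
            break  # resolution pass below
        iteration += 1
        if iteration > max_iter:
            raise RuntimeError("airway growth failed to terminate "
                               f"({len(remaining)} seeds left)")
        tip_ends = np.array([tree.nodes[tree.branches[t].end] for t in tips])
        nearest = np.argmin(cdist(remaining, tip_ends), axis=1)
        delete = np.zeros(len(remaining), dtype=bool)
        for ti, tip in enumerate(tips):
            cluster_idx = np.flatnonzero(nearest == ti)
            br = tree.branches[tip]
            if cluster_idx.size == 0:
                br.terminal = True
                continue
            end_pt = tree.nodes[br.end]
            if cluster_idx.size == 1:
                # termination base case: one terminal child toward the seed
                seed = remaining[cluster_idx[0]]
                nid = tree.add_node(end_pt + extension_fraction
                                    * (seed - end_pt))
                tree.add_branch(parent=tip, start=br.end, end=nid,
                                generation=br.generation + 1, terminal=True)
                delete[cluster_idx[0]] = True
                continue
            cluster = remaining[cluster_idx]
            centroid = cluster.mean(axis=0)
            parent_dir = end_pt - tree.nodes[br.start]
            normal = _split_normal(parent_dir, centroid - end_pt)
            side = (cluster - centroid) @ normal >= 0
            for sub_idx in (cluster_idx[side], cluster_idx[~side]):
                if sub_idx.size == 0:
                    continue
                sub = remaining[sub_idx]
                target = sub.mean(axis=0)
                new_end = end_pt + extension_fraction * (target - end_pt)
                length = extension_fraction * np.linalg.norm(target - end_pt)
                terminal = sub_idx.size == 1 or length < min_length
                nid = tree.add_node(new_end)
                tree.add_branch(parent=tip, start=br.end, end=nid,
                                generation=br.generation + 1,
                                terminal=terminal)
                if terminal:
                    d = np.linalg.norm(sub - new_end, axis=1)
                    delete[sub_idx[np.argmin(d)]] = True
        remaining = remaining[~delete]

    if len(remaining):
        logger.info("growth deadlock with %d seed(s); resolution pass",
                    len(remaining))
        for seed in remaining:
            leaf_ids = tree.leaves()
            ends = np.array([tree.nodes[tree.branches[b].end] for b in leaf_ids])
            near = leaf_ids[int(np.argmin(np.linalg.norm(ends - seed, axis=1)))]
            br = tree.branches[near]
            if len(tree.children(near)) >= 2:
                continue
            end_pt = tree.nodes[br.end]
            new_end = end_pt + extension_fraction * (seed - end_pt)
            nid = tree.add_node(new_end)
            # the closed branch keeps its terminal classification; the
            # resolution child it gains is itself terminal
            tree.add_branch(parent=near, start=br.end, end=nid,
                            generation=br.generation + 1, terminal=True)
    return tree


def assign_diameters(tree: AirwayTree, trachea_diameter: float = 16.0,
                     ratio: float = 2.0 ** (-1.0 / 3.0)) -> AirwayTree:
    """Assign per-branch diameters ``d0 * r^generation``.

    The default ratio 2^(-1/3) halves the cross-sectional area every two
    generations (Murray's-law flow-preserving reduction); it is exposed so
    alternative distal-diameter rules can be configured.
    """
    if trachea_diameter <= 0:
        raise ValueError("trachea diameter must be positive")
    if ratio >= 1:
        logger.warning("diameter ratio %.3f >= 1 is non-physiological", ratio)
    for br in tree.branches.values():
        br.diameter = trachea_diameter * ratio ** br.generation
    return tree


def morphometry(tree: AirwayTree, normalize: bool = True):
    """Per-generation diameter statistics, normalised by the generation-0 mean.

    Returns a DataFrame with columns generation, mean_diameter, sd_diameter,
    count (empty generations are simply absent).
    """
    import pandas as pd

    gens: dict[int, list[float]] = {}
    for br in tree.branches.values():
        gens.setdefault(br.generation, []).append(br.diameter)
    rows = []
    for g in sorted(gens):
        d = np.asarray(gens[g])
        rows.append({"generation": g, "mean_diameter": d.mean(),
                     "sd_diameter": d.std(), "count": len(d)})
    df = pd.DataFrame(rows)
    if normalize and len(df):
        ref = df.loc[df["generation"] == df["generation"].min(),
                     "mean_diameter"].iloc[0]
        df["mean_diameter"] /= ref
        df["sd_diameter"] /= ref
    return df


def tube_surface(tree: AirwayTree, generations=None) -> SurfaceMesh:
    """Capped-cylinder surface of the requested generations.

    One watertight capped tube per branch (visualisation and deposition
    fixtures, not CFD meshing); zero-diameter branches are skipped.
    """
    meshes = []
    for bid, br in sorted(tree.branches.items()):
        if generations is not None and br.generation not in generations:
            continue
        if br.diameter <= 0:
            logger.warning("tube_surface: skipping zero-diameter branch %d", bid)
            continue
        seg = np.array([tree.nodes[br.start], tree.nodes[br.end]])
        if np.linalg.norm(seg[1] - seg[0]) <= 0:
            continue
        meshes.append(trimesh.creation.cylinder(radius=br.diameter / 2,
                                                segment=seg, sections=16))
    if not meshes:
        return SurfaceMesh(vertices=np.empty((0, 3)),
                           faces=np.empty((0, 3), dtype=int),
                           face_normals=np.empty((0, 3)))
    combined = trimesh.util.concatenate(meshes)
    return SurfaceMesh.from_trimesh(combined)
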