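"""Seed grids, volume-filling growth, diameters and morphometry."""

import numpy as np
import pandas as pd
import pytest

from aerolung.airway import (AirwayTree, ResidualSeedError, SeedCloud,
                             assign_diameters, grow_tree, morphometry,
                             seed_points, tube_surface)
from aerolung.io_core import VolumeImage
from aerolung.phantoms import make_lung_phantom


def _stick_tree(end=(0.0, 0.0, 0.0)):
    t = AirwayTree()
    n0 = t.add_node((0.0, 0.0, -10.0))
    n1 = t.add_node(end)
    t.add_branch(None, n0, n1, generation=0)
    return t


class TestSeedPoints:
    def test_spacing_formula_exact(self):
        # 375,000 voxels of 8 mm^3 = 3e6 mm^3 -> Delta = 100^(1/3)
        mask = VolumeImage(voxels=np.ones((75, 100, 50), dtype=np.uint8),
                           spacing=2.0)
        cloud = seed_points(mask, n_terminal=30000)
        assert cloud.spacing == pytest.approx(100.0 ** (1 / 3), abs=1e-12)

    def test_unit_spacing_when_volume_equals_terminal_count(self):
        mask = VolumeImage(voxels=np.ones((30, 100, 10), dtype=np.uint8),
                           spacing=1.0)
        assert seed_points(mask, n_terminal=30000).spacing \
            == pytest.approx(1.0)

    def test_count_near_target_for_smooth_mask(self):
        ph = make_lung_phantom(spacing=2.0, include_airway=False)
        cloud = seed_points(ph.labelmap, n_terminal=1000, labels=(1, 2))
        assert abs(len(cloud.points) - 1000) / 1000 < 0.1

    def test_all_seeds_inside_mask(self):
        ph = make_lung_phantom(spacing=2.0, include_airway=False)
        mask = ph.labelmap
        cloud = seed_points(mask, n_terminal=500, labels=(1, 2))
        idx = np.rint(mask.index_from_world(cloud.points)).astype(int)
        assert np.all(np.isin(mask.voxels[idx[:, 0], idx[:, 1], idx[:, 2]],
                              (1, 2)))

    def test_empty_mask_rejected(self):
        mask = VolumeImage(voxels=np.zeros((4, 4, 4)), spacing=1.0)
        with pytest.raises(ValueError):
            seed_points(mask)


class TestGrowTree:
    def test_child_extends_40_pct_toward_centroid(self):
        # cluster centroid (10,0,0); parent end at the origin
        tree = grow_tree(_stick_tree(),
                         SeedCloud(points=np.array([[10.0, 0, 1],
                                                    [10.0, 0, -1]]),
                                   spacing=1.0))
        ends = np.array([tree.nodes[b.end] for b in tree.branches.values()])
        assert any(np.allclose(e, (4.0, 0, 0), atol=1e-12) for e in ends)
        tree.validate()

    def test_single_seed_terminates_with_one_terminal_branch(self):
        tree = grow_tree(_stick_tree(),
                         SeedCloud(points=np.array([[10.0, 0, 0]]),
                                   spacing=1.0))
        terminals = [b for b in tree.branches.values() if b.terminal]
        assert len(terminals) == 1
        np.testing.assert_allclose(tree.nodes[terminals[0].end],
                                   (4.0, 0, 0), atol=1e-12)

    def test_short_candidate_branch_is_terminal(self):
        # centroid 3 mm away -> candidate 1.2 mm < 2 mm -> terminal
        tree = grow_tree(_stick_tree(),
                         SeedCloud(points=np.array([[3.0, 0, 1],
                                                    [3.0, 0, -1]]),
                                   spacing=1.0))
        short = [b for b in tree.branches.values()
                 if b.parent is not None and b.length < 2.0]
        assert short and all(b.terminal for b in short)

    def test_ellipsoid_phantom_consumes_all_seeds(self):
        ph = make_lung_phantom(spacing=2.0)
        seeds = seed_points(ph.labelmap, n_terminal=1000, labels=(1, 2))
        tree = grow_tree(ph.tree, seeds)
        tree.validate()
        gens = [b.generation for b in tree.branches.values()]
        assert np.all(np.isfinite(gens))
        # binary branching with one terminal per seed: branch count bounded
        assert len(tree.branches) <= 3 + 2.5 * len(seeds.points)

    def test_grown_internal_branches_respect_min_length(self):
        ph = make_lung_phantom(spacing=2.0)
        seeds = seed_points(ph.labelmap, n_terminal=500, labels=(1, 2))
        tree = grow_tree(ph.tree, seeds, min_length=2.0)
        for bid, br in tree.branches.items():
            if bid > 2 and not br.terminal and tree.children(bid):
                assert br.length >= 2.0 - 1e-9

    def test_no_growing_tip_raises_residual_error(self):
        t = _stick_tree()
        t.branches[0].terminal = True
        with pytest.raises(ResidualSeedError):
            grow_tree(t, SeedCloud(points=np.array([[5.0, 0, 0]]),
                                   spacing=1.0))

    def test_growth_is_deterministic(self):
        ph = make_lung_phantom(spacing=3.0)
        seeds = seed_points(ph.labelmap, n_terminal=300, labels=(1, 2))
        a = grow_tree(ph.tree, seeds)
        b = grow_tree(ph.tree, seeds)
        assert len(a.branches) == len(b.branches)
        for k in a.nodes:
            np.testing.assert_array_equal(a.nodes[k], b.nodes[k])


class TestDiameters:
    def test_geometric_decay(self):
        t = _stick_tree()
        n2 = t.add_node((0, 0, 5.0))
        t.add_branch(0, 1, n2, generation=1)
        assign_diameters(t, trachea_diameter=16.0)
        assert t.branches[0].diameter == pytest.approx(16.0)
        # generation 3 at ratio 2^(-1/3): 16 * 2^-1 = 8
        assert 16.0 * (2 ** (-1 / 3)) ** 3 == pytest.approx(8.0)
        assert t.branches[1].diameter == pytest.approx(16.0 * 2 ** (-1 / 3))

    def test_diameters_non_increasing_along_paths(self):
        ph = make_lung_phantom(spacing=3.0)
        seeds = seed_points(ph.labelmap, n_terminal=200, labels=(1, 2))
        tree = assign_diameters(grow_tree(ph.tree, seeds))
        for bid, br in tree.branches.items():
            if br.parent is not None:
                assert br.diameter <= tree.branches[br.parent].diameter + 1e-12

    def test_non_physiological_ratio_warns(self, caplog):
        import logging

        t = _stick_tree()
        with caplog.at_level(logging.WARNING, logger="aerolung"):
            assign_diameters(t, trachea_diameter=10.0, ratio=1.1)
        assert any("non-physiological" in r.message for r in caplog.records)

    def test_invalid_trachea_diameter(self):
        with pytest.raises(ValueError):
            assign_diameters(_stick_tree(), trachea_diameter=0.0)


class TestMorphometry:
    def test_single_branch(self):
        t = _stick_tree()
        assign_diameters(t, trachea_diameter=10.0)
        df = morphometry(t)
        assert len(df) == 1
        assert df.iloc[0]["sd_diameter"] == 0.0
        assert df.iloc[0]["mean_diameter"] == pytest.approx(1.0)

    def test_hand_built_tree_matches_direct_computation(self):
        t = AirwayTree()
        pts = [(0, 0, 0), (0, 0, 5), (2, 0, 8), (-2, 0, 8), (3, 0, 11),
               (1, 0, 11), (-3, 0, 11), (-1, 0, 11)]
        ids = [t.add_node(p) for p in pts]
        t.add_branch(None, ids[0], ids[1], 0)
        t.add_branch(0, ids[1], ids[2], 1)
        t.add_branch(0, ids[1], ids[3], 1)
        t.add_branch(1, ids[2], ids[4], 2)
        t.add_branch(1, ids[2], ids[5], 2)
        t.add_branch(2, ids[3], ids[6], 2)
        t.add_branch(2, ids[3], ids[7], 2)
        diameters = {0: 10.0, 1: 8.0, 2: 6.0, 3: 5.0, 4: 4.0, 5: 4.0, 6: 3.0}
        for bid, d in diameters.items():
            t.branches[bid].diameter = d
        df = morphometry(t, normalize=False).set_index("generation")
        assert df.loc[0, "mean_diameter"] == pytest.approx(10.0)
        assert df.loc[1, "mean_diameter"] == pytest.approx(7.0)
        assert df.loc[1, "sd_diameter"] == pytest.approx(1.0)
        assert df.loc[2, "mean_diameter"] == pytest.approx(np.mean([5, 4, 4, 3]))
        assert df.loc[2, "sd_diameter"] == pytest.approx(np.std([5, 4, 4, 3]))
        assert df.loc[2, "count"] == 4

    def test_generation_zero_normalised_to_one(self):
        ph = make_lung_phantom(spacing=3.0)
        seeds = seed_points(ph.labelmap, n_terminal=200, labels=(1, 2))
        tree = assign_diameters(grow_tree(ph.tree, seeds))
        df = morphometry(tree)
        assert df.iloc[0]["mean_diameter"] == pytest.approx(1.0)


class TestTubeSurface:
    def test_cylinder_area(self):
        t = AirwayTree()
        n0 = t.add_node((0, 0, 0))
        n1 = t.add_node((0, 0, 10.0))
        t.add_branch(None, n0, n1, 0, diameter=2.0)
        mesh = tube_surface(t)
        tm = mesh.as_trimesh()
        expected = np.pi * 2.0 * 10.0 + 2 * np.pi * 1.0 ** 2
        assert abs(tm.area - expected) / expected < 0.05
        assert tm.volume > 0  # outward normals

    def test_empty_generation_range(self):
        t = _stick_tree()
        assign_diameters(t, trachea_diameter=10.0)
        mesh = tube_surface(t, generations=[5])
        assert len(mesh.faces) == 0


def test_tree_json_roundtrip(tmp_path):
    ph = make_lung_phantom(spacing=3.0)
    tree = assign_diameters(ph.tree)
    path = tmp_path / "tree.json"
    tree.save(path)
    back = AirwayTree.load(path)
    assert set(back.branches) == set(tree.branches)
    for bid in tree.branches:
        assert back.branches[bid].generation == tree.branches[bid].generation
        assert back.branches[bid].diameter \
            == pytest.approx(tree.branches[bid].diameter)
        np.testing.assert_allclose(back.nodes[back.branches[bid].end],
                                   tree.nodes[tree.branches[bid].end])
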