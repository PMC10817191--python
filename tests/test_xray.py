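"""DRR synthesis, edge maps, loss terms, fitting and template morphing."""

import numpy as np
import pytest
import trimesh

from aerolung.io_core import SurfaceMesh, VolumeImage
from aerolung.ssam import align_landmarks, build_model, reconstruct
from aerolung.xray import (EdgePointSet, FitConfig, Radiograph, compute_drr,
                           edge_map, fit_ssam, loss_fit, loss_gray,
                           loss_prior, loss_prior_dense, loss_shadow,
                           morph_template, project_points, sample_grays,
                           silhouette_landmarks, total_loss, _kernel_matrix)
from conftest import make_toy_cohort


class TestDrr:
    def test_zero_volume_gives_zero_image(self):
        vol = VolumeImage(voxels=np.zeros((6, 6, 6)), spacing=1.0)
        rad = compute_drr(vol, axis=1)
        assert np.all(rad.pixels == 0)

    def test_column_sums(self):
        # one column holds 2v total, another v: ratio survives normalisation
        vox = np.zeros((4, 5, 4))
        vox[1, :2, 2] = 3.0   # total 6 in column (1, 2)
        vox[3, 0, 0] = 3.0    # total 3 in column (3, 0)
        rad = compute_drr(VolumeImage(voxels=vox, spacing=1.0), axis=1)
        assert rad.pixels[1, 2] == pytest.approx(1.0)
        assert rad.pixels[3, 0] == pytest.approx(0.5)
        assert np.count_nonzero(rad.pixels) == 2

    def test_ellipsoid_peak_at_center_projection(self):
        x, y, z = np.meshgrid(*[np.linspace(-1, 1, 41)] * 3, indexing="ij")
        vox = ((x / 0.9) ** 2 + (y / 0.6) ** 2 + (z / 0.7) ** 2 <= 1).astype(float)
        rad = compute_drr(VolumeImage(voxels=vox, spacing=1.0), axis=1)
        peak = np.unravel_index(np.argmax(rad.pixels), rad.pixels.shape)
        assert peak == (20, 20)  # longest chord passes through the centre

    def test_invalid_axis(self):
        vol = VolumeImage(voxels=np.zeros((2, 2, 2)), spacing=1.0)
        with pytest.raises(ValueError):
            compute_drr(vol, axis=3)

    def test_in_plane_metadata(self):
        vol = VolumeImage(voxels=np.zeros((4, 5, 6)),
                          spacing=(1.0, 2.0, 3.0), origin=(7.0, 8.0, 9.0))
        rad = compute_drr(vol, axis=1)
        np.testing.assert_allclose(rad.pixel_spacing, (1.0, 3.0))
        np.testing.assert_allclose(rad.origin, (7.0, 9.0))


class TestEdgeMap:
    def test_constant_image_yields_empty_set(self):
        rad = Radiograph(pixels=np.full((64, 64), 0.3), pixel_spacing=1.0,
                         projection_axis=1)
        assert len(edge_map(rad)) == 0

    def test_disk_edge_ring(self):
        n, r = 160, 40.0
        ii, jj = np.mgrid[0:n, 0:n] - n / 2
        img = ((ii ** 2 + jj ** 2) <= r ** 2).astype(float)
        rad = Radiograph(pixels=img, pixel_spacing=1.0, projection_axis=1,
                         origin=(-n / 2, -n / 2))
        edges = edge_map(rad)
        assert len(edges) > 10
        radii = np.linalg.norm(edges.points, axis=1)
        # localisation is limited by the 4x downsampling and the 2-coarse-px
        # Canny kernel: allow 1.5 coarse pixels (6 original px)
        assert np.all(np.abs(radii - r) <= 6.0)
        assert np.abs(np.abs(radii - r)).mean() <= 4.0

    def test_invariant_to_linear_intensity_rescale(self):
        rng = np.random.default_rng(0)
        img = rng.random((64, 64))
        img[20:40, 20:40] += 2.0
        a = edge_map(Radiograph(pixels=img, pixel_spacing=1.0,
                                projection_axis=1))
        b = edge_map(Radiograph(pixels=0.2 + 0.3 * img, pixel_spacing=1.0,
                                projection_axis=1))
        np.testing.assert_array_equal(a.points, b.points)


class TestSilhouette:
    def test_sphere_silhouette_near_great_circle(self):
        tm = trimesh.creation.icosphere(subdivisions=4)
        mesh = SurfaceMesh.from_trimesh(tm)
        vmap = np.arange(len(tm.vertices))
        sil = silhouette_landmarks(mesh, vmap, axis=1)
        assert len(sil) > 0
        # selected vertices lie within 10 degrees of the y=0 great circle
        lat = np.abs(np.degrees(np.arcsin(tm.vertices[sil][:, 1])))
        assert np.all(lat < 10.0)

    def test_bicone_silhouette_is_the_rim(self):
        # solid of revolution about z: silhouette along z = rim circle
        n = 24
        theta = 2 * np.pi * np.arange(n) / n
        rim = np.column_stack([np.cos(theta), np.sin(theta), np.zeros(n)])
        verts = np.vstack([rim, [0, 0, 1.0], [0, 0, -1.0]])
        faces = []
        for i in range(n):
            j = (i + 1) % n
            faces.append([i, j, n])       # upper cone
            faces.append([j, i, n + 1])   # lower cone
        mesh = SurfaceMesh(vertices=verts, faces=np.array(faces))
        sil = silhouette_landmarks(mesh, np.arange(len(verts)), axis=2)
        assert set(sil) == set(range(n))  # every rim vertex, no apex

    def test_convex_mesh_silhouette_nonempty_any_axis(self, unit_sphere_mesh):
        vmap = np.arange(unit_sphere_mesh.n_vertices)
        for axis in (0, 1, 2):
            assert len(silhouette_landmarks(unit_sphere_mesh, vmap, axis)) > 0

    def test_airway_group_excluded(self, unit_sphere_mesh):
        vmap = np.arange(unit_sphere_mesh.n_vertices)
        groups = np.full(len(vmap), "airway")
        sil = silhouette_landmarks(unit_sphere_mesh, vmap, axis=1,
                                   groups=groups)
        assert len(sil) == 0


class TestLossFit:
    def test_zero_distance_gives_zero(self):
        pts = np.array([[0.0, 0], [1.0, 2]])
        edges = EdgePointSet(points=pts)
        assert loss_fit(pts, edges) == pytest.approx(0.0, abs=1e-12)

    def test_distance_equal_to_scale(self):
        edges = EdgePointSet(points=[[0.0, 0.0]])
        val = loss_fit(np.array([[5.0, 0.0]]), edges, c_dist=5.0)
        assert val == pytest.approx(1 - np.exp(-1), abs=1e-4)  # 0.6321

    def test_far_limit_approaches_one(self):
        edges = EdgePointSet(points=[[0.0, 0.0]])
        assert loss_fit(np.array([[1e9, 0.0]]), edges) == pytest.approx(1.0)

    def test_empty_edges_rejected(self):
        with pytest.raises(ValueError):
            loss_fit(np.array([[0.0, 0]]), EdgePointSet(points=np.empty((0, 2))))


class TestLossPrior:
    @pytest.fixture()
    def toy(self):
        cohort = make_toy_cohort(n_samples=5, n_landmarks=3, n_projections=0)
        model = build_model(cohort, variance_target=1.0)
        states = np.array([align_landmarks(s)[0].state for s in cohort])
        cov = np.cov(states.T)
        return model, cov

    def test_mean_shape_has_zero_prior(self, toy):
        model, _ = toy
        assert loss_prior(np.zeros(model.n_modes), model) == 0.0

    def test_matches_dense_covariance_oracle(self, toy):
        model, cov = toy
        b = np.zeros(model.n_modes)
        b[0] = 1.0  # one SD along the leading mode
        state = reconstruct(model, b).state
        dense = loss_prior_dense(state, model.mean_state, cov,
                                 model.n_landmarks)
        assert loss_prior(b, model) == pytest.approx(dense, abs=1e-8)

    def test_quadratic_homogeneity(self, toy):
        model, _ = toy
        b = np.full(model.n_modes, 0.5)
        assert loss_prior(2 * b, model) == pytest.approx(
            4 * loss_prior(b, model))


class TestLossGray:
    def test_identical_vectors(self):
        assert loss_gray([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_mean_absolute_difference(self):
        assert loss_gray([0.0, 0.0], [0.2, 0.4]) == pytest.approx(0.3)

    def test_symmetry(self):
        a, b = np.array([0.1, 0.9]), np.array([0.5, 0.2])
        assert loss_gray(a, b) == loss_gray(b, a)


class TestLossShadow:
    def _image(self, pixels):
        return Radiograph(pixels=pixels, pixel_spacing=1.0,
                          projection_axis=1)

    def test_uniform_image_gives_zero(self):
        img = self._image(np.full((100, 100), 0.7))
        val = loss_shadow(np.array([[50.0, 50.0]]), np.array([[1.0, 0.0]]),
                          img, s_as=20, r_as=14)
        assert val == pytest.approx(0.0, abs=1e-12)

    def test_dark_band_contrast(self):
        px = np.full((120, 120), 1.0)
        px[:60, :] = 0.5  # dark band on the inside (smaller first axis)
        img = self._image(px)
        # landmark on the border, outward normal toward the bright side
        val = loss_shadow(np.array([[60.0, 60.0]]), np.array([[1.0, 0.0]]),
                          img, s_as=20, r_as=14)
        assert val == pytest.approx((0.5 - 1.0) / 1.0, abs=1e-6)

    def test_contrast_inversion_flips_sign(self):
        px = np.full((120, 120), 1.0)
        px[:60, :] = 0.5
        img_a = self._image(px)
        img_b = self._image(1.5 - px)  # swap bright and dark
        args = (np.array([[60.0, 60.0]]), np.array([[1.0, 0.0]]))
        va = loss_shadow(*args, img_a, s_as=20, r_as=14)
        vb = loss_shadow(*args, img_b, s_as=20, r_as=14)
        assert va < 0 < vb

    def test_absolute_flag(self):
        px = np.full((120, 120), 1.0)
        px[:60, :] = 0.5
        img = self._image(px)
        args = (np.array([[60.0, 60.0]]), np.array([[1.0, 0.0]]))
        assert loss_shadow(*args, img, absolute=True) > 0


class TestTotalLoss:
    def test_unit_components_with_default_weights(self):
        cfg = FitConfig()
        val = total_loss({"fit": 1.0, "prior": 1.0, "gray": 1.0,
                          "shadow": 1.0}, cfg)
        assert val == pytest.approx(0.795 + 4.4e-4 + 0.687 + 0.2, abs=1e-12)

    def test_zero_components(self):
        assert total_loss({"fit": 0, "prior": 0, "gray": 0, "shadow": 0},
                          FitConfig()) == 0.0

    def test_zero_weights_kill_everything(self):
        cfg = FitConfig(c_fit=0, c_prior=0, c_g=0, c_as=0)
        assert total_loss({"fit": 9, "prior": 9, "gray": 9, "shadow": 9},
                          cfg) == 0.0

    def test_linear_in_weights(self):
        comp = {"fit": 0.4, "prior": 2.0, "gray": 0.1, "shadow": -0.2}
        a = total_loss(comp, FitConfig(c_fit=1.0, c_prior=0, c_g=0, c_as=0))
        b = total_loss(comp, FitConfig(c_fit=2.0, c_prior=0, c_g=0, c_as=0))
        assert b == pytest.approx(2 * a)


class TestSampleGrays:
    def test_bilinear_and_clamping(self):
        px = np.outer(np.arange(4.0), np.ones(4))
        rad = Radiograph(pixels=px, pixel_spacing=1.0, projection_axis=1)
        vals, n_clamped = sample_grays(rad, np.array([[1.5, 1.0],
                                                      [99.0, 0.0]]))
        assert vals[0] == pytest.approx(1.5)
        assert vals[1] == pytest.approx(3.0)  # clamped to the border row
        assert n_clamped == 1


@pytest.fixture(scope="module")
def fit_setup():
    from aerolung.studies import (_template_silhouettes, _train_model,
                                  render_radiograph)
    model = _train_model(10, seed=0, axes=(1,), pixel_spacing=1.0)
    _, silhouettes = _template_silhouettes((1,))
    rad = render_radiograph(1.0, 1.0, axis=1, pixel_spacing=1.0)
    return model, [silhouettes[1]], rad


class TestFitting:
    def test_zero_budget_returns_initialisation(self, fit_setup):
        model, sil, rad = fit_setup
        res = fit_ssam(model, [rad], FitConfig(budget=0),
                       silhouette_indices=sil)
        np.testing.assert_array_equal(res.weights, 0)
        assert res.scale == pytest.approx(model.mean_scale)

    def test_fit_reduces_loss_and_respects_bounds(self, fit_setup):
        model, sil, rad = fit_setup
        res = fit_ssam(model, [rad], FitConfig(budget=200, seed=3),
                       silhouette_indices=sil)
        assert res.loss_trace[-1] <= res.loss_trace[0]
        assert np.all(np.abs(res.weights) <= 3.0)
        assert np.all(np.diff(res.loss_trace) <= 1e-15)  # running minimum

    def test_empty_edges_cannot_fit(self, fit_setup):
        model, sil, rad = fit_setup
        blank = Radiograph(pixels=np.zeros_like(rad.pixels),
                           pixel_spacing=rad.pixel_spacing,
                           projection_axis=1, origin=rad.origin)
        with pytest.raises(ValueError):
            fit_ssam(model, [blank], FitConfig(budget=10),
                     silhouette_indices=sil)


class TestMorphTemplate:
    def test_identity_when_landmarks_unchanged(self, unit_sphere_mesh):
        lms = unit_sphere_mesh.vertices[::40]
        morphed = morph_template(unit_sphere_mesh, lms, lms, sigma=0.3)
        np.testing.assert_allclose(morphed.vertices,
                                   unit_sphere_mesh.vertices, atol=1e-10)

    def test_mesh_points_at_landmarks_map_exactly(self, unit_sphere_mesh):
        idx = np.arange(0, unit_sphere_mesh.n_vertices, 40)
        lms = unit_sphere_mesh.vertices[idx]
        new = lms + np.random.default_rng(2).normal(scale=0.05,
                                                    size=lms.shape)
        morphed = morph_template(unit_sphere_mesh, lms, new, sigma=0.3)
        np.testing.assert_allclose(morphed.vertices[idx], new, atol=1e-8)

    def test_kernel_properties(self):
        a = np.zeros((1, 3))
        d = np.linspace(0, 2, 9)[:, None] * np.array([[1.0, 0, 0]])
        k = _kernel_matrix(d, a, sigma=0.3, form="gaussian").ravel()
        assert k[0] == pytest.approx(1.0)
        assert np.all(np.diff(k) < 0)  # strictly decreasing with distance

    def test_duplicate_landmarks_regularised(self, unit_sphere_mesh, caplog):
        lms = np.repeat(unit_sphere_mesh.vertices[:1], 3, axis=0)
        new = lms + 0.01
        morphed = morph_template(unit_sphere_mesh, lms, new, sigma=0.3)
        assert np.all(np.isfinite(morphed.vertices))


def test_project_points_drops_projection_axis():
    pts = np.arange(12.0).reshape(4, 3)
    np.testing.assert_array_equal(project_points(pts, 1), pts[:, [0, 2]])
    np.testing.assert_array_equal(project_points(pts, 0), pts[:, [1, 2]])
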