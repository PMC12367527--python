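"""Encoding-model fitting, smoothed assignment, kriging alignment, sign maps."""

import numpy as np
import pytest

import vrcortex as vx
from vrcortex import retinotopy as rt
from vrcortex.simulate import reference_retinotopy


def gauge_corrected_error(assign, shifts, gt):
    xs = assign.x - shifts[assign.kernel, 1]
    ys = assign.y - shifts[assign.kernel, 0]
    return np.hypot(xs - gt.rf_x, ys - gt.rf_y)


@pytest.fixture(scope="module")
def fitted_bank(demo_retino):
    cfg, images, responses, kernels, gt = demo_retino
    bank, assign = rt.fit_kernel_bank(responses, images,
                                      n_kernels=cfg.n_kernels,
                                      kernel_size=cfg.kernel_size, seed=0)
    return bank, assign


class TestKernelBankFit:
    def test_noiseless_recovery_of_positions_and_kernels(self, demo_retino,
                                                         fitted_bank):
        _, _, _, true_kernels, gt = demo_retino
        bank, assign = fitted_bank
        pairing, shifts, corrs = rt.match_kernels(bank.kernels, true_kernels)
        err = gauge_corrected_error(assign, shifts, gt)
        assert (err == 0).mean() >= 0.99
        assert corrs.min() > 0.95
        assert (pairing[assign.kernel] == gt.rf_kernel).all()

    def test_single_neuron_single_kernel_centre(self):
        rng = np.random.default_rng(0)
        images = rng.standard_normal((300, 21, 21)).astype(np.float32)
        kernel = vx.simulate.make_kernel_bank(1, 13, rng)
        maps = rt.kernel_response_maps(images, kernel)
        resp = maps[0, 10, 10, :][None, :]
        bank, assign = rt.fit_kernel_bank(resp, images, n_kernels=1,
                                          kernel_size=13, seed=0,
                                          init_kernels=kernel)
        assert (assign.x[0], assign.y[0]) == (10, 10)
        assert assign.correlation[0] == pytest.approx(1.0, abs=1e-5)

    def test_kernels_recentred_every_iteration(self, fitted_bank):
        bank, _ = fitted_bank
        com = rt.kernel_centre_of_mass(bank.kernels)
        assert np.abs(com - 6.0).max() <= 0.5

    def test_iteration_log_non_decreasing(self, fitted_bank):
        bank, _ = fitted_bank
        assert all(np.diff(bank.iteration_log) >= -1e-12)

    def test_amplitudes_positive(self, fitted_bank):
        _, assign = fitted_bank
        assert (assign.amplitude > 0).all()


class TestSmoothedAssignment:
    def test_shared_neighbourhood_position_recovered(self, demo_retino,
                                                     fitted_bank):
        _, images, responses, true_kernels, gt = demo_retino
        bank, _ = fitted_bank
        sa = rt.assign_neurons_smoothed(responses, images, bank,
                                        gt.tissue_xy, n_neighbors=10)
        _, shifts, _ = rt.match_kernels(bank.kernels, true_kernels)
        err = gauge_corrected_error(sa, shifts, gt)
        assert np.median(err) <= 1.0

    def test_single_neighbor_reduces_to_plain_assignment(self, demo_retino,
                                                         fitted_bank):
        _, images, responses, _, gt = demo_retino
        bank, plain = fitted_bank
        sa = rt.assign_neurons_smoothed(responses, images, bank,
                                        gt.tissue_xy, n_neighbors=1)
        assert np.array_equal(sa.x, plain.x)
        assert np.array_equal(sa.y, plain.y)
        assert np.array_equal(sa.kernel, plain.kernel)

    def test_silent_neuron_inherits_neighbourhood_argmax(self, demo_retino,
                                                         fitted_bank):
        _, images, responses, _, gt = demo_retino
        bank, _ = fitted_bank
        silent = responses.copy()
        silent[0] = 0.0  # flat response: its own map carries no signal
        sa = rt.assign_neurons_smoothed(silent, images, bank, gt.tissue_xy,
                                        n_neighbors=30)
        same_cluster = np.flatnonzero(
            (gt.rf_x == gt.rf_x[0]) & (gt.rf_y == gt.rf_y[0]))[1:]
        assert abs(sa.x[0] - np.median(sa.x[same_cluster])) <= 2
        assert abs(sa.y[0] - np.median(sa.y[same_cluster])) <= 2

    def test_excess_neighbors_clipped_with_warning(self, demo_retino,
                                                   fitted_bank):
        _, images, responses, _, gt = demo_retino
        bank, _ = fitted_bank
        with pytest.warns(UserWarning, match="clipping"):
            rt.assign_neurons_smoothed(responses[:20], images, bank,
                                       gt.tissue_xy[:20], n_neighbors=50)


class TestKriging:
    def grid_field(self, spacing=150.0):
        xs = np.arange(0, 1500 + spacing / 2, spacing)
        ys = np.arange(0, 800 + spacing / 2, spacing)
        tissue = np.array([[x, y] for y in ys for x in xs])
        retino = np.column_stack([0.05 * tissue[:, 0], 0.04 * tissue[:, 1]])
        return tissue, retino

    def test_interpolation_property_at_reference_points(self):
        tissue, retino = self.grid_field()
        krig = vx.fit_kriging_transform(tissue, retino, sigma=200.0)
        pred = krig.predict(tissue)
        denom = max(np.abs(retino).max(), 1.0)
        assert np.abs(pred - retino).max() / denom < 1e-6

    def test_linear_field_error_shrinks_with_density(self):
        rng = np.random.default_rng(0)
        query = np.column_stack([rng.uniform(300, 1200, 50),
                                 rng.uniform(200, 600, 50)])
        errs = []
        for spacing in (300.0, 150.0, 75.0):
            tissue, retino = self.grid_field(spacing)
            krig = vx.fit_kriging_transform(tissue, retino, sigma=200.0)
            truth = np.column_stack([0.05 * query[:, 0], 0.04 * query[:, 1]])
            errs.append(np.abs(krig.predict(query) - truth).max())
        assert errs[2] < errs[1] < errs[0]
        # max error small relative to the field's range (~75 map units)
        assert errs[2] < 0.05

    def test_large_sigma_approaches_global_linear_fit(self):
        tissue, retino = self.grid_field(300.0)
        krig = vx.fit_kriging_transform(tissue, retino, sigma=5000.0)
        query = np.array([[700.0, 350.0], [400.0, 500.0]])
        truth = np.column_stack([0.05 * query[:, 0], 0.04 * query[:, 1]])
        assert np.abs(krig.predict(query) - truth).max() < 0.05

    def test_too_few_points_raises(self):
        with pytest.raises(ValueError):
            vx.fit_kriging_transform(np.zeros((2, 2)), np.zeros((2, 2)))


@pytest.fixture(scope="module")
def reference():
    cfg = vx.RetinoSimConfig(n_kernels=4, n_neurons=200, n_images=50,
                             n_clusters=25, seed=5)
    _, _, _, gt = vx.simulate_image_responses(cfg)
    ref_t, ref_r = reference_retinotopy(gt, spacing=100.0)
    krig = vx.fit_kriging_transform(ref_t, ref_r, 200.0)
    g = gt.gradient
    true_map = np.column_stack(
        [g["margin"] + gt.aligned_tissue_xy[:, 0] * g["gx"],
         g["margin"] + gt.aligned_tissue_xy[:, 1] * g["gy"]])
    return gt, krig, true_map


class TestAlignment:
    def test_identity_case(self, reference):
        gt, krig, true_map = reference
        fit = vx.align_session(gt.aligned_tissue_xy, true_map, krig,
                               search_range=200.0, max_iter=200)
        assert np.abs(fit.a1 - np.eye(2)).max() < 0.01
        assert np.abs(fit.a2).max() < 5.0
        assert fit.cost < 0.05

    def test_planted_translation_recovered(self, reference):
        gt, krig, true_map = reference
        a2t = np.array([300.0, -200.0])
        zp = gt.aligned_tissue_xy - a2t
        fit = vx.align_session(zp, true_map, krig, max_iter=400)
        assert np.abs(fit.a2 - a2t).max() <= 10.0

    def test_planted_rotation_recovered(self, reference):
        gt, krig, true_map = reference
        th = np.deg2rad(10.0)
        a1t = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        a2t = np.array([150.0, 100.0])
        zp = (np.linalg.inv(a1t) @ (gt.aligned_tissue_xy - a2t).T).T
        fit = vx.align_session(zp, true_map, krig, max_iter=500)
        ang = np.rad2deg(np.arctan2(fit.a1[1, 0], fit.a1[0, 0]))
        assert abs(ang - 10.0) <= 1.0
        assert np.abs(fit.a2 - a2t).max() <= 10.0

    def test_cost_log_never_increases(self, reference):
        gt, krig, true_map = reference
        fit = vx.align_session(gt.aligned_tissue_xy - [100, 50], true_map,
                               krig, search_range=200.0, max_iter=200)
        assert all(np.diff(fit.cost_log) <= 1e-12)

    def test_fixed_determinant_mode_has_unit_determinant(self, reference):
        gt, krig, true_map = reference
        fit = vx.align_session(gt.aligned_tissue_xy, true_map, krig,
                               search_range=100.0, max_iter=100,
                               fixed_det=True)
        assert np.linalg.det(fit.a1) == pytest.approx(1.0, abs=1e-9)


class TestSignMap:
    def test_orthogonal_linear_fields_one_positive_parcel(self):
        rows, cols = np.mgrid[0:20, 0:40].astype(float)
        sm = vx.compute_sign_map(2.0 * cols, 3.0 * rows)
        assert np.nanmin(sm.sign) == pytest.approx(1.0)
        assert sm.n_parcels == 1

    def test_mirrored_half_yields_two_parcels(self):
        rows, cols = np.mgrid[0:20, 0:40].astype(float)
        y = np.where(cols < 20, 3.0 * rows, -3.0 * rows)
        sm = vx.compute_sign_map(2.0 * cols, y)
        assert sm.n_parcels == 2
        assert (sm.labels > 0).all()
        left = sm.labels[:, :15]
        right = sm.labels[:, 25:]
        assert np.unique(left).size == 1 and np.unique(right).size == 1
        assert left[0, 0] != right[0, 0]

    def test_swapping_fields_negates_map(self):
        rng = np.random.default_rng(0)
        from scipy.ndimage import gaussian_filter
        x = gaussian_filter(rng.standard_normal((20, 30)), 3)
        y = gaussian_filter(rng.standard_normal((20, 30)), 3)
        s1 = vx.compute_sign_map(x, y).sign
        s2 = vx.compute_sign_map(y, x).sign
        assert np.allclose(s1, -s2, equal_nan=True)

    def test_flat_field_masked(self):
        sm = vx.compute_sign_map(np.ones((5, 5)), np.ones((5, 5)))
        assert np.isnan(sm.sign).all() and sm.n_parcels == 0
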