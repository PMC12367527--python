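"""Generator ground truth: calibration, determinism, regimes, behaviour."""

import numpy as np
import pytest

import vrcortex as vx
from vrcortex.simulate import (DEFAULT_COHORTS, LickPolicy,
                               analytic_pooled_dprime,
                               rectified_gaussian_moments)


class TestRectifiedGaussianOracle:
    def test_moments_match_monte_carlo(self, rng):
        m, s = 0.4, 0.7
        mean, var = rectified_gaussian_moments(np.array([m]), s)
        draws = np.maximum(rng.normal(m, s, 400_000), 0.0)
        assert mean[0] == pytest.approx(draws.mean(), abs=3e-3)
        assert var[0] == pytest.approx(draws.var(), abs=3e-3)

    def test_noise_free_limit(self):
        mean, var = rectified_gaussian_moments(np.array([-1.0, 0.5]), 0.0)
        assert np.allclose(mean, [0.0, 0.5]) and np.allclose(var, 0.0)


class TestSelectivityCalibration:
    def test_zero_target_leaves_classes_indistinguishable(self):
        cfg = vx.SimConfig(n_neurons=300, n_trials=60, target_dprime=0.0,
                           rp_fraction=0.0, seed=2)
        session, trials, gt = vx.simulate_session(cfg)
        mask = vx.compute_running_mask(session.speed, session.frame_times)
        d = vx.session_dprime(session, trials, "leaf1", "circle1", mask)
        sel = gt.neuron_class != "none"
        # planted-but-null neurons look like the background population
        assert abs(np.abs(d[sel]).mean() - np.abs(d[~sel]).mean()) < 0.05

    def test_planted_dprime_recovered(self):
        cfg = vx.SimConfig(n_neurons=400, n_trials=200, target_dprime=1.0,
                           rp_fraction=0.0, seed=3)
        session, trials, gt = vx.simulate_session(cfg)
        mask = vx.compute_running_mask(session.speed, session.frame_times)
        d = vx.session_dprime(session, trials, "leaf1", "circle1", mask)
        pos = gt.neuron_class == "selective_pos"
        neg = gt.neuron_class == "selective_neg"
        assert d[pos].mean() == pytest.approx(1.0, abs=0.03)
        assert d[neg].mean() == pytest.approx(-1.0, abs=0.03)

    def test_planted_class_separability(self):
        """With target d'=1 and >=100 trials nearly all planted neurons pass
        the 0.3 criterion while the false-positive rate stays at the level
        the d'-estimator sampling noise predicts."""
        # pause-free running keeps the position occupancy identical on
        # every trial, so the d' estimator noise is the iid-sample term
        cfg = vx.SimConfig(n_neurons=600, n_trials=100, target_dprime=1.0,
                           rp_fraction=0.0, pause_prob=0.0, seed=4)
        session, trials, gt = vx.simulate_session(cfg)
        mask = vx.compute_running_mask(session.speed, session.frame_times)
        d = vx.session_dprime(session, trials, "leaf1", "circle1", mask)
        planted = gt.neuron_class != "none"
        assert (np.abs(d[planted]) >= 0.3).mean() >= 0.95
        # Oracle false-positive rate: per-neuron analytic d' of the
        # generating model (nonzero for bumps truncated by a corridor edge
        # in one corridor only) plus the estimator's sampling s.e.
        from scipy.stats import norm
        keep = mask.mask & np.isfinite(session.position) & \
            (session.position < 4.0)
        n_samp = min((keep & np.isin(session.trial_id,
                                     trials.trial_ids(s))).sum()
                     for s in ("leaf1", "circle1"))
        se = np.sqrt(2.0 / n_samp)
        null = np.flatnonzero(~planted)
        grid = np.arange(67) * 0.06  # the running occupancy grid
        curves = {}
        for stim in ("leaf1", "circle1"):
            pref = gt.pref_position[stim][null]
            curves[stim] = cfg.baseline + gt.bump_amp[null, None] * np.exp(
                -0.5 * ((grid[None, :] - pref[:, None])
                        / cfg.bump_width) ** 2)
        true_d = analytic_pooled_dprime(curves["leaf1"], curves["circle1"],
                                        cfg.noise_scale)
        p_fp = (norm.sf((0.3 - true_d) / se)
                + norm.cdf((-0.3 - true_d) / se))
        fp_oracle = p_fp.mean()
        fp = (np.abs(d[null]) >= 0.3).mean()
        assert fp <= fp_oracle + 2 * np.sqrt(max(fp_oracle, 1e-6)
                                             * (1 - fp_oracle) / null.size)

    def test_analytic_oracle_matches_empirical_pool(self, rng):
        grid = np.linspace(0.05, 3.95, 40)
        curve1 = 0.2 + 1.0 * np.exp(-0.5 * ((grid - 2.0) / 0.4) ** 2) + 0.5
        curve2 = 0.2 + 1.0 * np.exp(-0.5 * ((grid - 1.0) / 0.4) ** 2)
        d_analytic = analytic_pooled_dprime(curve1[None], curve2[None], 0.3)[0]
        draws1 = np.maximum(curve1[:, None]
                            + rng.normal(0, 0.3, (40, 20000)), 0).ravel()
        draws2 = np.maximum(curve2[:, None]
                            + rng.normal(0, 0.3, (40, 20000)), 0).ravel()
        d_emp = vx.compute_dprime(draws1, draws2)
        assert d_analytic == pytest.approx(d_emp, abs=0.02)


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        cfg = vx.SimConfig(n_neurons=50, n_trials=10, seed=9)
        s1, t1, g1 = vx.simulate_session(cfg)
        s2, t2, g2 = vx.simulate_session(cfg)
        assert np.array_equal(s1.activity, s2.activity)
        assert t1.trials.equals(t2.trials)
        assert t1.licks.equals(t2.licks)
        assert np.array_equal(g1.delta, g2.delta)

    def test_image_responses_deterministic(self):
        cfg = vx.RetinoSimConfig(n_kernels=3, n_neurons=40, n_images=50,
                                 n_clusters=8, seed=5)
        i1, r1, k1, _ = vx.simulate_image_responses(cfg)
        i2, r2, k2, _ = vx.simulate_image_responses(cfg)
        assert np.array_equal(i1, i2) and np.array_equal(r1, r2)
        assert np.array_equal(k1, k2)


class TestImageResponses:
    def test_noiseless_responses_follow_encoding_model(self, demo_retino):
        _, images, responses, kernels, gt = demo_retino
        from vrcortex.retinotopy import kernel_response_maps
        maps = kernel_response_maps(images, kernels)
        expected = gt.rf_amp[:, None] * maps[gt.rf_kernel, gt.rf_y, gt.rf_x, :]
        assert np.allclose(responses[:, :, 0], expected, atol=1e-4)
        # repeats share the mean (noise-free)
        assert np.array_equal(responses[:, :, 0], responses[:, :, 1])

    def test_planted_gradient_monotone_in_tissue(self, demo_retino):
        _, _, _, _, gt = demo_retino
        order = np.argsort(gt.aligned_tissue_xy[:, 0], kind="stable")
        # cluster-shared map positions: monotone non-decreasing up to the
        # within-cluster tissue scatter
        x_sorted = gt.rf_x[order]
        from scipy.stats import spearmanr
        assert spearmanr(gt.aligned_tissue_xy[:, 0], gt.rf_x).statistic > 0.97
        assert np.median(np.diff(x_sorted) >= 0) == 1.0

    def test_repeat_average_reduces_noise(self):
        cfg = vx.RetinoSimConfig(n_kernels=3, n_neurons=60, n_images=200,
                                 n_clusters=10, n_repeats=3, noise_scale=1.0,
                                 seed=6)
        images, responses, kernels, gt = vx.simulate_image_responses(cfg)
        from vrcortex.retinotopy import kernel_response_maps
        maps = kernel_response_maps(images, kernels)
        clean = gt.rf_amp[:, None] * maps[gt.rf_kernel, gt.rf_y, gt.rf_x, :]
        err_single = np.mean((responses[:, :, 0] - clean) ** 2)
        err_mean = np.mean((responses.mean(axis=2) - clean) ** 2)
        assert err_mean == pytest.approx(err_single / 3, rel=0.15)


class TestBehaviourCohorts:
    def test_perfect_discrimination_gives_unit_difference(self):
        cfg = vx.SimConfig(n_neurons=10, n_trials=10, seed=0)
        table = vx.simulate_behavior_cohorts(
            cfg, n_mice=2, days=3,
            policies={"perfect": LickPolicy(level=1.0, tau=0.0)})
        daily = vx.daily_performance(table)
        assert np.allclose(daily["difference"], 1.0)

    def test_zero_discrimination_gives_no_difference(self):
        cfg = vx.SimConfig(n_neurons=10, n_trials=10, seed=0)
        table = vx.simulate_behavior_cohorts(
            cfg, n_mice=4, days=2, n_trials=200,
            policies={"blind": LickPolicy(level=0.0, tau=0.0)})
        daily = vx.daily_performance(table)
        assert np.abs(daily["difference"]).max() < 0.1

    def test_pretraining_speeds_learning(self):
        cfg = vx.SimConfig(n_neurons=10, n_trials=10, seed=1)
        table = vx.simulate_behavior_cohorts(cfg, n_mice=6, days=5,
                                             n_trials=100,
                                             policies=DEFAULT_COHORTS)
        daily = vx.daily_performance(table)
        day1 = daily[daily["day"] == 1].groupby("cohort")["difference"].mean()
        assert day1["pretrained"] > day1["no_pretraining"]
        # oracle: the configured learning curves themselves
        pol = DEFAULT_COHORTS
        assert (pol["pretrained"].discrimination(1)
                > pol["no_pretraining"].discrimination(1))

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            vx.SimConfig(selective_fraction={"V1": 1.2, "medial": 0,
                                             "lateral": 0, "anterior": 0})
        with pytest.raises(ValueError):
            vx.SimConfig(n_trials=2)
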