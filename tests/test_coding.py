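"""Normalization, coding axis, projections, similarity index."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import vrcortex as vx
from vrcortex.session import TuningMatrix, position_bins


def tuning_from(values, stimulus="leaf1"):
    values = np.asarray(values, dtype=np.float32)
    return TuningMatrix(values, position_bins(0.1), stimulus, 0.1,
                        np.arange(values.shape[0]))


class TestNormalization:
    def setup_method(self):
        rng = np.random.default_rng(0)
        self.r1 = rng.uniform(1, 2, (4, 60, 3))
        self.r2 = rng.uniform(0.5, 1.5, (4, 60, 3))
        self.tunings = {"leaf1": tuning_from(self.r1),
                        "circle1": tuning_from(self.r2, "circle1")}

    def test_activity_at_baseline_normalizes_to_zero(self):
        mu = np.full(3, 1.5)
        r = {k: tuning_from(np.full((2, 60, 3), 1.5), k)
             for k in ("leaf1", "circle1")}
        # zero variance -> all neurons invalid (excluded), values NaN
        norm = vx.normalize_activity(r, mu, ("leaf1", "circle1"))
        assert not norm.valid.any()

    def test_unit_excursion_normalizes_to_one(self):
        norm = vx.normalize_activity(self.tunings, np.zeros(3),
                                     ("leaf1", "circle1"))
        s = 0.5 * (norm.sigma_ref["leaf1"] + norm.sigma_ref["circle1"])
        manual = self.r1 / s[None, None, :]
        assert np.allclose(norm.values["leaf1"], manual, atol=1e-6)

    def test_scale_invariance_per_neuron(self):
        """Scaling one neuron's activity (and baseline) by 3 leaves its
        normalized activity unchanged, because mu and sigma scale together."""
        mu = np.array([0.2, 0.2, 0.2])
        norm1 = vx.normalize_activity(self.tunings, mu, ("leaf1", "circle1"))
        scaled = {k: tuning_from(v.values * 3.0, k)
                  for k, v in self.tunings.items()}
        norm2 = vx.normalize_activity(scaled, mu * 3.0, ("leaf1", "circle1"))
        assert np.allclose(norm1.values["leaf1"], norm2.values["leaf1"],
                           atol=1e-5)


class TestCodingAxis:
    def test_top_five_percent_each_way(self):
        d = np.linspace(-1, 1, 100)
        axis = vx.fit_coding_axis(d, percentile=5.0)
        assert axis.positive.size == 5 and axis.negative.size == 5
        assert set(axis.positive) == set(range(95, 100))
        assert set(axis.negative) == set(range(5))

    def test_ties_break_by_neuron_index_and_sets_disjoint(self):
        axis = vx.fit_coding_axis(np.zeros(40), percentile=5.0)
        assert axis.positive.tolist() == [0, 1]
        assert axis.negative.tolist() == [2, 3]

    def test_small_pool_raises(self):
        with pytest.raises(ValueError):
            vx.fit_coding_axis(np.zeros(39))

    def test_weights_formulation(self):
        axis = vx.fit_coding_axis(np.linspace(-1, 1, 100))
        w = axis.weights(100)
        assert w.sum() == pytest.approx(0.0)
        assert np.count_nonzero(w) == 10

    def test_axis_members_are_planted_selective(self, demo_session):
        cfg, session, trials, gt, mask = demo_session
        d = vx.session_dprime(session, trials, "leaf1", "circle1", mask)
        axis = vx.fit_coding_axis(d, 5.0, ("leaf1", "circle1"))
        frac_pos = np.mean(gt.neuron_class[axis.positive] != "none")
        frac_neg = np.mean(gt.neuron_class[axis.negative] == "selective_neg")
        assert frac_pos >= 0.9 and frac_neg >= 0.9


class TestProjection:
    def run_projection(self, exclude_train=True, seed=123):
        cfg = vx.SimConfig(
            n_neurons=300, n_trials=60, stimuli=("leaf1", "circle1"),
            rp_fraction=0.0, selective_fraction={
                "V1": 0.3, "medial": 0.3, "lateral": 0.3, "anterior": 0.3},
            seed=seed)
        session, trials, _ = vx.simulate_session(cfg)
        mask = vx.compute_running_mask(session.speed, session.frame_times)
        split = vx.split_trials(trials, ("leaf1", "circle1"), seed=0)
        d = vx.session_dprime(session, trials, "leaf1", "circle1", mask,
                              split.train["leaf1"], split.train["circle1"])
        tunings = {s: vx.build_tuning_matrix(session, trials, s, 0.1, mask)
                   for s in ("leaf1", "circle1")}
        mu = vx.grey_baseline(session, trials, ("leaf1", "circle1"), mask)
        norm = vx.normalize_activity(tunings, mu, ("leaf1", "circle1"))
        axis = vx.fit_coding_axis(d, 5.0, ("leaf1", "circle1"),
                                  valid=norm.valid)
        excl = ({"leaf1": split.train["leaf1"],
                 "circle1": split.train["circle1"]} if exclude_train else
                {"leaf1": split.test("leaf1"),
                 "circle1": split.test("circle1")})
        return vx.project_trials(norm, axis, exclude_trials=excl)

    def test_identical_populations_project_to_zero(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(0, 1, (3, 60, 6))
        vals[:, :, 3:] = vals[:, :, :3]  # negative set mirrors positive set
        norm = vx.normalize_activity(
            {"leaf1": tuning_from(vals), "circle1": tuning_from(vals)},
            np.zeros(6), ("leaf1", "circle1"))
        axis = vx.CodingAxis(np.array([0, 1, 2]), np.array([3, 4, 5]),
                             ("leaf1", "circle1"), 50.0)
        proj = vx.project_trials(norm, axis)
        assert np.allclose(proj.per_trial["leaf1"], 0.0, atol=1e-6)

    def test_planted_structure_separates_held_out_trials(self):
        proj = self.run_projection()
        assert proj.a_proj["leaf1"] > 0 > proj.a_proj["circle1"]

    def test_weight_and_mean_difference_formulations_agree(self):
        rng = np.random.default_rng(2)
        vals = rng.uniform(0, 1, (4, 60, 10)).astype(np.float32)
        norm = vx.normalize_activity(
            {"leaf1": tuning_from(vals),
             "circle1": tuning_from(rng.uniform(0, 1, (4, 60, 10)))},
            np.zeros(10), ("leaf1", "circle1"))
        axis = vx.CodingAxis(np.array([0, 1, 2]), np.array([5, 6]),
                             ("leaf1", "circle1"), 25.0)
        proj = vx.project_trials(norm, axis)
        w = np.zeros(10)
        w[axis.positive] = 1 / 3
        w[axis.negative] = -1 / 2
        manual = np.tensordot(norm.values["leaf1"], w, axes=(2, 0))
        assert np.allclose(proj.per_trial["leaf1"], manual, atol=1e-5)

    def test_selection_bias_on_training_trials(self):
        """a_proj evaluated on the axis-fitting trials exceeds the held-out
        value: the reason projections are always cross-validated."""
        held_out = self.run_projection(exclude_train=True)
        train = self.run_projection(exclude_train=False)
        sep_out = held_out.a_proj["leaf1"] - held_out.a_proj["circle1"]
        sep_in = train.a_proj["leaf1"] - train.a_proj["circle1"]
        assert sep_in > sep_out


class TestSimilarityIndex:
    def test_probe_at_references_and_midpoint(self):
        a = {"leaf1": 2.0, "circle1": -1.0}
        assert vx.similarity_index({**a, "p": 2.0}, ("leaf1", "circle1"),
                                   "p").si == pytest.approx(1.0)
        assert vx.similarity_index({**a, "p": -1.0}, ("leaf1", "circle1"),
                                   "p").si == pytest.approx(-1.0)
        assert vx.similarity_index({**a, "p": 0.5}, ("leaf1", "circle1"),
                                   "p").si == pytest.approx(0.0)

    def test_out_of_range_flagged_not_clipped(self):
        res = vx.similarity_index({"leaf1": 1.0, "circle1": -1.0, "p": 2.0},
                                  ("leaf1", "circle1"), "p")
        assert res.si > 1.0 and res.out_of_range

    def test_degenerate_axis_raises(self):
        with pytest.raises(ValueError):
            vx.similarity_index({"leaf1": 1.0, "circle1": 1.0, "p": 0.0},
                                ("leaf1", "circle1"), "p")

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.floats(-5, 5), st.floats(-5, 5), st.floats(-5, 5),
           st.floats(-10, 10), st.floats(0.01, 10))
    def test_affine_invariance(self, a1, a2, p, shift, scale):
        if abs(a1 - a2) < 1e-6:
            return
        base = vx.similarity_index({"x": a1, "y": a2, "p": p}, ("x", "y"),
                                   "p").si
        moved = vx.similarity_index(
            {"x": scale * a1 + shift, "y": scale * a2 + shift,
             "p": scale * p + shift}, ("x", "y"), "p").si
        assert moved == pytest.approx(base, rel=1e-9, abs=1e-9)
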