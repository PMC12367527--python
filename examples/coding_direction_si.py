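"""Coding-direction projections and the similarity index (SI).

The coding axis is the pair of top-5% d'-selective populations from train
trials; held-out trials are projected as the difference of the two
populations' mean normalized activity, and the similarity index locates a
probe stimulus between the two references (+1 at leaf1, -1 at circle1,
0 at the midpoint).  Sweeping the probe's category drive from full to
none moves its projection from the leaf1 end toward the midpoint -- the
orthogonalization signature of a stimulus becoming familiar.
"""

import vrcortex as vx

print("probe drive -> a_proj(leaf2), SI(leaf2)")
for beta in (1.0, 0.75, 0.5, 0.25, 0.0):
    cfg = vx.SimConfig(n_neurons=300, n_trials=60, noise_scale=0.0,
                       stimuli=("leaf1", "circle1", "leaf2"),
                       stimulus_drives={"leaf2": (beta, 0.0)},
                       rp_fraction=0.0,
                       selective_fraction={"V1": 0.3, "medial": 0.3,
                                           "lateral": 0.3, "anterior": 0.3},
                       seed=5)
    session, trials, _ = vx.simulate_session(cfg)
    mask = vx.compute_running_mask(session.speed, session.frame_times)
    split = vx.split_trials(trials, ("leaf1", "circle1"), seed=0)
    d = vx.session_dprime(session, trials, "leaf1", "circle1", mask,
                          split.train["leaf1"], split.train["circle1"])
    tunings = {s: vx.build_tuning_matrix(session, trials, s, 0.1, mask)
               for s in cfg.stimuli}
    mu_grey = vx.grey_baseline(session, trials, ("leaf1", "circle1"), mask)
    norm = vx.normalize_activity(tunings, mu_grey, ("leaf1", "circle1"))
    axis = vx.fit_coding_axis(d, 5.0, ("leaf1", "circle1"), valid=norm.valid)
    proj = vx.project_trials(norm, axis,
                             exclude_trials={"leaf1": split.train["leaf1"],
                                             "circle1": split.train["circle1"]})
    si = vx.similarity_index(proj.a_proj, ("leaf1", "circle1"), "leaf2")
    print(f"  beta={beta:4.2f}: a_leaf1={proj.a_proj['leaf1']:+.3f} "
          f"a_circle1={proj.a_proj['circle1']:+.3f} "
          f"a_leaf2={proj.a_proj['leaf2']:+.3f}  SI={si.si:+.3f}")
# SI decreases monotonically from ~+1 toward 0 as the probe's drive
# fades: its representation becomes orthogonal to the leaf1-circle1 axis.
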