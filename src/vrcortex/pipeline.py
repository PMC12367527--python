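"""End-to-end orchestration: simulate -> analyze -> report.

Runs every analysis stage on a session (simulated or loaded from a
container), writes TSV/JSON artifacts per stage plus a manifest, and
houses the group-comparison statistics (two-sided Student's t-tests,
paired or independent, reported raw without multiple-comparison
adjustment; summary error bars are s.e.m.).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import behavior, coding, reward, retinotopy, selectivity, sequences
from .session import (SessionRecording, TrialTable, build_tuning_matrix,
                      compute_running_mask, read_session, write_session)
from .simulate import (RetinoSimConfig, SimConfig, simulate_image_responses,
                       simulate_session)

logger = logging.getLogger("vrcortex")

__version__ = "0.1.0"


@dataclass
class AnalysisConfig:
    """Resolved settings of one pipeline run (serializable to JSON)."""

    selectivity_threshold: float = 0.3
    axis_percentile: float = 5.0
    bin_step: float = 0.1
    speed_threshold: float = 6.0  # cm/s
    min_run_duration: float = 66.0  # ms
    density_bin: float = 100.0  # μm
    density_sigma: float = 200.0  # μm
    cv_folds: int = 10
    seed: int = 1
    reference_pair: tuple = ("leaf1", "circle1")
    use_atlas: bool = True
    sim: dict = field(default_factory=dict)  # SimConfig overrides
    retino: dict | None = None  # RetinoSimConfig overrides, None = skip

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self),
                                         sort_keys=True, indent=1))

    @classmethod
    def from_json(cls, path) -> "AnalysisConfig":
        data = json.loads(Path(path).read_text())
        data["reference_pair"] = tuple(data.get("reference_pair",
                                                ("leaf1", "circle1")))
        return cls(**data)


@dataclass
class GroupComparison:
    statistic: float
    p_value: float
    kind: str
    n: tuple
    missing_reason: str | None = None


def compare_groups(values_a, values_b, paired: bool = False) -> GroupComparison:
    """Two-sided Student's t-test between two groups of session values."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    kind = "paired" if paired else "independent"
    if paired:
        if a.size != b.size:
            raise ValueError("paired test requires equal group sizes")
        if np.std(a - b) == 0:
            return GroupComparison(float("nan"), float("nan"), kind,
                                   (a.size, b.size),
                                   "zero variance in paired differences")
        res = stats.ttest_rel(a, b)
    else:
        res = stats.ttest_ind(a, b)
    return GroupComparison(float(res.statistic), float(res.pvalue), kind,
                           (a.size, b.size))


def significance_stars(p: float) -> str:
    """Report-rendering stars; p-values themselves stay raw."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "NS"


def sem(values) -> float:
    v = np.asarray(values, dtype=float)
    return float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else float("nan")


# ---------------------------------------------------------------------------
# pipeline


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, sort_keys=True, indent=1,
                               default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not serializable: {type(o)}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_done(files) -> bool:
    return all(Path(f).exists() for f in files)


def run_pipeline(config: AnalysisConfig, out_dir, session_path=None,
                 force: bool = True) -> dict:
    """Execute every analysis stage and write a report bundle.

    With ``force=False`` a stage whose output files already exist is
    skipped, so deleting one stage's outputs and re-running regenerates
    only that stage.  Returns the manifest (also written as
    ``manifest.json``); all outputs are deterministic for a fixed seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed, "stages": {}}

    if session_path is not None:
        session, trials = read_session(session_path)
        manifest["input"] = {"path": str(session_path),
                             "sha256": _sha256(Path(session_path))}
    else:
        sim_cfg = SimConfig(**{"seed": config.seed, **config.sim})
        session, trials, gt = simulate_session(sim_cfg)
        sess_file = out / "session.h5"
        write_session(session, trials, sess_file)
        gt.to_frame().to_csv(out / "ground_truth.tsv", sep="\t",
                             index_label="neuron_id", float_format="%.10g")
        manifest["input"] = {"simulated": True,
                             "sim_config": dataclasses.asdict(sim_cfg)}

    mask = compute_running_mask(session.speed, session.frame_times,
                                config.speed_threshold, config.min_run_duration)
    ref_a, ref_b = config.reference_pair
    stimuli = list(dict.fromkeys(trials.trials["stimulus"]))
    atlas = selectivity.default_atlas() if config.use_atlas else None

    # --- selectivity stage -------------------------------------------------
    files = [out / "selectivity.tsv", out / "density_map.tsv",
             out / "region_fractions.json"]
    if force or not _stage_done(files):
        try:
            d = selectivity.session_dprime(session, trials, ref_a, ref_b, mask)
            sel = selectivity.select_neurons(d, config.selectivity_threshold,
                                             (ref_a, ref_b))
            cls = np.full(d.size, "none", dtype=object)
            cls[sel.selected_pos] = "positive"
            cls[sel.selected_neg] = "negative"
            region = (atlas.region_of(session.tissue_xy) if atlas is not None
                      else np.full(d.size, "", dtype=str))
            _write_tsv(pd.DataFrame({"neuron_id": np.arange(d.size),
                                     "dprime": d, "class": cls,
                                     "region": region}), files[0])
            dm = selectivity.density_map(session.tissue_xy[sel.selected],
                                         session.tissue_xy, config.density_bin,
                                         config.density_sigma)
            np.savetxt(files[1], dm.grid, delimiter="\t", fmt="%.10g")
            if atlas is not None:
                fr = selectivity.region_fraction(sel, atlas, session.tissue_xy)
            else:
                logger.warning("no atlas configured; regional stage skipped")
                fr = {}
            _write_json({"fractions_pct": fr,
                         "density_meta": {"bin_um": config.density_bin,
                                          "sigma_um": config.density_sigma}},
                        files[2])
        except Exception:
            logger.exception("selectivity stage failed")
            raise RuntimeError("stage failed: selectivity")
    manifest["stages"]["selectivity"] = [f.name for f in files]

    # --- tuning matrices shared by later stages ----------------------------
    split = sequences.split_trials(trials, (ref_a, ref_b), seed=config.seed)
    d_train = selectivity.session_dprime(
        session, trials, ref_a, ref_b, mask,
        trial_subset_a=split.train[ref_a], trial_subset_b=split.train[ref_b])
    sel_train = selectivity.select_neurons(d_train,
                                           config.selectivity_threshold,
                                           (ref_a, ref_b))
    tunings = {s: build_tuning_matrix(session, trials, s, config.bin_step, mask)
               for s in stimuli}

    # --- sequences stage ---------------------------------------------------
    files = [out / "preferred_positions.tsv", out / "sequence_correlations.json"]
    if force or not _stage_done(files):
        rows = []
        pref_sets = {}
        for stim in stimuli:
            for name in ("odd", "even"):
                ids = getattr(split, f"test_{name}")[stim]
                if ids.size == 0:
                    continue
                pp = sequences.preferred_positions(
                    tunings[stim].subset(ids), sel_train, split=name)
                pref_sets[(stim, name)] = pp
                rows.extend({"neuron_id": n, "stimulus": stim, "split": name,
                             "preferred_position": p}
                            for n, p in zip(pp.neuron_ids, pp.positions))
        _write_tsv(pd.DataFrame(rows), files[0])
        corrs = {}
        for stim in stimuli:
            key = (stim, "odd")
            if key in pref_sets and (ref_a, "even") in pref_sets:
                try:
                    sc = sequences.sequence_correlation(
                        pref_sets[(ref_a, "even")], pref_sets[key])
                    corrs[f"{ref_a}_even_vs_{stim}_odd"] = sc.r
                except ValueError:
                    corrs[f"{ref_a}_even_vs_{stim}_odd"] = None
        _write_json(corrs, files[1])
    manifest["stages"]["sequences"] = [f.name for f in files]

    # --- coding-direction stage --------------------------------------------
    files = [out / "projections.tsv", out / "similarity_index.json"]
    if force or not _stage_done(files):
        mu_grey = coding.grey_baseline(session, trials, (ref_a, ref_b), mask)
        norm = coding.normalize_activity(tunings, mu_grey, (ref_a, ref_b))
        axis = coding.fit_coding_axis(d_train, config.axis_percentile,
                                      (ref_a, ref_b), valid=norm.valid)
        proj = coding.project_trials(
            norm, axis, exclude_trials={ref_a: split.train[ref_a],
                                        ref_b: split.train[ref_b]})
        rows = []
        for stim, a_tr in proj.a_proj_trials.items():
            rows.extend({"stimulus": stim, "trial": i, "a_proj": a}
                        for i, a in enumerate(a_tr))
        _write_tsv(pd.DataFrame(rows), files[0])
        si = {}
        for stim in stimuli:
            if stim in proj.a_proj:
                try:
                    res = coding.similarity_index(proj.a_proj, (ref_a, ref_b),
                                                  stim)
                    si[stim] = {"si": res.si, "dx": res.dx, "dy": res.dy,
                                "out_of_range": res.out_of_range}
                except ValueError:
                    si[stim] = None
        _write_json(si, files[1])
    manifest["stages"]["coding_direction"] = [f.name for f in files]

    # --- reward-prediction stage --------------------------------------------
    files = [out / "reward_prediction.tsv", out / "cv_trace.tsv"]
    rewarded_stim = ref_a
    if force or not _stage_done(files):
        try:
            early, late = reward.split_by_cue(trials, rewarded_stim)
            rp = reward.dprime_late_vs_early(tunings[rewarded_stim], trials,
                                             early, late)
            flags = np.zeros(rp.dprime.size, bool)
            flags[rp.selected] = True
            _write_tsv(pd.DataFrame({"neuron_id": np.arange(rp.dprime.size),
                                     "dprime_late_vs_early": rp.dprime,
                                     "selected": flags}), files[0])
            cv = reward.crossval_population_trace(
                tunings[rewarded_stim], trials, k=config.cv_folds,
                seed=config.seed)
            cv_df = pd.DataFrame(cv.trace,
                                 columns=[f"bin_{i}" for i in
                                          range(cv.trace.shape[1])])
            cv_df.insert(0, "fold", cv.fold)
            cv_df.insert(0, "trial_index", cv.trial_indices)
            _write_tsv(cv_df, files[1])
        except ValueError as exc:
            logger.warning("reward-prediction stage skipped: %s", exc)
            _write_tsv(pd.DataFrame(), files[0])
            _write_tsv(pd.DataFrame(), files[1])
    manifest["stages"]["reward_prediction"] = [f.name for f in files]

    # --- behaviour stage -----------------------------------------------------
    files = [out / "behavior.tsv", out / "behavior_summary.json"]
    if force or not _stage_done(files):
        rows = []
        for tid, tr in trials.trials.iterrows():
            lp = trials.lick_positions(tid)
            rows.append({
                "trial_index": tid, "stimulus": tr["stimulus"],
                "cue_position": tr["cue_position"],
                "first_lick": lp[0] if lp.size else np.nan,
                "n_licks": lp.size,
                "response": behavior.anticipatory_lick_response(
                    lp, tr["cue_position"]),
            })
        bdf = pd.DataFrame(rows)
        _write_tsv(bdf, files[0])
        rates = {s: float(g["response"].mean())
                 for s, g in bdf.groupby("stimulus", sort=True)}
        summary = {"response_rates": rates}
        if ref_a in rates and ref_b in rates:
            summary["difference"] = rates[ref_a] - rates[ref_b]
        _write_json(summary, files[1])
    manifest["stages"]["behavior"] = [f.name for f in files]

    # --- retinotopy stage (optional) ----------------------------------------
    if config.retino is not None:
        files = [out / "rf_assignments.tsv", out / "alignment.json",
                 out / "sign_map.tsv"]
        if force or not _stage_done(files):
            rcfg = RetinoSimConfig(**{"seed": config.seed, **config.retino})
            images, responses, _, rgt = simulate_image_responses(rcfg)
            bank, _ = retinotopy.fit_kernel_bank(
                responses, images, n_kernels=rcfg.n_kernels,
                kernel_size=rcfg.kernel_size, seed=config.seed)
            assign = retinotopy.assign_neurons_smoothed(
                responses, images, bank, rgt.tissue_xy,
                n_neighbors=min(50, rcfg.n_neurons))
            _write_tsv(pd.DataFrame({"neuron_id": np.arange(assign.x.size),
                                     "x": assign.x, "y": assign.y,
                                     "kernel": assign.kernel,
                                     "amplitude": assign.amplitude,
                                     "correlation": assign.correlation}),
                       files[0])
            krig = retinotopy.fit_kriging_transform(
                rgt.tissue_xy, np.column_stack([assign.x, assign.y]))
            fit = retinotopy.align_session(
                rgt.tissue_xy, np.column_stack([assign.x, assign.y]), krig,
                search_range=100.0, max_iter=50)
            _write_json({"A1": fit.a1, "A2": fit.a2, "cost": fit.cost,
                         "sigma_um": krig.sigma, "converged": fit.converged},
                        files[1])
            gx = np.linspace(rgt.tissue_xy[:, 0].min(),
                             rgt.tissue_xy[:, 0].max(), 40)
            gy = np.linspace(rgt.tissue_xy[:, 1].min(),
                             rgt.tissue_xy[:, 1].max(), 20)
            gridp = np.array([[x, y] for y in gy for x in gx])
            pred = krig.predict(gridp)
            xf = pred[:, 0].reshape(gy.size, gx.size)
            yf = pred[:, 1].reshape(gy.size, gx.size)
            sm = retinotopy.compute_sign_map(xf, yf)
            np.savetxt(files[2], sm.sign, delimiter="\t", fmt="%.10g")
        manifest["stages"]["retinotopy"] = [f.name for f in files]

    # --- manifest ------------------------------------------------------------
    manifest["config"] = dataclasses.asdict(config)
    manifest["files"] = {
        f.name: _sha256(f) for f in sorted(out.iterdir())
        if f.is_file() and f.name != "manifest.json"}
    _write_json(manifest, out / "manifest.json")
    return manifest
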