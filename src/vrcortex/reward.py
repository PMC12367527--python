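"""Reward-prediction signal detection and cross-validated population traces.

Reward-prediction neurons anticipate reward: their activity ramps from
corridor entry and is shut off by the cue/reward.  Because the sound cue
position varies per trial, trials of the rewarded corridor can be divided
into early-cue and late-cue halves; a neuron whose activity tracks reward
expectation accumulates more pre-cue ramp on late-cue trials, whereas a
purely stimulus-driven neuron has identical profiles in both halves.  The
late-vs-early discrimination index

    d'_late_vs_early = (mu_late - mu_early) / ((sigma_late + sigma_early) / 2)

is computed over per-trial position-profile statistics, and neurons with
d' >= 0.3 (one-sided) are selected.  Population traces are k-fold
cross-validated: each trial is scored only by neurons selected without it,
which removes the selection bias that would otherwise paint a ramp onto
pure noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._util import nanmean, nanstd
from .selectivity import dprime_from_stats
from .session import (RunningMask, SessionRecording, TEXTURE_END, TrialTable,
                      TuningMatrix)

RP_THRESHOLD = 0.3


def split_by_cue(trials: TrialTable, stimulus: str):
    """Median split of one stimulus's trials by sound-cue position.

    Returns (early_ids, late_ids); with an odd trial count the extra trial
    goes to the early set.  All-equal cue positions cannot be split.
    """
    ids = trials.trial_ids(stimulus)
    cues = trials.trials.loc[ids, "cue_position"].to_numpy(float)
    ok = np.isfinite(cues)
    ids, cues = ids[ok], cues[ok]
    if ids.size < 4:
        raise ValueError("need >= 4 trials with cues")
    if np.ptp(cues) == 0:
        raise ValueError("all cue positions equal; cannot split")
    order = np.lexsort((ids, cues))
    n_early = (ids.size + 1) // 2
    return np.sort(ids[order[:n_early]]), np.sort(ids[order[n_early:]])


@dataclass
class RewardPredictionIndex:
    """Per-neuron late-vs-early discrimination with the selection set."""

    dprime: np.ndarray
    threshold: float
    selected: np.ndarray
    window: tuple[float, float]


def _profile_stat(tuning: TuningMatrix, trial_ids, lo: float, hi: float):
    """Per-trial mean of the interpolated profile over positions [lo, hi)."""
    rows = np.flatnonzero(np.isin(tuning.trial_indices, trial_ids))
    bins = (tuning.bin_centres >= lo) & (tuning.bin_centres < hi)
    return nanmean(tuning.values[rows][:, bins, :], axis=1)  # (trials, neurons)


def dprime_late_vs_early(tuning: TuningMatrix, trials: TrialTable,
                         early_ids, late_ids, threshold: float = RP_THRESHOLD,
                         window: str = "pre_cue") -> RewardPredictionIndex:
    """Late-vs-early cue discrimination index per neuron.

    ``window='pre_cue'`` compares per-trial profile means over
    [0, min late-group cue), which is pre-cue territory for every
    late trial while early trials are already cue-suppressed inside it;
    ``window='full'`` uses the whole texture zone [0, 4).  Selection is
    one-sided at ``d' >= threshold``.
    """
    early_ids = np.asarray(early_ids)
    late_ids = np.asarray(late_ids)
    if early_ids.size == 0 or late_ids.size == 0:
        raise ValueError("both cue groups must be non-empty")
    if window == "pre_cue":
        hi = float(trials.trials.loc[late_ids, "cue_position"].min())
    elif window == "full":
        hi = TEXTURE_END
    else:
        raise ValueError("window must be 'pre_cue' or 'full'")
    stat_e = _profile_stat(tuning, early_ids, 0.0, hi)
    stat_l = _profile_stat(tuning, late_ids, 0.0, hi)
    d = dprime_from_stats(nanmean(stat_l, 0), nanstd(stat_l, 0),
                          nanmean(stat_e, 0), nanstd(stat_e, 0))
    selected = np.flatnonzero(np.isfinite(d) & (d >= threshold))
    return RewardPredictionIndex(d, threshold, selected, (0.0, hi))


@dataclass
class CrossValTrace:
    """Per-trial population traces scored by models fitted without each trial."""

    trace: np.ndarray  # (n_trials, n_bins); NaN rows = fold selected no neurons
    trial_indices: np.ndarray
    fold: np.ndarray
    selected_per_fold: list
    bin_centres: np.ndarray


def crossval_population_trace(tuning: TuningMatrix, trials: TrialTable,
                              k: int = 10, seed: int = 0,
                              threshold: float = RP_THRESHOLD,
                              top_k: int | None = None,
                              window: str = "pre_cue") -> CrossValTrace:
    """k-fold cross-validated reward-prediction population trace.

    Trials are shuffled into k folds; for each fold, neurons are selected
    by d'_late_vs_early on the other k-1 folds (threshold rule, or the
    ``top_k`` highest-d' neurons when forcing a selection on null data),
    and the held-out trials are scored as the mean interpolated activity
    over the selected neurons.  Every trial is scored exactly once.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    ids = tuning.trial_indices
    if ids.size < 2 * k:
        raise ValueError("not enough trials for the requested fold count")
    rng = np.random.default_rng(seed)
    fold_of = np.empty(ids.size, dtype=int)
    fold_of[rng.permutation(ids.size)] = np.arange(ids.size) % k
    trace = np.full((ids.size, tuning.n_bins), np.nan)
    selected_per_fold = []
    for f in range(k):
        test_rows = np.flatnonzero(fold_of == f)
        train_ids = ids[fold_of != f]
        early, late = split_by_cue_subset(trials, tuning.stimulus, train_ids)
        rp = dprime_late_vs_early(tuning, trials, early, late,
                                  threshold=threshold, window=window)
        if top_k is not None:
            finite = np.flatnonzero(np.isfinite(rp.dprime))
            order = finite[np.argsort(-rp.dprime[finite], kind="stable")]
            selected = np.sort(order[:top_k])
        else:
            selected = rp.selected
        selected_per_fold.append(selected)
        if selected.size:
            trace[test_rows] = nanmean(
                tuning.values[test_rows][:, :, selected], axis=2)
    return CrossValTrace(trace, ids, fold_of, selected_per_fold,
                         tuning.bin_centres)


def split_by_cue_subset(trials: TrialTable, stimulus: str, subset_ids):
    """Median cue split restricted to a subset of trials (for CV folds)."""
    subset_ids = np.asarray(subset_ids)
    cues = trials.trials.loc[subset_ids, "cue_position"].to_numpy(float)
    ok = np.isfinite(cues)
    ids, cues = subset_ids[ok], cues[ok]
    if ids.size < 4:
        raise ValueError("need >= 4 trials with cues")
    if np.ptp(cues) == 0:
        raise ValueError("all cue positions equal; cannot split")
    order = np.lexsort((ids, cues))
    n_early = (ids.size + 1) // 2
    return np.sort(ids[order[:n_early]]), np.sort(ids[order[n_early:]])


def population_trace(tuning: TuningMatrix, selected) -> np.ndarray:
    """Plain (non-cross-validated) per-trial mean over a fixed neuron set."""
    return nanmean(tuning.values[:, :, np.asarray(selected)], axis=2)


@dataclass
class EventAlignedTrace:
    """Population activity and lick rate on a time axis centred on an event."""

    time: np.ndarray
    activity: np.ndarray  # trial-averaged population activity
    lick_rate: np.ndarray  # Hz, smoothed
    included_trials: np.ndarray
    excluded: dict  # trial id -> reason


def align_to_event(session: SessionRecording, trials: TrialTable,
                   neuron_ids, stimulus: str, event: str = "cue",
                   window: float = 3.0, lick_bin: float = 0.1,
                   lick_smooth: float = 0.25) -> EventAlignedTrace:
    """Trial-averaged population activity aligned to the cue or first lick.

    ``event='first_lick'`` includes only trials whose first lick came
    after 2 m (which rules out alignment artefacts from early consummatory
    licking); trials with no qualifying event are excluded with a reason.
    Window overhangs beyond the recorded trace are missing (NaN), never
    zero-filled.  The lick rate is computed in ``lick_bin``-second bins
    and box-smoothed over ``lick_smooth`` seconds.
    """
    ids = trials.trial_ids(stimulus)
    neuron_ids = np.asarray(neuron_ids)
    dt = float(np.median(np.diff(session.frame_times)))
    n_half = int(round(window / dt))
    time = np.arange(-n_half, n_half + 1) * dt
    pop = session.activity[neuron_ids].mean(axis=0)
    traces, lick_times_rel, included, excluded = [], [], [], {}
    for tid in ids:
        frames = np.flatnonzero(session.trial_id == tid)
        if frames.size == 0:
            excluded[int(tid)] = "no frames"
            continue
        if event == "cue":
            cue = trials.trials.loc[tid, "cue_position"]
            reached = frames[session.position[frames] >= cue]
            if not np.isfinite(cue) or reached.size == 0:
                excluded[int(tid)] = "cue not reached"
                continue
            t0 = session.frame_times[reached[0]]
        elif event == "first_lick":
            lp = trials.lick_positions(tid)
            if lp.size == 0:
                excluded[int(tid)] = "no licks"
                continue
            if lp[0] <= 2.0:
                excluded[int(tid)] = "first lick before 2 m"
                continue
            sel = trials.licks["trial_index"] == tid
            t0 = float(trials.licks.loc[sel, "time"].min())
        else:
            raise ValueError("event must be 'cue' or 'first_lick'")
        centre = int(round((t0 - session.frame_times[0]) / dt))
        row = np.full(time.size, np.nan)
        src_lo = max(0, centre - n_half)
        src_hi = min(session.n_timepoints, centre + n_half + 1)
        row[src_lo - (centre - n_half):src_hi - (centre - n_half)] = \
            pop[src_lo:src_hi]
        traces.append(row)
        included.append(int(tid))
        sel = trials.licks["trial_index"] == tid
        lick_times_rel.append(trials.licks.loc[sel, "time"].to_numpy() - t0)
    if not traces:
        raise ValueError(f"no qualifying trials for event {event!r}")
    activity = nanmean(np.stack(traces), axis=0)
    # lick rate on the same axis: histogram in lick_bin bins, box smoothing
    edges = np.arange(time[0] - lick_bin / 2, time[-1] + lick_bin, lick_bin)
    counts = np.histogram(np.concatenate(lick_times_rel), bins=edges)[0]
    rate = counts / (len(traces) * lick_bin)
    width = max(1, int(round(lick_smooth / lick_bin)))
    kernel = np.ones(width) / width
    rate = np.convolve(rate, kernel, mode="same")
    centres = 0.5 * (edges[:-1] + edges[1:])
    rate = np.interp(time, centres, rate)
    return EventAlignedTrace(time, activity, rate, np.asarray(included), excluded)
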