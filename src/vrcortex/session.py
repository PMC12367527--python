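"""Session data model, container I/O, running mask and position interpolation.

A session is one imaging recording of a head-fixed mouse running through
virtual-reality corridors.  Each corridor trial spans positions [0, 6) m:
the first 4 m carry the visual texture, the last 2 m are blank grey.
Activity traces are non-negative deconvolved event amplitudes, one row per
neuron, sampled at the imaging frame times.  All downstream analyses build
on two primitives defined here: the running mask (timepoints where the
mouse runs faster than a speed threshold for a sustained minimum duration)
and per-trial linear interpolation of activity onto a regular position grid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

CORRIDOR_LENGTH = 6.0
TEXTURE_END = 4.0  # texture occupies [0, 4) m, grey [4, 6) m

GROUPS = ("task", "unsupervised", "unsupervised_gratings", "naive")
PHASES = ("before", "after", "test1", "test2", "test3")


class FormatError(ValueError):
    """Raised when a session container is missing a mandatory field."""


@dataclass
class SessionRecording:
    """One recording: traces, frame-wise behaviour, and tissue coordinates.

    Parameters
    ----------
    activity : (n_neurons, n_timepoints) array
        Non-negative deconvolved event amplitudes (a.u.).
    frame_times : (n_timepoints,) array
        Frame times in seconds, strictly increasing.
    position : (n_timepoints,) array
        Position in metres within the current trial frame; NaN between trials.
    trial_id : (n_timepoints,) int array
        Trial index per timepoint, -1 between trials.
    speed : (n_timepoints,) array
        Running speed in cm/s.
    tissue_xy : (n_neurons, 2) array
        Tissue coordinates of each neuron in micrometres.
    group, phase : str
        Experimental cohort and session phase labels.
    """

    activity: np.ndarray
    frame_times: np.ndarray
    position: np.ndarray
    trial_id: np.ndarray
    speed: np.ndarray
    tissue_xy: np.ndarray
    group: str = "task"
    phase: str = "after"

    def __post_init__(self) -> None:
        self.activity = np.asarray(self.activity)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.position = np.asarray(self.position, dtype=float)
        self.trial_id = np.asarray(self.trial_id, dtype=np.int64)
        self.speed = np.asarray(self.speed, dtype=float)
        self.tissue_xy = np.asarray(self.tissue_xy, dtype=float)
        self.validate()

    @property
    def n_neurons(self) -> int:
        return self.activity.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.activity.shape[1]

    def validate(self) -> None:
        t = self.activity.shape[1]
        for name in ("frame_times", "position", "trial_id", "speed"):
            arr = getattr(self, name)
            if arr.shape != (t,):
                raise ValueError(f"{name} has shape {arr.shape}, expected ({t},)")
        if self.tissue_xy.shape != (self.activity.shape[0], 2):
            raise ValueError("tissue_xy must be (n_neurons, 2)")
        if np.nanmin(self.activity) < 0:
            raise ValueError("activity must be non-negative")
        if np.any(np.diff(self.frame_times) <= 0):
            raise ValueError("frame_times must be strictly increasing")
        in_trial = self.trial_id >= 0
        pos = self.position[in_trial]
        if pos.size and (np.nanmin(pos) < 0 or np.nanmax(pos) >= CORRIDOR_LENGTH):
            raise ValueError("in-trial positions must lie in [0, 6) m")
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.phase not in PHASES:
            raise ValueError(f"unknown phase {self.phase!r}")


@dataclass
class TrialTable:
    """Per-trial stimulus labels, cue/reward positions and lick events.

    ``trials`` is indexed by trial_index with columns
    ``stimulus, cue_position, reward_position, rewarded``; ``licks`` has
    columns ``time, position, trial_index`` and is ordered by time.
    """

    trials: pd.DataFrame
    licks: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        {"time": [], "position": [], "trial_index": []}))

    def __post_init__(self) -> None:
        required = {"stimulus", "cue_position", "reward_position", "rewarded"}
        missing = required - set(self.trials.columns)
        if missing:
            raise FormatError(f"trial table missing columns: {sorted(missing)}")
        cue = self.trials["cue_position"].to_numpy(dtype=float)
        ok = np.isnan(cue) | ((cue >= 0.5) & (cue <= 3.5))
        if not ok.all():
            raise ValueError("cue positions must lie in [0.5, 3.5] m when present")
        lp = self.licks["position"].to_numpy(dtype=float)
        if lp.size and (np.nanmin(lp) < 0 or np.nanmax(lp) >= CORRIDOR_LENGTH):
            raise ValueError("lick positions must lie in [0, 6) m")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def trial_ids(self, stimulus: str) -> np.ndarray:
        """Trial indices (sorted) of all trials of one stimulus."""
        sel = self.trials.index[self.trials["stimulus"] == stimulus]
        return np.sort(sel.to_numpy())

    def lick_positions(self, trial_index: int) -> np.ndarray:
        sel = self.licks["trial_index"] == trial_index
        return self.licks.loc[sel, "position"].to_numpy(dtype=float)

    def to_tsv(self, path) -> None:
        self.trials.to_csv(path, sep="\t", index_label="trial_index",
                           float_format="%.9g")


@dataclass
class RunningMask:
    """Boolean running mask: speed above threshold sustained for a minimum time."""

    mask: np.ndarray
    speed_threshold: float
    min_duration: float  # ms


def compute_running_mask(speed, frame_times, threshold: float = 6.0,
                         min_duration: float = 66.0) -> RunningMask:
    """Mark timepoints inside sustained running bouts.

    A timepoint is running if it belongs to a maximal run of consecutive
    frames with ``speed > threshold`` whose duration, measured as the
    frame-time difference between the run's last and first frame, is at
    least ``min_duration`` milliseconds.  Measuring duration in seconds
    (rather than frames) makes the rule sampling-rate independent.
    """
    speed = np.asarray(speed, dtype=float)
    frame_times = np.asarray(frame_times, dtype=float)
    if speed.shape != frame_times.shape:
        raise ValueError("speed and frame_times must have the same length")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    above = speed > threshold
    mask = np.zeros_like(above)
    if not above.any():
        return RunningMask(mask, threshold, min_duration)
    # run-length encode the `above` indicator
    edges = np.flatnonzero(np.diff(above.astype(np.int8)))
    starts = np.r_[0, edges + 1]
    ends = np.r_[edges, above.size - 1]
    for s, e in zip(starts, ends):
        if above[s] and (frame_times[e] - frame_times[s]) * 1000.0 >= min_duration:
            mask[s:e + 1] = True
    return RunningMask(mask, threshold, min_duration)


@dataclass
class TuningMatrix:
    """Trials x position-bins x neurons interpolated activity for one stimulus.

    ``values`` has shape (n_trials, n_bins, n_neurons); bins with no
    activity samples (positions the mouse never reached while running) are
    NaN and excluded from downstream averages.
    """

    values: np.ndarray
    bin_edges: np.ndarray
    stimulus: str
    bin_step: float
    trial_indices: np.ndarray

    @property
    def bin_centres(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def trial_average(self) -> np.ndarray:
        """(n_bins, n_neurons) mean tuning curve, ignoring NaN bins."""
        from ._util import nanmean
        return nanmean(self.values, axis=0)

    def subset(self, trial_indices) -> "TuningMatrix":
        trial_indices = np.asarray(trial_indices)
        rows = np.flatnonzero(np.isin(self.trial_indices, trial_indices))
        return TuningMatrix(self.values[rows], self.bin_edges, self.stimulus,
                            self.bin_step, self.trial_indices[rows])


def position_bins(bin_step: float = 0.1) -> np.ndarray:
    """Bin edges spanning the corridor [0, 6) m at the given step."""
    n = round(CORRIDOR_LENGTH / bin_step)
    if abs(n * bin_step - CORRIDOR_LENGTH) > 1e-9:
        raise ValueError("bin_step must divide the 6 m corridor evenly")
    return np.linspace(0.0, CORRIDOR_LENGTH, n + 1)


def _interp_weights(x: np.ndarray, grid: np.ndarray):
    """Sparse piecewise-linear interpolation weights from samples x to grid.

    Returns (idx_left, idx_right, w_right, valid) so that
    ``y_grid = y[idx_left]*(1-w) + y[idx_right]*w`` where valid, NaN elsewhere.
    Assumes x sorted and strictly increasing.
    """
    valid = (grid >= x[0]) & (grid <= x[-1])
    j = np.searchsorted(x, grid, side="right") - 1
    j = np.clip(j, 0, x.size - 2)
    x0 = x[j]
    x1 = x[j + 1]
    denom = np.where(x1 > x0, x1 - x0, 1.0)
    w = np.clip((grid - x0) / denom, 0.0, 1.0)
    return j, j + 1, w, valid


def build_tuning_matrix(session: SessionRecording, trials: TrialTable,
                        stimulus: str, bin_step: float = 0.1,
                        mask: RunningMask | None = None,
                        trial_subset=None) -> TuningMatrix:
    """Interpolate per-trial activity onto a regular position grid.

    For each trial of ``stimulus``, the (position, activity) samples from
    running timepoints are linearly interpolated onto bin centres spanning
    [0, 6) m.  Frames sharing an identical position (the mouse standing
    still) are averaged before interpolation.  Bins outside the sampled
    position range are NaN.
    """
    edges = position_bins(bin_step)
    centres = 0.5 * (edges[:-1] + edges[1:])
    ids = trials.trial_ids(stimulus)
    if trial_subset is not None:
        trial_subset = np.asarray(trial_subset)
        ids = ids[np.isin(ids, trial_subset)]
    if ids.size == 0:
        raise ValueError(f"no trials of stimulus {stimulus!r}")
    keep = mask.mask if mask is not None else np.ones(session.n_timepoints, bool)
    n_neurons = session.n_neurons
    values = np.full((ids.size, centres.size, n_neurons), np.nan, dtype=np.float32)
    for row, tid in enumerate(ids):
        sel = (session.trial_id == tid) & keep & np.isfinite(session.position)
        if sel.sum() < 2:
            continue
        pos = session.position[sel]
        act = session.activity[:, sel]
        order = np.argsort(pos, kind="stable")
        pos = pos[order]
        act = act[:, order]
        # collapse duplicate positions by averaging
        uniq, inv = np.unique(pos, return_inverse=True)
        if uniq.size != pos.size:
            summed = np.zeros((uniq.size, n_neurons), dtype=np.float64)
            np.add.at(summed, inv, act.T)
            counts = np.bincount(inv, minlength=uniq.size)[:, None]
            act = (summed / counts).T
            pos = uniq
        if pos.size < 2:
            continue
        jl, jr, w, ok = _interp_weights(pos, centres)
        interp = act[:, jl] * (1.0 - w) + act[:, jr] * w
        interp[:, ~ok] = np.nan
        values[row] = interp.T
    return TuningMatrix(values, edges, stimulus, bin_step, ids)


# ---------------------------------------------------------------------------
# container I/O


def write_session(session: SessionRecording, trials: TrialTable, path) -> None:
    """Write a session and its trial table to the single-file HDF5 container."""
    with h5py.File(path, "w") as f:
        f.create_dataset("activity", data=session.activity)
        g = f.create_group("frames")
        g.create_dataset("times", data=session.frame_times)
        g.create_dataset("position", data=session.position)
        g.create_dataset("trial_id", data=session.trial_id)
        g.create_dataset("speed", data=session.speed)
        t = f.create_group("trials")
        tt = trials.trials
        t.create_dataset("trial_index", data=tt.index.to_numpy(dtype=np.int64))
        t.create_dataset(
            "stimulus",
            data=np.array([s.encode() for s in tt["stimulus"]]))
        t.create_dataset("cue_position", data=tt["cue_position"].to_numpy(float))
        t.create_dataset("reward_position",
                         data=tt["reward_position"].to_numpy(float))
        t.create_dataset("rewarded", data=tt["rewarded"].to_numpy(bool))
        lk = f.create_group("licks")
        lk.create_dataset("times", data=trials.licks["time"].to_numpy(float))
        lk.create_dataset("positions", data=trials.licks["position"].to_numpy(float))
        lk.create_dataset("trial_index",
                          data=trials.licks["trial_index"].to_numpy(np.int64))
        nr = f.create_group("neurons")
        nr.create_dataset("tissue_xy", data=session.tissue_xy)
        meta = f.create_group("meta")
        meta.attrs["group"] = session.group
        meta.attrs["phase"] = session.phase
        meta.attrs["json"] = json.dumps({"format_version": 1}, sort_keys=True)


def read_session(path) -> tuple[SessionRecording, TrialTable]:
    """Read a session container written by :func:`write_session`."""
    with h5py.File(path, "r") as f:
        for key in ("activity", "frames", "trials", "neurons", "meta"):
            if key not in f:
                raise FormatError(f"container missing mandatory group {key!r}")
        tg = f["trials"]
        if "stimulus" not in tg:
            raise FormatError("container missing mandatory field 'trials/stimulus'")
        session = SessionRecording(
            activity=f["activity"][()],
            frame_times=f["frames/times"][()],
            position=f["frames/position"][()],
            trial_id=f["frames/trial_id"][()],
            speed=f["frames/speed"][()],
            tissue_xy=f["neurons/tissue_xy"][()],
            group=f["meta"].attrs["group"],
            phase=f["meta"].attrs["phase"],
        )
        trials_df = pd.DataFrame(
            {
                "stimulus": [s.decode() for s in tg["stimulus"][()]],
                "cue_position": tg["cue_position"][()],
                "reward_position": tg["reward_position"][()],
                "rewarded": tg["rewarded"][()].astype(bool),
            },
            index=pd.Index(tg["trial_index"][()], name="trial_index"),
        )
        licks_df = pd.DataFrame(
            {
                "time": f["licks/times"][()],
                "position": f["licks/positions"][()],
                "trial_index": f["licks/trial_index"][()].astype(np.int64),
            }
        )
    return session, TrialTable(trials_df, licks_df)
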