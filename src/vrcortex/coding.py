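"""Coding-direction projections and the similarity index.

Activity is normalized per neuron by subtracting the grey-zone baseline
and dividing by the average of the two reference-corridor standard
deviations.  The coding axis is the pair of top-5% selective populations
(by train-trial d'), and the per-trial projection is the difference of the
two populations' mean normalized activity — equivalent to a weight vector
with entries 1/N_A, -1/N_B and 0.  Averaging projections over the texture
zone gives one scalar per stimulus, from which the similarity index

    dy = a_ref_pos - a_probe,  dx = a_probe - a_ref_neg,
    SI = (dx - dy) / (dx + dy)

locates a probe stimulus between the two reference stimuli (+1 at the
positive reference, -1 at the negative one, 0 at the midpoint).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._util import nanmean, nanstd
from .session import (RunningMask, SessionRecording, TEXTURE_END, TrialTable,
                      TuningMatrix)


@dataclass
class NormalizedActivity:
    """Bin-wise normalized tuning matrices with the per-neuron scalers."""

    values: dict  # stimulus -> (n_trials, n_bins, n_neurons)
    mu_grey: np.ndarray
    sigma_ref: dict  # reference stimulus -> per-neuron s.d.
    valid: np.ndarray  # neurons with a nonzero denominator
    bin_centres: np.ndarray
    trial_indices: dict


def grey_baseline(session: SessionRecording, trials: TrialTable,
                  reference_pair, mask: RunningMask | None = None) -> np.ndarray:
    """Per-neuron mean activity in the grey zone [4, 6) m of reference trials."""
    keep = mask.mask if mask is not None else np.ones(session.n_timepoints, bool)
    keep = keep & np.isfinite(session.position) & (session.position >= TEXTURE_END)
    ids = np.r_[trials.trial_ids(reference_pair[0]),
                trials.trial_ids(reference_pair[1])]
    keep &= np.isin(session.trial_id, ids)
    if keep.sum() == 0:
        raise ValueError("no grey-zone running samples in the reference corridors")
    return session.activity[:, keep].astype(np.float64).mean(axis=1)


def normalize_activity(tunings: dict, mu_grey: np.ndarray,
                       reference_pair) -> NormalizedActivity:
    """Normalize every tuning matrix by the grey baseline and reference s.d.

    r_norm = (r - mu_grey) / ((sigma_ref1 + sigma_ref2) / 2) bin-wise.
    Neurons whose denominator is zero are flagged invalid (NaN) and are
    excluded from axes and projections.
    """
    sigma = {}
    for stim in reference_pair:
        tm: TuningMatrix = tunings[stim]
        flat = tm.values.reshape(-1, tm.values.shape[2])
        sigma[stim] = nanstd(flat, axis=0)
    denom = 0.5 * (sigma[reference_pair[0]] + sigma[reference_pair[1]])
    valid = np.isfinite(denom) & (denom > 0)
    safe = np.where(valid, denom, 1.0)
    values = {}
    trial_indices = {}
    for stim, tm in tunings.items():
        v = (tm.values - mu_grey[None, None, :]) / safe[None, None, :]
        v[:, :, ~valid] = np.nan
        values[stim] = v
        trial_indices[stim] = tm.trial_indices
    any_tm = next(iter(tunings.values()))
    return NormalizedActivity(values, mu_grey, sigma, valid,
                              any_tm.bin_centres, trial_indices)


@dataclass
class CodingAxis:
    """Top-percentile selective populations defining the readout axis."""

    positive: np.ndarray  # neuron ids, most selective toward the positive stimulus
    negative: np.ndarray
    pair: tuple[str, str]
    percentile: float

    def weights(self, n_neurons: int) -> np.ndarray:
        """Equivalent projection weights 1/N_pos, -1/N_neg and 0."""
        w = np.zeros(n_neurons)
        w[self.positive] = 1.0 / self.positive.size
        w[self.negative] = -1.0 / self.negative.size
        return w


def fit_coding_axis(dprime_train, percentile: float = 5.0,
                    pair: tuple[str, str] = ("A", "B"),
                    pool=None, valid=None) -> CodingAxis:
    """Select the top-percentile populations toward each reference stimulus.

    Ranks by train-trial d' (descending for the positive set, ascending
    for the negative set); ties break by neuron index, and the two sets
    are kept disjoint.  ``pool`` restricts the candidate neurons (e.g. to
    one cortical region); ``valid`` removes neurons with degenerate
    normalization.
    """
    d = np.asarray(dprime_train, dtype=float)
    candidates = np.arange(d.size) if pool is None else np.asarray(pool)
    if valid is not None:
        candidates = candidates[np.asarray(valid)[candidates]]
    candidates = candidates[np.isfinite(d[candidates])]
    if candidates.size < 40:
        raise ValueError("selection pool too small (need >= 40 neurons)")
    n_top = math.ceil(percentile / 100.0 * candidates.size)
    order_pos = candidates[np.lexsort((candidates, -d[candidates]))]
    positive = order_pos[:n_top]
    remaining = order_pos[n_top:]
    order_neg = remaining[np.lexsort((remaining, d[remaining]))]
    negative = order_neg[:n_top]
    return CodingAxis(np.sort(positive), np.sort(negative), pair, percentile)


@dataclass
class ProjectionResult:
    """Per-trial coding-direction projections and their texture-zone averages."""

    per_trial: dict  # stimulus -> (n_trials, n_bins) projection traces
    trial_average: dict  # stimulus -> (n_bins,)
    a_proj_trials: dict  # stimulus -> (n_trials,) texture-zone means
    a_proj: dict = field(init=False)  # stimulus -> scalar
    bin_centres: np.ndarray = None

    def __post_init__(self) -> None:
        self.a_proj = {s: float(nanmean(v))
                       for s, v in self.a_proj_trials.items()}


def project_trials(norm: NormalizedActivity, axis: CodingAxis,
                   stimuli=None, exclude_trials: dict | None = None
                   ) -> ProjectionResult:
    """Project trials onto the coding direction.

    Per trial and position bin, the projection is the difference between
    the mean normalized activity of the positive and negative axis
    populations.  ``exclude_trials`` (stimulus -> trial ids) removes the
    axis-fitting trials, so projections are cross-validated.
    """
    if stimuli is None:
        stimuli = list(norm.values)
    tex = norm.bin_centres < TEXTURE_END
    per_trial, trial_avg, a_trials = {}, {}, {}
    for stim in stimuli:
        v = norm.values[stim]
        ids = norm.trial_indices[stim]
        if exclude_trials and stim in exclude_trials:
            keep = ~np.isin(ids, np.asarray(exclude_trials[stim]))
            v = v[keep]
        if v.shape[0] == 0:
            continue
        proj = (nanmean(v[:, :, axis.positive], axis=2)
                - nanmean(v[:, :, axis.negative], axis=2))
        per_trial[stim] = proj
        trial_avg[stim] = nanmean(proj, axis=0)
        a_trials[stim] = nanmean(proj[:, tex], axis=1)
    return ProjectionResult(per_trial, trial_avg, a_trials,
                            bin_centres=norm.bin_centres)


@dataclass
class SimilarityResult:
    dx: float
    dy: float
    si: float
    probe: str
    reference_pair: tuple[str, str]
    out_of_range: bool


def similarity_index(a_proj: dict, reference_pair: tuple[str, str],
                     probe: str) -> SimilarityResult:
    """Locate the probe's projection between the two reference projections.

    The raw SI is reported without clipping; values outside [-1, 1]
    (probe projecting outside the reference interval) carry an
    out_of_range flag.
    """
    a_pos = a_proj[reference_pair[0]]
    a_neg = a_proj[reference_pair[1]]
    a_p = a_proj[probe]
    dy = a_pos - a_p
    dx = a_p - a_neg
    if dx + dy == 0:
        raise ValueError("degenerate axis: reference projections coincide")
    si = (dx - dy) / (dx + dy)
    return SimilarityResult(dx, dy, float(si), probe, reference_pair,
                            not -1.0 <= si <= 1.0)
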