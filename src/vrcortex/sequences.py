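"""Spatial-vs-visual coding tests via preferred-position correlations.

Half of the reference-corridor trials (train) select neurons by |d'|; the
held-out half is split into odd and even trials to build independent
tuning-curve estimates.  Each selected neuron's preferred position is the
corridor position of its maximal trial-averaged response, restricted to
the texture zone.  Correlating preferred positions between corridors (or
between odd and even trials of one corridor) distinguishes a spatial code
(shared sequences, high r) from a visual code (independent sequences,
r indistinguishable from a permutation null).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .selectivity import SelectivityResult
from .session import TEXTURE_END, TrialTable, TuningMatrix


@dataclass
class TrialSplit:
    """Seeded half-split into train/test, with test split odd/even.

    For stimuli not used in neuron selection, all trials go to the
    odd/even split ("train" is empty for them).
    """

    train: dict
    test_odd: dict
    test_even: dict
    seed: int

    def test(self, stimulus: str) -> np.ndarray:
        return np.sort(np.r_[self.test_odd[stimulus], self.test_even[stimulus]])


def split_trials(trials: TrialTable, selection_stimuli, seed: int = 0,
                 all_stimuli=None) -> TrialSplit:
    """Random half-split per selection stimulus; odd/even for everything else.

    Odd/even assignment alternates over trials ordered by presentation,
    so the two halves interleave in time.
    """
    rng = np.random.default_rng(seed)
    if all_stimuli is None:
        all_stimuli = list(dict.fromkeys(trials.trials["stimulus"]))
    train, odd, even = {}, {}, {}
    for stim in all_stimuli:
        ids = trials.trial_ids(stim)
        if stim in selection_stimuli:
            if ids.size < 4:
                raise ValueError(f"need >=4 trials of {stim!r} to split")
            perm = rng.permutation(ids)
            half = ids.size // 2
            train[stim] = np.sort(perm[:half])
            rest = np.sort(perm[half:])
        else:
            train[stim] = np.array([], dtype=ids.dtype)
            rest = ids
        odd[stim] = rest[1::2]
        even[stim] = rest[0::2]
    return TrialSplit(train, odd, even, seed)


@dataclass
class PreferredPositionSet:
    """Preferred positions (metres) of selected neurons for one tuning matrix."""

    neuron_ids: np.ndarray
    positions: np.ndarray
    stimulus: str
    split: str


def preferred_positions(tuning: TuningMatrix, selection: SelectivityResult,
                        split: str = "", texture_only: bool = True
                        ) -> PreferredPositionSet:
    """Argmax of the trial-averaged tuning curve per selected neuron.

    Ties break toward the smallest position; neurons whose curve is all
    NaN (never sampled) are excluded.
    """
    neurons = selection.selected
    curves = tuning.trial_average()[:, neurons]  # (n_bins, n_sel)
    centres = tuning.bin_centres
    if texture_only:
        keep = centres < TEXTURE_END
        curves = curves[keep]
        centres = centres[keep]
    valid = ~np.all(np.isnan(curves), axis=0)
    curves = np.where(np.isnan(curves), -np.inf, curves)
    best = np.argmax(curves, axis=0)
    return PreferredPositionSet(neurons[valid], centres[best[valid]],
                                tuning.stimulus, split)


@dataclass
class SequenceCorrelation:
    r: float
    pair: tuple[str, str]
    split: str
    n_neurons: int


def sequence_correlation(set_a: PreferredPositionSet,
                         set_b: PreferredPositionSet,
                         method: str = "pearson") -> SequenceCorrelation:
    """Correlation of paired preferred positions across two corridors/splits."""
    common, ia, ib = np.intersect1d(set_a.neuron_ids, set_b.neuron_ids,
                                    return_indices=True)
    if common.size < 3:
        raise ValueError("need at least 3 paired neurons")
    x = set_a.positions[ia]
    y = set_b.positions[ib]
    pair = (set_a.stimulus, set_b.stimulus)
    split = f"{set_a.split}|{set_b.split}"
    if x.std() == 0 or y.std() == 0:
        return SequenceCorrelation(float("nan"), pair, split, common.size)
    if method == "pearson":
        r = stats.pearsonr(x, y).statistic
    elif method == "spearman":
        r = stats.spearmanr(x, y).statistic
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    return SequenceCorrelation(float(r), pair, split, common.size)


def permutation_null(set_a: PreferredPositionSet, set_b: PreferredPositionSet,
                     n_shuffles: int = 1000, seed: int = 0,
                     method: str = "pearson") -> np.ndarray:
    """Null distribution of r from shuffling the neuron pairing."""
    common, ia, ib = np.intersect1d(set_a.neuron_ids, set_b.neuron_ids,
                                    return_indices=True)
    x = set_a.positions[ia]
    y = set_b.positions[ib].copy()
    rng = np.random.default_rng(seed)
    out = np.empty(n_shuffles)
    for i in range(n_shuffles):
        perm = rng.permutation(y.size)
        out[i] = np.corrcoef(x, y[perm])[0, 1]
    return out
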