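"""Behavioural readouts: anticipatory licks, discrimination, first-lick maps.

The behavioural discrimination readout is the anticipatory lick response:
a trial counts as a response if the mouse licked at least once inside the
corridor but before the sound cue (or, in the cue-less behaviour-only
task, before the reward-zone onset drawn per trial from [2, 3] m).  Licks
after the cue never affect the flag, which rules out responses triggered
by reward delivery itself.  Discrimination performance is the response-
rate difference between the rewarded and non-rewarded corridor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def anticipatory_lick_response(lick_positions, cue_position: float) -> bool:
    """True iff any lick falls inside the corridor before the cue."""
    lp = np.asarray(lick_positions, dtype=float)
    if lp.size == 0:
        return False
    return bool(np.any((lp > 0.0) & (lp < cue_position)))


@dataclass
class LickMetrics:
    """Per-stimulus anticipatory response rates for one set of trials."""

    response_rate: dict  # stimulus -> fraction of trials with a response
    n_trials: dict


def lick_metrics(table: pd.DataFrame, boundary_column: str = "boundary",
                 licks_column: str = "lick_positions",
                 stimulus_column: str = "stimulus") -> LickMetrics:
    """Response rates per stimulus from a per-trial lick table."""
    rates, counts = {}, {}
    for stim, grp in table.groupby(stimulus_column, sort=True):
        flags = [anticipatory_lick_response(r[licks_column], r[boundary_column])
                 for _, r in grp.iterrows()]
        rates[stim] = float(np.mean(flags))
        counts[stim] = len(flags)
    return LickMetrics(rates, counts)


def performance_difference(metrics: LickMetrics, rewarded: str = "rewarded",
                           unrewarded: str = "unrewarded") -> float:
    """Response rate of the rewarded minus the non-rewarded stimulus."""
    for stim in (rewarded, unrewarded):
        if stim not in metrics.response_rate:
            raise ValueError(f"missing stimulus {stim!r}")
    return metrics.response_rate[rewarded] - metrics.response_rate[unrewarded]


@dataclass
class FirstLickDistribution:
    """Histogram of first-lick positions, normalized over trials with licks."""

    histogram: np.ndarray
    bin_edges: np.ndarray
    n_licked: int
    n_no_lick: int


def first_lick_distribution(first_lick_positions,
                            bin_step: float = 0.1) -> FirstLickDistribution:
    """Distribution of first-lick positions over the corridor [0, 6) m.

    Trials without licks are counted separately and do not enter the
    (sum-to-one) histogram.
    """
    fl = np.asarray(first_lick_positions, dtype=float)
    licked = fl[np.isfinite(fl)]
    edges = np.arange(0.0, 6.0 + bin_step, bin_step)
    hist = np.histogram(licked, bins=edges)[0].astype(float)
    if licked.size:
        hist /= licked.size
    return FirstLickDistribution(hist, edges, int(licked.size),
                                 int(fl.size - licked.size))


def daily_performance(table: pd.DataFrame) -> pd.DataFrame:
    """Per-cohort, per-mouse, per-day lick-response difference."""
    rows = []
    for (cohort, mouse, day), grp in table.groupby(["cohort", "mouse", "day"],
                                                   sort=True):
        diff = performance_difference(lick_metrics(grp))
        rows.append({"cohort": cohort, "mouse": mouse, "day": day,
                     "difference": diff})
    return pd.DataFrame(rows)
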