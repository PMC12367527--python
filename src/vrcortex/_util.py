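"""Small numeric helpers shared across modules."""

from __future__ import annotations

import warnings

import numpy as np


def nanmean(a, axis=None):
    """np.nanmean without the all-NaN-slice warning (all-NaN stays NaN)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        return np.nanmean(a, axis=axis)


def nanstd(a, axis=None):
    """np.nanstd without the all-NaN-slice warning."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        return np.nanstd(a, axis=axis)
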