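"""Selectivity index d', neuron selection, cortical density maps, region fractions.

The selectivity index of a neuron between two corridors is the standardized
mean difference of its activity samples,

    d' = (mu1 - mu2) / ((sigma1 + sigma2) / 2),

computed from raw (uninterpolated) deconvolved trace samples restricted to
the texture zone [0, 4) m and to running timepoints.  Neurons with
|d'| >= 0.3 are called selective.  Density maps are smoothed 2-D histograms
of selective-neuron tissue positions divided by the total neuron count,
with uncovered bins set to NaN before cross-session averaging.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .session import RunningMask, SessionRecording, TEXTURE_END, TrialTable

SELECTIVITY_THRESHOLD = 0.3


def compute_dprime(samples_a, samples_b) -> float:
    """Standardized mean difference between two condition sample sets.

    Uses population standard deviations (ddof=0).  When both conditions
    have zero variance the result is 0 for equal means and signed infinity
    otherwise; infinite values are excluded from selection downstream so a
    silent neuron can never enter a selected set.
    """
    a = np.asarray(samples_a, dtype=float)
    b = np.asarray(samples_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both conditions must be non-empty")
    mu1, mu2 = a.mean(), b.mean()
    denom = 0.5 * (a.std() + b.std())
    if denom == 0.0:
        return 0.0 if mu1 == mu2 else np.sign(mu1 - mu2) * np.inf
    return (mu1 - mu2) / denom


def dprime_from_stats(mu1, sigma1, mu2, sigma2):
    """d' from precomputed condition means and standard deviations."""
    mu1, sigma1 = np.asarray(mu1, float), np.asarray(sigma1, float)
    mu2, sigma2 = np.asarray(mu2, float), np.asarray(sigma2, float)
    denom = 0.5 * (sigma1 + sigma2)
    diff = mu1 - mu2
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom > 0, diff / np.where(denom > 0, denom, 1.0),
                       np.where(diff == 0, 0.0, np.sign(diff) * np.inf))
    return out


def session_dprime(session: SessionRecording, trials: TrialTable,
                   stimulus_a: str, stimulus_b: str,
                   mask: RunningMask | None = None,
                   trial_subset_a=None, trial_subset_b=None) -> np.ndarray:
    """Per-neuron d' between two corridors from raw running-timepoint samples.

    Samples are restricted to the texture zone [0, 4) m; the original
    deconvolved traces are used without interpolation.
    """
    keep = mask.mask if mask is not None else np.ones(session.n_timepoints, bool)
    keep = keep & np.isfinite(session.position) & (session.position < TEXTURE_END)

    def cond(stim, subset):
        ids = trials.trial_ids(stim)
        if subset is not None:
            ids = ids[np.isin(ids, np.asarray(subset))]
        if ids.size == 0:
            raise ValueError(f"no trials of stimulus {stim!r}")
        return keep & np.isin(session.trial_id, ids)

    sel_a = cond(stimulus_a, trial_subset_a)
    sel_b = cond(stimulus_b, trial_subset_b)
    if sel_a.sum() == 0 or sel_b.sum() == 0:
        raise ValueError("a condition has no running texture-zone samples")
    a = session.activity[:, sel_a].astype(np.float64)
    b = session.activity[:, sel_b].astype(np.float64)
    return dprime_from_stats(a.mean(1), a.std(1), b.mean(1), b.std(1))


@dataclass
class SelectivityResult:
    """Per-neuron d' with the threshold partition into selective sets."""

    dprime: np.ndarray
    pair: tuple[str, str]
    threshold: float
    selected_pos: np.ndarray = field(init=False)
    selected_neg: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        d = np.asarray(self.dprime, dtype=float)
        finite = np.isfinite(d)
        self.selected_pos = np.flatnonzero(finite & (d >= self.threshold))
        self.selected_neg = np.flatnonzero(finite & (d <= -self.threshold))

    @property
    def selected(self) -> np.ndarray:
        return np.sort(np.r_[self.selected_pos, self.selected_neg])


def select_neurons(dprime, threshold: float = SELECTIVITY_THRESHOLD,
                   pair: tuple[str, str] = ("A", "B")) -> SelectivityResult:
    """Partition neurons by the |d'| >= threshold criterion (boundary included)."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return SelectivityResult(np.asarray(dprime, float), pair, threshold)


@dataclass
class DensityMap:
    """Smoothed fraction of selective neurons per tissue bin (NaN = uncovered)."""

    grid: np.ndarray
    x_edges: np.ndarray
    y_edges: np.ndarray
    bin_size: float
    smoothing_sigma: float
    coverage: np.ndarray


def density_map(selected_xy, all_xy, bin_size: float = 100.0,
                smoothing_sigma: float = 200.0,
                extent=None) -> DensityMap:
    """Smoothed 2-D histogram of selective neurons over tissue coordinates.

    The histogram of selected neurons is Gaussian-filtered (sigma in the
    same micrometre units as the coordinates) and divided by the total
    number of recorded neurons.  Bins with no recorded neurons anywhere
    nearby (after the same smoothing of the all-neuron histogram) are NaN
    so that cross-session averages are not diluted by unsampled cortex.
    """
    all_xy = np.asarray(all_xy, dtype=float)
    selected_xy = np.asarray(selected_xy, dtype=float).reshape(-1, 2)
    if all_xy.size == 0:
        raise ValueError("at least one recorded neuron required")
    if not np.isfinite(all_xy).all():
        raise ValueError("tissue coordinates must be finite")
    if extent is None:
        x0, x1 = all_xy[:, 0].min(), all_xy[:, 0].max()
        y0, y1 = all_xy[:, 1].min(), all_xy[:, 1].max()
    else:
        x0, x1, y0, y1 = extent
    x_edges = np.arange(x0, x1 + bin_size, bin_size)
    y_edges = np.arange(y0, y1 + bin_size, bin_size)
    hist_sel, _, _ = np.histogram2d(selected_xy[:, 0], selected_xy[:, 1],
                                    bins=(x_edges, y_edges))
    hist_all, _, _ = np.histogram2d(all_xy[:, 0], all_xy[:, 1],
                                    bins=(x_edges, y_edges))
    sigma_bins = smoothing_sigma / bin_size
    if sigma_bins > 0:
        smooth_sel = gaussian_filter(hist_sel, sigma_bins)
        smooth_all = gaussian_filter(hist_all, sigma_bins)
    else:
        smooth_sel, smooth_all = hist_sel, hist_all
    coverage = smooth_all > 1e-12
    grid = smooth_sel / all_xy.shape[0]
    grid[~coverage] = np.nan
    return DensityMap(grid, x_edges, y_edges, bin_size, smoothing_sigma, coverage)


def average_density_maps(maps: list[DensityMap]) -> np.ndarray:
    """Cross-session average ignoring NaN (uncovered) bins."""
    from ._util import nanmean
    return nanmean(np.stack([m.grid for m in maps]), axis=0)


@dataclass
class RegionAtlas:
    """Named rectangular region masks over tissue coordinates (micrometres).

    A schematic stand-in for a reference widefield atlas: four
    non-overlapping rectangles covering V1 and the medial, lateral and
    anterior higher visual areas.  Real atlases may be supplied as any
    mapping from region name to (x0, x1, y0, y1).
    """

    regions: dict[str, tuple[float, float, float, float]]

    def __post_init__(self) -> None:
        names = list(self.regions)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                xa, xb = self.regions[a], self.regions[b]
                if (xa[0] < xb[1] and xb[0] < xa[1]
                        and xa[2] < xb[3] and xb[2] < xa[3]):
                    raise ValueError(f"regions {a!r} and {b!r} overlap")

    def region_of(self, tissue_xy) -> np.ndarray:
        """Region name per neuron, or '' outside all regions."""
        xy = np.asarray(tissue_xy, dtype=float)
        out = np.full(xy.shape[0], "", dtype=object)
        for name, (x0, x1, y0, y1) in self.regions.items():
            inside = ((xy[:, 0] >= x0) & (xy[:, 0] < x1)
                      & (xy[:, 1] >= y0) & (xy[:, 1] < y1))
            out[inside] = name
        return out.astype(str)


def default_atlas() -> RegionAtlas:
    """Schematic four-region layout (micrometre blocks)."""
    return RegionAtlas({
        "V1": (0.0, 1000.0, 0.0, 1000.0),
        "medial": (0.0, 1000.0, 1000.0, 1800.0),
        "lateral": (1000.0, 1800.0, 0.0, 1000.0),
        "anterior": (1000.0, 1800.0, 1000.0, 1800.0),
    })


def region_fraction(selection: SelectivityResult, atlas: RegionAtlas,
                    tissue_xy) -> dict[str, float]:
    """Percentage of selective neurons per region.

    Returns 100 * (#selected in region) / (#recorded in region); regions
    with no recorded neurons get NaN.  Neurons outside all regions are
    excluded.
    """
    labels = atlas.region_of(tissue_xy)
    sel_mask = np.zeros(labels.size, dtype=bool)
    sel_mask[selection.selected] = True
    out: dict[str, float] = {}
    for name in atlas.regions:
        in_region = labels == name
        n = int(in_region.sum())
        out[name] = float("nan") if n == 0 else 100.0 * sel_mask[in_region].sum() / n
    return out
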