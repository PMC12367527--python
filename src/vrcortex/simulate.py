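"""Synthetic sessions, behaviour cohorts and image responses with ground truth.

The generator emulates the statistical structure the analyses assume, so
every analysis can be exercised as a parameter-recovery problem:

* position-tuned neurons (Gaussian bumps over corridor position) with a
  planted between-corridor selectivity calibrated analytically so the
  population d' of planted neurons equals ``target_dprime`` in expectation;
* a spatial vs visual coding regime switch: in the spatial regime a
  neuron's preferred position is shared across stimulus exemplars, in the
  visual regime it is drawn independently per exemplar while the additive
  category drive (the "leafiness" signal) is shared;
* novelty responses that decay exponentially with stimulus repetitions;
* reward-prediction neurons that ramp with position from corridor entry
  and are suppressed once the sound cue is reached, in the rewarded
  corridor only;
* lick behaviour with a configurable discrimination level and learning
  curve, for single sessions and multi-day cohorts;
* natural-image responses generated exactly by the convolutional encoding
  model ``F_n(img) = a_n * (K o img)(k_n, x_n, y_n)`` from a planted kernel
  bank with a planted retinotopic gradient across tissue.

Deconvolved amplitudes are modelled as rectified Gaussians around the mean
rate, which keeps traces non-negative (like real deconvolved traces) while
allowing closed-form moments for oracle computations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.stats import norm

from .selectivity import default_atlas
from .session import CORRIDOR_LENGTH, SessionRecording, TEXTURE_END, TrialTable

# ---------------------------------------------------------------------------
# rectified-Gaussian moments (analytic oracles for the rate model)


def rectified_gaussian_moments(m, s):
    """Mean and variance of max(0, N(m, s^2)) elementwise."""
    m = np.asarray(m, dtype=float)
    if np.isscalar(s) or np.ndim(s) == 0:
        s = np.full_like(m, float(s))
    s = np.asarray(s, dtype=float)
    out_mean = np.where(m > 0, m, 0.0).astype(float)
    out_var = np.zeros_like(out_mean)
    pos = s > 0
    if np.any(pos):
        z = m[pos] / s[pos]
        phi = norm.pdf(z)
        cdf = norm.cdf(z)
        mean = m[pos] * cdf + s[pos] * phi
        ex2 = (m[pos] ** 2 + s[pos] ** 2) * cdf + m[pos] * s[pos] * phi
        out_mean[pos] = mean
        out_var[pos] = np.maximum(ex2 - mean ** 2, 0.0)
    return out_mean, out_var


def pooled_moments(curve, noise_scale):
    """Moments of activity pooled uniformly over a position grid.

    ``curve`` is the mean rate over the grid (last axis); samples at each
    position are rectified Gaussians with standard deviation
    ``noise_scale``.  Returns the pooled mean and standard deviation of
    the position mixture.
    """
    mean_p, var_p = rectified_gaussian_moments(curve, noise_scale)
    mu = mean_p.mean(axis=-1)
    ex2 = (var_p + mean_p ** 2).mean(axis=-1)
    var = np.maximum(ex2 - mu ** 2, 0.0)
    return mu, np.sqrt(var)


def analytic_pooled_dprime(curve1, curve2, noise_scale):
    """d' of the generating distributions, pooled over positions."""
    mu1, s1 = pooled_moments(curve1, noise_scale)
    mu2, s2 = pooled_moments(curve2, noise_scale)
    denom = 0.5 * (s1 + s2)
    return (mu1 - mu2) / denom


# ---------------------------------------------------------------------------
# configuration and ground truth


def stimulus_drive(name: str) -> tuple[float, float]:
    """Default (leaf, circle) category drive of a stimulus by its label."""
    if name.startswith("leaf"):
        return (1.0, 0.0)
    if name.startswith("circle"):
        return (0.0, 1.0)
    return (0.0, 0.0)


@dataclass
class SimConfig:
    """Generator settings; the defaults define the standard study conditions."""

    n_neurons: int = 1000
    n_trials: int = 200  # per stimulus
    stimuli: tuple = ("leaf1", "circle1")
    stimulus_drives: dict | None = None  # overrides for (leaf, circle) drives
    region_fractions: dict = field(default_factory=lambda: {
        "V1": 0.40, "medial": 0.25, "lateral": 0.20, "anterior": 0.15})
    selective_fraction: dict = field(default_factory=lambda: {
        "V1": 0.05, "medial": 0.20, "lateral": 0.05, "anterior": 0.05})
    target_dprime: float = 0.6
    coding_regime: str = "visual"  # or "spatial"
    novelty_gain: float = 0.0
    adaptation_rate: float = 0.05
    novel_stimuli: tuple = ()
    rp_fraction: float = 0.1  # of anterior neurons
    ramp_gain: float = 1.0
    noise_scale: float = 0.3
    baseline: float = 0.2
    bump_amp_range: tuple = (0.5, 1.5)
    bump_width: float = 0.4  # m
    rewarded_stimulus: str = "leaf1"
    frame_rate: float = 10.0  # Hz
    run_speed: float = 60.0  # cm/s, the fixed virtual-reality speed
    pause_prob: float = 0.1  # probability of a brief stop per trial
    discrimination: float = 0.9
    anticipation_onset: float = 1.0  # m, earliest anticipatory lick
    lick_rate: float = 3.0  # licks per metre while responding
    group: str = "task"
    phase: str = "after"
    seed: int = 0

    def __post_init__(self) -> None:
        for frac in list(self.selective_fraction.values()) + [self.rp_fraction]:
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if abs(sum(self.region_fractions.values()) - 1.0) > 1e-9:
            raise ValueError("region fractions must sum to 1")
        if self.target_dprime < 0:
            raise ValueError("target_dprime must be non-negative")
        if self.n_trials < 4:
            raise ValueError("need at least 4 trials per stimulus")
        if self.coding_regime not in ("spatial", "visual"):
            raise ValueError("coding_regime must be 'spatial' or 'visual'")

    def drives(self, name: str) -> tuple[float, float]:
        if self.stimulus_drives and name in self.stimulus_drives:
            return self.stimulus_drives[name]
        return stimulus_drive(name)


@dataclass
class GroundTruth:
    """Planted per-neuron structure behind a simulated session."""

    region: np.ndarray
    neuron_class: np.ndarray  # selective_pos / selective_neg / reward_prediction / none
    pref_position: dict  # stimulus -> (n_neurons,) metres, NaN for untuned
    delta: np.ndarray  # planted selective drive amplitude
    bump_amp: np.ndarray
    rp_flag: np.ndarray
    true_dprime: np.ndarray  # analytic pooled d' of the generating model
    # retinotopy fields (populated by simulate_image_responses)
    rf_x: np.ndarray | None = None
    rf_y: np.ndarray | None = None
    rf_kernel: np.ndarray | None = None
    rf_amp: np.ndarray | None = None
    tissue_xy: np.ndarray | None = None
    aligned_tissue_xy: np.ndarray | None = None
    planted_affine: tuple | None = None
    gradient: dict | None = None

    def to_frame(self) -> pd.DataFrame:
        data = {"region": self.region, "neuron_class": self.neuron_class,
                "delta": self.delta, "bump_amp": self.bump_amp,
                "rp_flag": self.rp_flag, "true_dprime": self.true_dprime}
        for stim, pos in self.pref_position.items():
            data[f"pref_{stim}"] = pos
        return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# session generator


def _allocate_counts(n: int, fractions: dict) -> dict:
    """Largest-remainder allocation of n items to named fractions."""
    names = list(fractions)
    raw = np.array([fractions[k] * n for k in names])
    counts = np.floor(raw).astype(int)
    rem = n - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    for i in order[:rem]:
        counts[i] += 1
    return dict(zip(names, counts))


def _bump(pos, pref, width):
    """Gaussian position tuning restricted to the texture zone."""
    out = np.exp(-0.5 * ((pos[None, :] - pref[:, None]) / width) ** 2)
    out[:, pos >= TEXTURE_END] = 0.0
    return out


def _calibrate_delta(curve1, curve2, target, noise_scale, hi=None):
    """Per-neuron drive delta so the analytic pooled d' equals target.

    Solves d'(curve1 + delta, curve2) = target by vectorized bisection;
    the analytic d' is monotone increasing in delta.
    """
    n = curve1.shape[0]
    if target == 0:
        return np.zeros(n)
    if hi is None:
        hi = 10.0 * (noise_scale + 1.0) * (1.0 + target)
    lo_v = np.zeros(n)
    hi_v = np.full(n, hi)
    # widen until bracket is valid
    for _ in range(20):
        d_hi = analytic_pooled_dprime(curve1 + hi_v[:, None], curve2, noise_scale)
        bad = d_hi < target
        if not bad.any():
            break
        hi_v[bad] *= 2.0
    for _ in range(60):
        mid = 0.5 * (lo_v + hi_v)
        d_mid = analytic_pooled_dprime(curve1 + mid[:, None], curve2, noise_scale)
        low = d_mid < target
        lo_v = np.where(low, mid, lo_v)
        hi_v = np.where(low, hi_v, mid)
    return 0.5 * (lo_v + hi_v)


def simulate_session(config: SimConfig):
    """Generate one session, its trial table, and the planted ground truth.

    Deterministic for a fixed ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_neurons
    atlas = default_atlas()

    # --- tissue coordinates and classes -----------------------------------
    counts = _allocate_counts(n, config.region_fractions)
    region = np.empty(n, dtype=object)
    tissue = np.empty((n, 2))
    i0 = 0
    for name, cnt in counts.items():
        x0, x1, y0, y1 = atlas.regions[name]
        region[i0:i0 + cnt] = name
        tissue[i0:i0 + cnt, 0] = rng.uniform(x0, x1, cnt)
        tissue[i0:i0 + cnt, 1] = rng.uniform(y0, y1, cnt)
        i0 += cnt
    region = region.astype(str)

    neuron_class = np.full(n, "none", dtype=object)
    for name, cnt in counts.items():
        idx = np.flatnonzero(region == name)
        n_sel = round(config.selective_fraction[name] * cnt)
        chosen = rng.choice(idx, size=n_sel, replace=False)
        half = n_sel // 2
        neuron_class[chosen[:n_sel - half]] = "selective_pos"
        neuron_class[chosen[n_sel - half:]] = "selective_neg"
    ant = np.flatnonzero((region == "anterior") & (neuron_class == "none"))
    n_rp = round(config.rp_fraction * counts.get("anterior", 0))
    n_rp = min(n_rp, ant.size)
    rp_idx = rng.choice(ant, size=n_rp, replace=False) if n_rp else np.array([], int)
    neuron_class[rp_idx] = "reward_prediction"
    neuron_class = neuron_class.astype(str)
    rp_flag = neuron_class == "reward_prediction"
    is_pos = neuron_class == "selective_pos"
    is_neg = neuron_class == "selective_neg"

    # --- tuning parameters -------------------------------------------------
    amp = rng.uniform(*config.bump_amp_range, size=n)
    amp[rp_flag] = 0.0  # reward-prediction neurons carry the ramp only
    pref: dict[str, np.ndarray] = {}
    base_pref = rng.uniform(0.0, TEXTURE_END, size=n)
    for stim in config.stimuli:
        if config.coding_regime == "spatial":
            pref[stim] = base_pref.copy()
        else:
            pref[stim] = rng.uniform(0.0, TEXTURE_END, size=n)
        pref[stim][rp_flag] = np.nan

    # --- calibrate the selective drive -------------------------------------
    grid = np.linspace(0.0, TEXTURE_END, 81)[:-1] + TEXTURE_END / 162.0
    delta = np.zeros(n)
    true_dprime = np.zeros(n)
    sel = is_pos | is_neg
    if sel.any() and config.target_dprime > 0 and len(config.stimuli) >= 2:
        stim_a, stim_b = config.stimuli[0], config.stimuli[1]
        def curves(idx, stim):
            g = np.exp(-0.5 * ((grid[None, :] - pref[stim][idx, None])
                               / config.bump_width) ** 2)
            return config.baseline + amp[idx, None] * g
        for mask_cls, own, other, sign in ((is_pos, stim_a, stim_b, 1.0),
                                           (is_neg, stim_b, stim_a, -1.0)):
            idx = np.flatnonzero(mask_cls)
            if idx.size == 0:
                continue
            d = _calibrate_delta(curves(idx, own), curves(idx, other),
                                 config.target_dprime, config.noise_scale)
            delta[idx] = d
            true_dprime[idx] = sign * config.target_dprime
    # reward-prediction neurons are leaf1-active: their pooled d' is left as
    # computed downstream rather than planted to a target
    # --- trial structure ----------------------------------------------------
    stim_seq = rng.permutation(np.repeat(config.stimuli, config.n_trials))
    n_tr = stim_seq.size
    cue = rng.uniform(0.5, 3.5, size=n_tr)
    rewarded = (stim_seq == config.rewarded_stimulus) & (config.group == "task")
    reward_pos = np.where(rewarded, np.minimum(cue + 0.1, 5.9), np.nan)

    dt = 1.0 / config.frame_rate
    step = config.run_speed / 100.0 * dt  # metres per running frame
    n_run = int(round(CORRIDOR_LENGTH / step))
    n_gap = 3
    n_pause = max(1, int(round(0.6 * config.frame_rate)))

    pos_list, speed_list, tid_list = [], [], []
    trial_frame_pos = []  # (positions, start offset) per trial for lick timing
    for t in range(n_tr):
        p = np.arange(n_run) * step
        s = np.full(n_run, config.run_speed)
        if rng.random() < config.pause_prob:
            at = rng.integers(1, n_run - 1)
            p = np.concatenate([p[:at], np.full(n_pause, p[at]), p[at:]])
            s = np.concatenate([s[:at], np.full(n_pause, 2.0), s[at:]])
        start = sum(len(x) for x in pos_list)
        pos_list.append(p)
        speed_list.append(s)
        tid_list.append(np.full(p.size, t))
        trial_frame_pos.append((p, start))
        pos_list.append(np.full(n_gap, np.nan))
        speed_list.append(np.full(n_gap, config.run_speed))
        tid_list.append(np.full(n_gap, -1))
    position = np.concatenate(pos_list)
    speed = np.concatenate(speed_list)
    trial_id = np.concatenate(tid_list).astype(np.int64)
    n_frames = position.size
    frame_times = np.arange(n_frames) * dt

    # --- mean rates ---------------------------------------------------------
    mean = np.full((n, n_frames), config.baseline, dtype=np.float32)
    seen: dict[str, int] = {}
    for t in range(n_tr):
        stim = stim_seq[t]
        k = seen.get(stim, 0)
        seen[stim] = k + 1
        p, start = trial_frame_pos[t]
        cols = slice(start, start + p.size)
        tex = p < TEXTURE_END
        block = np.zeros((n, p.size), dtype=np.float32)
        tuned = ~rp_flag
        block[tuned] = (amp[tuned, None]
                        * _bump(p, pref[stim][tuned], config.bump_width))
        dl, dc = config.drives(stim)
        drive = delta * (is_pos * dl + is_neg * dc)
        block[:, tex] += drive[:, None].astype(np.float32)
        if stim in config.novel_stimuli and config.novelty_gain > 0:
            nov = config.novelty_gain * math.exp(-config.adaptation_rate * k)
            block[:, tex] += nov
        if stim == config.rewarded_stimulus and rp_flag.any():
            ramp = np.where(p < cue[t], config.ramp_gain * p / TEXTURE_END, 0.0)
            block[rp_flag] += ramp[None, :].astype(np.float32)
        mean[:, cols] += block
    noise = rng.standard_normal((n, n_frames), dtype=np.float32)
    activity = np.maximum(mean + config.noise_scale * noise, 0.0)
    del mean, noise

    # --- licks --------------------------------------------------------------
    lick_rows = []
    for t in range(n_tr):
        stim = stim_seq[t]
        assoc = config.drives(stim)[0] if config.rewarded_stimulus.startswith(
            "leaf") else config.drives(stim)[1]
        p_resp = assoc * 1.0 + (1.0 - assoc) * (1.0 - config.discrimination)
        licks = []
        if rng.random() < p_resp:
            lo = min(config.anticipation_onset, 0.5 * cue[t])
            x = rng.uniform(lo, cue[t])
            while x < cue[t]:
                licks.append(x)
                x += rng.exponential(1.0 / config.lick_rate)
            if rewarded[t]:
                x = reward_pos[t]
                while x < min(reward_pos[t] + 0.5, CORRIDOR_LENGTH - 0.01):
                    licks.append(x)
                    x += rng.exponential(1.0 / config.lick_rate)
        p, start = trial_frame_pos[t]
        for lp in sorted(licks):
            fi = np.searchsorted(p, lp)
            fi = min(fi, p.size - 1)
            lick_rows.append((frame_times[start + fi], lp, t))

    trials_df = pd.DataFrame(
        {"stimulus": stim_seq, "cue_position": cue,
         "reward_position": reward_pos, "rewarded": rewarded},
        index=pd.Index(np.arange(n_tr), name="trial_index"))
    licks_df = pd.DataFrame(lick_rows, columns=["time", "position", "trial_index"])
    session = SessionRecording(activity, frame_times, position, trial_id,
                               speed, tissue, config.group, config.phase)
    gt = GroundTruth(region=region, neuron_class=neuron_class,
                     pref_position=pref, delta=delta, bump_amp=amp,
                     rp_flag=rp_flag, true_dprime=true_dprime,
                     tissue_xy=tissue)
    return session, TrialTable(trials_df, licks_df), gt


# ---------------------------------------------------------------------------
# behaviour cohorts


@dataclass
class LickPolicy:
    """Lick-discrimination learning curve of one cohort.

    The discrimination level on a given day is
    ``level * (1 - exp(-(day - 1 + prior_days) / tau))`` (or ``level``
    exactly when ``tau`` is 0); ``prior_days`` credits pretraining.
    Rewarded-corridor trials always contain anticipatory licks; the
    unrewarded corridor is licked with probability ``1 - discrimination``.
    """

    level: float = 0.9
    prior_days: float = 0.0
    tau: float = 1.5

    def discrimination(self, day: int) -> float:
        if self.tau == 0:
            return self.level
        return self.level * (1.0 - math.exp(-(day - 1 + self.prior_days) / self.tau))


DEFAULT_COHORTS = {
    "pretrained": LickPolicy(0.9, prior_days=2.0),
    "pretrained_gratings": LickPolicy(0.9, prior_days=0.7),
    "no_pretraining": LickPolicy(0.9, prior_days=0.0),
}


def simulate_behavior_cohorts(config: SimConfig, n_mice: int = 5, days: int = 5,
                              policies: dict | None = None,
                              n_trials: int = 50) -> pd.DataFrame:
    """Per-trial lick tables for multi-day training cohorts.

    Emulates the behaviour-only task: no sound cue; the reward-zone onset
    is drawn per trial from a uniform distribution between 2 m and 3 m and
    serves as the anticipation boundary.  Returns one row per trial with
    the boundary, the first-lick position and the full lick-position list.
    """
    if days < 1:
        raise ValueError("days must be >= 1")
    policies = policies if policies is not None else DEFAULT_COHORTS
    rng = np.random.default_rng(config.seed)
    rows = []
    for cohort, policy in policies.items():
        for mouse in range(n_mice):
            for day in range(1, days + 1):
                disc = policy.discrimination(day)
                for trial in range(n_trials):
                    stim = "rewarded" if rng.random() < 0.5 else "unrewarded"
                    boundary = rng.uniform(2.0, 3.0)
                    p_resp = 1.0 if stim == "rewarded" else 1.0 - disc
                    licks = []
                    if rng.random() < p_resp:
                        x = rng.uniform(config.anticipation_onset, boundary)
                        while x < boundary:
                            licks.append(x)
                            x += rng.exponential(1.0 / config.lick_rate)
                        if stim == "rewarded":
                            licks.extend(boundary + 0.1 * np.arange(3))
                    elif rng.random() < 0.3:
                        licks.append(rng.uniform(boundary, CORRIDOR_LENGTH - 0.01))
                    licks = sorted(np.clip(licks, 0, CORRIDOR_LENGTH - 1e-6))
                    rows.append({
                        "cohort": cohort, "mouse": mouse, "day": day,
                        "trial": trial, "stimulus": stim, "boundary": boundary,
                        "first_lick_position": licks[0] if licks else np.nan,
                        "lick_positions": np.asarray(licks),
                    })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# encoding-model image responses


@dataclass
class RetinoSimConfig:
    """Settings for the planted convolutional encoding model."""

    n_kernels: int = 20
    kernel_size: int = 13
    image_shape: tuple = (30, 120)
    n_images: int = 500
    n_repeats: int = 3
    n_neurons: int = 1000
    n_clusters: int = 50
    cluster_scatter: float = 30.0  # μm
    tissue_span: tuple = (1800.0, 900.0)  # μm, mapped to (columns, rows)
    amp_range: tuple = (0.5, 1.5)
    noise_scale: float = 0.0  # noise s.d. relative to signal s.d. per neuron
    planted_affine: tuple | None = None  # (A1 2x2, A2 2-vector)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd")
        m = self.kernel_size // 2
        h, w = self.image_shape
        if h - 2 * m <= 0 or w - 2 * m <= 0:
            raise ValueError("image too small for the kernel size")


def make_kernel_bank(n_kernels: int, size: int, rng) -> np.ndarray:
    """Localized smoothed random filters, unit norm, centred centre of mass.

    A Gaussian spatial envelope keeps each filter's energy away from the
    frame border, like a measured receptive field; smoothing sets the
    filters' spatial scale.
    """
    from .retinotopy import recentre_kernels
    k = rng.standard_normal((n_kernels, size, size))
    for i in range(n_kernels):
        k[i] = gaussian_filter(k[i], 1.2)
    c = (size - 1) / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    envelope = np.exp(-((yy - c) ** 2 + (xx - c) ** 2) / (2 * (size / 4) ** 2))
    k *= envelope
    k -= k.mean(axis=(1, 2), keepdims=True)
    k *= envelope  # keep the zero-mean correction localized too
    k /= np.linalg.norm(k, axis=(1, 2), keepdims=True)
    return recentre_kernels(k)


def simulate_image_responses(config: RetinoSimConfig):
    """Images, encoding-model responses and the planted retinotopic truth.

    Tissue positions are drawn in columnar clusters; all neurons of a
    cluster share a planted map position given by a linear retinotopic
    gradient evaluated at the cluster centre.  This emulates the dense-
    sampling regime of large recordings, where the nearest tissue
    neighbours of any neuron are retinotopically homogeneous.  Responses
    are generated exactly by the convolutional encoding model plus
    optional Gaussian noise per repeat.
    """
    from .retinotopy import kernel_response_maps
    rng = np.random.default_rng(config.seed)
    h, w = config.image_shape
    m = config.kernel_size // 2
    kernels = make_kernel_bank(config.n_kernels, config.kernel_size, rng)

    # clustered tissue with a linear retinotopic gradient
    sx, sy = config.tissue_span
    centres = np.column_stack([rng.uniform(0, sx, config.n_clusters),
                               rng.uniform(0, sy, config.n_clusters)])
    assign = rng.permutation(np.arange(config.n_neurons) % config.n_clusters)
    tissue = (centres[assign]
              + config.cluster_scatter * rng.standard_normal((config.n_neurons, 2)))
    gx = (w - 2 * m - 1) / sx  # map columns per μm of tissue x
    gy = (h - 2 * m - 1) / sy
    map_x = np.clip(np.round(m + centres[assign, 0] * gx), m, w - m - 1).astype(int)
    map_y = np.clip(np.round(m + centres[assign, 1] * gy), m, h - m - 1).astype(int)
    k_idx = rng.integers(0, config.n_kernels, config.n_neurons)
    amps = rng.uniform(*config.amp_range, size=config.n_neurons)

    images = rng.standard_normal((config.n_images, h, w)).astype(np.float32)
    maps = kernel_response_maps(images, kernels)  # (K, H, W, n_images)
    clean = amps[:, None] * maps[k_idx, map_y, map_x, :]
    if config.noise_scale > 0:
        sd = clean.std(axis=1, keepdims=True) * config.noise_scale
        responses = (clean[:, :, None] + sd[:, :, None]
                     * rng.standard_normal(clean.shape + (config.n_repeats,),
                                           dtype=np.float32))
    else:
        responses = np.repeat(clean[:, :, None], config.n_repeats, axis=2)

    if config.planted_affine is not None:
        a1 = np.asarray(config.planted_affine[0], float)
        a2 = np.asarray(config.planted_affine[1], float)
        recorded = (np.linalg.inv(a1) @ (tissue - a2).T).T
        affine = (a1, a2)
    else:
        recorded = tissue
        affine = (np.eye(2), np.zeros(2))

    gt = GroundTruth(
        region=np.full(config.n_neurons, "none", dtype=str),
        neuron_class=np.full(config.n_neurons, "none", dtype=str),
        pref_position={}, delta=np.zeros(config.n_neurons),
        bump_amp=np.zeros(config.n_neurons),
        rp_flag=np.zeros(config.n_neurons, bool),
        true_dprime=np.zeros(config.n_neurons),
        rf_x=map_x, rf_y=map_y, rf_kernel=k_idx, rf_amp=amps,
        tissue_xy=recorded, aligned_tissue_xy=tissue, planted_affine=affine,
        gradient={"gx": gx, "gy": gy, "margin": m,
                  "span": (float(sx), float(sy))},
    )
    return images, responses, kernels, gt


def reference_retinotopy(gt: GroundTruth, spacing: float = 100.0,
                         margin: float = 400.0):
    """Dense (tissue, retinotopy) reference pairs from the planted gradient.

    Samples the planted linear retinotopic gradient on a regular tissue
    grid extending ``margin`` μm beyond the simulated span, giving the
    reference-session map that kriging alignment is fitted on.  Targets
    are the continuous (unrounded) map coordinates.
    """
    if gt.gradient is None:
        raise ValueError("ground truth carries no retinotopic gradient")
    g = gt.gradient
    sx, sy = g["span"]
    xs = np.arange(-margin, sx + margin + spacing / 2, spacing)
    ys = np.arange(-margin, sy + margin + spacing / 2, spacing)
    tissue = np.array([[x, y] for y in ys for x in xs])
    retino = np.column_stack([g["margin"] + tissue[:, 0] * g["gx"],
                              g["margin"] + tissue[:, 1] * g["gy"]])
    return tissue, retino
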