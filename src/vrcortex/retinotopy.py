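"""Retinotopic mapping from natural-image responses.

Four stages:

1. **Kernel-bank fitting** — neural responses to images are modelled as
   ``F_n(img) = a_n * (K o img)(k_n, x_n, y_n)``: each neuron reads one
   convolutional filter at one position of the downsampled image frame.
   An EM-like loop alternates brute-force assignment (correlate every
   neuron with every kernel at every position, take the best) with kernel
   re-estimation (least-squares regression of the assigned neurons'
   responses onto their image patches, the exact form of averaging their
   aligned linear receptive fields), recentring kernels by their
   absolute-value centre of mass after each iteration.  The model is
   identifiable only up to per-kernel integer shifts (kernel moved one
   pixel, positions moved the opposite way); :func:`match_kernels`
   quotients that gauge out when comparing fits.
2. **Smoothed assignment** — for robustness on weak neurons, each
   neuron's maximum-correlation map is averaged with the maps of its
   nearest tissue neighbours (self included) before the argmax.
3. **Kriging alignment** — a squared-exponential-kernel interpolator
   fitted on a reference session maps tissue coordinates to retinotopy;
   new sessions are registered to it with an affine transform found by a
   translation grid search plus backtracking gradient descent with an
   identity-regularized linear part (optionally determinant-fixed).
4. **Sign map** — the sine of the angle between the cortical gradients
   of the two retinotopic coordinates, parcellated into constant-sign
   regions; the sign flips across area boundaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans
from sklearn.neighbors import NearestNeighbors


# ---------------------------------------------------------------------------
# shared primitives


def kernel_response_maps(images: np.ndarray, kernels: np.ndarray) -> np.ndarray:
    """Cross-correlation of every image with every kernel.

    Returns (n_kernels, H, W, n_images): the response of kernel k centred
    at (y, x) to image i.
    """
    images = np.asarray(images, dtype=np.float32)
    n_img, h, w = images.shape
    out = np.empty((kernels.shape[0], h, w, n_img), dtype=np.float32)
    for k in range(kernels.shape[0]):
        flipped = kernels[k][::-1, ::-1].astype(np.float32)
        conv = signal.fftconvolve(images, flipped[None], mode="same", axes=(1, 2))
        out[k] = np.transpose(conv, (1, 2, 0))
    return out


def _roll_zero(k: np.ndarray, shift: tuple) -> np.ndarray:
    """np.roll with zero fill instead of wrap-around."""
    rolled = np.roll(k, shift, axis=(0, 1))
    sy, sx = shift
    if sy > 0:
        rolled[:sy, :] = 0
    elif sy < 0:
        rolled[sy:, :] = 0
    if sx > 0:
        rolled[:, :sx] = 0
    elif sx < 0:
        rolled[:, sx:] = 0
    return rolled


def recentre_kernels(kernels: np.ndarray) -> np.ndarray:
    """Integer-shift kernels so the centre of mass of |K| is central.

    After recentring the centre of mass lies within half a pixel of the
    frame centre.  The encoding model is invariant to moving a kernel by
    one pixel while moving all its neurons' positions the opposite way,
    so recovered kernels are defined only up to such an integer shift;
    :func:`match_kernels` quotients that gauge out when comparing banks.
    """
    out = np.array(kernels, dtype=float, copy=True)
    size = out.shape[-1]
    centre = (size - 1) / 2.0
    idx = np.arange(size)
    for i in range(out.shape[0]):
        a = np.abs(out[i])
        total = a.sum()
        if total == 0:
            continue
        cy = (a.sum(1) * idx).sum() / total
        cx = (a.sum(0) * idx).sum() / total
        shift = (int(round(centre - cy)), int(round(centre - cx)))
        if shift != (0, 0):
            out[i] = _roll_zero(out[i], shift)
    return out


def match_kernels(fitted: np.ndarray, reference: np.ndarray,
                  max_shift: int = 1):
    """Pair fitted kernels with reference kernels modulo the shift gauge.

    Because (K shifted by d, positions - d) generates identical
    responses, a fitted bank equals the generating bank only up to a
    permutation and a per-kernel integer shift.  Returns
    ``(pairing, shifts, correlations)``: ``pairing[i]`` is the reference
    index matched to fitted kernel i (Hungarian assignment on the
    shift-maximized absolute correlation), ``shifts[i]`` the (dy, dx)
    that best aligns fitted kernel i to its reference, and
    ``correlations[i]`` the correlation after alignment.  A neuron
    assigned to fitted kernel i sits at true map position
    ``(x - shifts[i, 1], y - shifts[i, 0])``.
    """
    from scipy.optimize import linear_sum_assignment
    nf, nr = fitted.shape[0], reference.shape[0]
    offsets = [(dy, dx) for dy in range(-max_shift, max_shift + 1)
               for dx in range(-max_shift, max_shift + 1)]
    corr = np.zeros((nf, nr))
    best_shift = np.zeros((nf, nr, 2), dtype=int)
    for i in range(nf):
        for (dy, dx) in offsets:
            cand = _roll_zero(fitted[i], (dy, dx)).ravel()
            if cand.std() == 0:
                continue
            c = np.abs(np.corrcoef(cand, reference.reshape(nr, -1))[0, 1:])
            better = c > corr[i]
            corr[i, better] = c[better]
            best_shift[i, better] = (dy, dx)
    rows, cols = linear_sum_assignment(-corr)
    pairing = np.empty(nf, dtype=int)
    shifts = np.zeros((nf, 2), dtype=int)
    corrs = np.zeros(nf)
    pairing[rows] = cols
    for i, j in zip(rows, cols):
        shifts[i] = best_shift[i, j]
        corrs[i] = corr[i, j]
    return pairing, shifts, corrs


def kernel_centre_of_mass(kernels: np.ndarray) -> np.ndarray:
    """(n_kernels, 2) centre of mass (row, col) of the absolute coefficients."""
    size = kernels.shape[-1]
    idx = np.arange(size)
    a = np.abs(kernels)
    tot = a.sum(axis=(1, 2))
    cy = (a.sum(2) * idx).sum(1) / tot
    cx = (a.sum(1) * idx).sum(1) / tot
    return np.column_stack([cy, cx])


# ---------------------------------------------------------------------------
# encoding-model fit


@dataclass
class KernelBank:
    """Fitted convolutional filters with the per-iteration correlation log."""

    kernels: np.ndarray  # (n_kernels, k, k)
    image_shape: tuple
    iteration_log: list = field(default_factory=list)

    @property
    def margin(self) -> int:
        return self.kernels.shape[-1] // 2


@dataclass
class NeuronRFAssignment:
    """Per-neuron receptive-field fit: map position, kernel index, amplitude."""

    x: np.ndarray
    y: np.ndarray
    kernel: np.ndarray
    amplitude: np.ndarray
    correlation: np.ndarray


class _CorrEngine:
    """Precomputes z-scored kernel response maps for fast correlation."""

    def __init__(self, images, kernels):
        self.n_img, self.h, self.w = images.shape
        self.m = kernels.shape[-1] // 2
        maps = kernel_response_maps(images, kernels)
        self.ys = np.arange(self.m, self.h - self.m)
        self.xs = np.arange(self.m, self.w - self.m)
        sub = maps[:, self.m:self.h - self.m, self.m:self.w - self.m, :]
        k = kernels.shape[0]
        self.n_pos = self.ys.size * self.xs.size
        flat = sub.reshape(k, self.n_pos, self.n_img)
        mean = flat.mean(axis=2, keepdims=True)
        std = flat.std(axis=2, keepdims=True)
        self.map_std = std[:, :, 0]
        safe = np.where(std > 0, std, 1.0)
        self.maps_z = ((flat - mean) / safe).astype(np.float32)
        self.k = k

    def correlations(self, responses):
        """(n_neurons, n_kernels, n_pos) Pearson correlations."""
        r = np.asarray(responses, dtype=np.float32)
        mean = r.mean(axis=1, keepdims=True)
        std = r.std(axis=1, keepdims=True)
        self.resp_std = std[:, 0]
        rz = (r - mean) / np.where(std > 0, std, 1.0)
        flat = self.maps_z.reshape(self.k * self.n_pos, self.n_img)
        corr = rz @ flat.T / self.n_img
        return corr.reshape(r.shape[0], self.k, self.n_pos)

    def pos_to_xy(self, pos_idx):
        yy, xx = np.unravel_index(pos_idx, (self.ys.size, self.xs.size))
        return self.xs[xx], self.ys[yy]


def _average_repeats(responses):
    r = np.asarray(responses, dtype=np.float32)
    return r.mean(axis=2) if r.ndim == 3 else r


def _assign_best(engine: _CorrEngine, responses):
    corr = engine.correlations(responses)
    n = corr.shape[0]
    flat = corr.reshape(n, -1)
    best = flat.argmax(axis=1)
    best_corr = flat[np.arange(n), best]
    k_idx, pos_idx = np.unravel_index(best, (engine.k, engine.n_pos))
    x, y = engine.pos_to_xy(pos_idx)
    slope = (best_corr * engine.resp_std
             / np.maximum(engine.map_std[k_idx, pos_idx], 1e-12))
    amp = np.maximum(slope, 1e-12)
    return NeuronRFAssignment(x, y, k_idx, amp, best_corr), corr


def _neuron_rfs(responses, images):
    """Linear receptive fields (response-weighted image averages)."""
    r = responses - responses.mean(axis=1, keepdims=True)
    n_img, h, w = images.shape
    rf = r @ images.reshape(n_img, h * w) / n_img
    return rf.reshape(-1, h, w)


def _refit_kernels(assign: NeuronRFAssignment, resp, images, rfs, n_kernels,
                   size, h, w, cov_cache: dict | None = None):
    """M-step: least-squares kernel estimate given fixed assignments.

    Solves ``K_k = argmin sum_n ||r_n - a_n X_n K||^2`` over the neurons
    assigned to kernel k, where X_n is the stack of image patches at the
    neuron's position.  Unlike averaging the neurons' linear receptive
    fields (which this reduces to for infinitely many white-noise
    images), the regression removes the finite-image sampling noise: on
    noise-free responses with correct assignments it recovers the kernel
    exactly, which pins the alternation's fixed point.
    """
    m = size // 2
    n_img = images.shape[0]
    d = size * size
    if cov_cache is None:
        cov_cache = {}

    def patch_design(y, x):
        return images[:, y - m:y + m + 1, x - m:x + m + 1].reshape(n_img, d)

    def patch_cov(y, x):
        key = (int(y), int(x))
        if key in cov_cache:
            return cov_cache[key]
        p = patch_design(*key).astype(np.float64)
        cov = p.T @ p
        if len(cov_cache) < 1200:  # ~0.23 MB per entry
            cov_cache[key] = cov
        return cov

    def regress(members, ys, xs):
        a_mat = np.zeros((d, d))
        b_vec = np.zeros(d)
        # group members by position so each patch covariance enters once
        by_pos: dict = {}
        for n, y, x in zip(members, ys, xs):
            by_pos.setdefault((int(y), int(x)), []).append(n)
        for (y, x), ns in by_pos.items():
            amps = assign.amplitude[ns]
            a_mat += float(np.sum(amps ** 2)) * patch_cov(y, x)
            rsum = (amps[:, None] * resp[ns].astype(np.float64)).sum(axis=0)
            b_vec += patch_design(y, x).astype(np.float64).T @ rsum
        ridge = 1e-9 * max(np.trace(a_mat), 1e-30) / d
        k_hat = np.linalg.solve(a_mat + ridge * np.eye(d), b_vec)
        # residual = r'r - b'K, so b'K ranks registrations by fit quality
        return k_hat.reshape(size, size), float(b_vec @ k_hat)

    new = np.zeros((n_kernels, size, size))
    counts = np.bincount(assign.kernel, minlength=n_kernels)
    for k in range(n_kernels):
        members = np.flatnonzero(assign.kernel == k)
        if members.size == 0:
            continue
        if members.size >= 10:
            # trimmed estimation: mis-registered members correlate worse
            # with the current kernel and would drag the estimate toward
            # a blurred blend, so refit from the well-fitted majority
            cut = np.quantile(assign.correlation[members], 0.4)
            members = members[assign.correlation[members] >= cut]
        ys, xs = assign.y[members], assign.x[members]
        # A coherent mis-registration of the whole cluster (every position
        # one pixel off, kernel shifted the opposite way) is a stable
        # local optimum because shifted patches truncate the kernel, so
        # the refit scores all one-pixel coherent shifts and keeps the
        # registration that explains the responses best.
        best_hat, best_score = None, -np.inf
        for dy in (0, -1, 1):
            for dx in (0, -1, 1):
                k_hat, score = regress(members,
                                       np.clip(ys + dy, m, h - m - 1),
                                       np.clip(xs + dx, m, w - m - 1))
                if best_hat is None or score > best_score + 1e-9 * abs(best_score):
                    best_hat, best_score = k_hat, score
        new[k] = best_hat
    norms = np.linalg.norm(new, axis=(1, 2), keepdims=True)
    new /= np.where(norms > 0, norms, 1.0)

    # k-means-style cluster maintenance: a kernel that captured no neurons,
    # or that duplicates another (|corr| > 0.9), is re-seeded from the
    # receptive field of a strong, badly fitted neuron -- typically a
    # neuron of an underlying filter the bank does not yet represent.
    flat = new.reshape(n_kernels, -1)
    gram = np.abs(flat @ flat.T)
    redundant = set(np.flatnonzero(counts == 0))
    for i in range(n_kernels):
        for j in range(i + 1, n_kernels):
            if gram[i, j] > 0.9 and j not in redundant and i not in redundant:
                redundant.add(j if counts[j] <= counts[i] else i)
    if redundant:
        patches, pnorms = _energy_centred_patches(rfs, size, h, w)
        score = pnorms * (1.0 - assign.correlation)
        for k in sorted(redundant):
            n = int(score.argmax())
            score[n] = -np.inf
            new[k] = patches[n].reshape(size, size)
    return recentre_kernels(new)


def _energy_centred_patches(rfs, size, h, w):
    """Unit-norm receptive-field patches centred on the smoothed RF energy.

    The energy window spans the full kernel size, so its argmax sits at
    the receptive field's centre rather than wherever the filter's
    largest single coefficient happens to be.
    """
    m = size // 2
    n = rfs.shape[0]
    raw = np.empty((n, size, size))
    norms = np.empty(n)
    for i in range(n):
        energy = ndimage.uniform_filter(rfs[i] ** 2, size=size)
        yy, xx = np.unravel_index(
            energy[m:h - m, m:w - m].argmax(), (h - 2 * m, w - 2 * m))
        patch = rfs[i, yy:yy + size, xx:xx + size]
        norms[i] = np.linalg.norm(patch)
        raw[i] = patch / max(norms[i], 1e-12)
    return raw.reshape(n, size * size), norms


def _init_from_patches(rfs, n_kernels, size, h, w, start_rank: int = 0):
    """Seed kernels from mutually dissimilar neuron receptive-field patches.

    Greedy farthest-point selection on patch correlation (the k-means++
    idea): start from the ``start_rank``-th strongest receptive field,
    then repeatedly add the strongest patch least correlated with
    everything chosen so far, and denoise each seed by averaging its most
    similar peers.  This avoids the local optima of a purely random
    start, where two kernels converge onto one underlying filter and
    leave another unclaimed.
    """
    patches, norms = _energy_centred_patches(rfs, size, h, w)
    # candidate pool: signal-dominated patches only, so that pure-noise
    # patches cannot corrupt the cluster centroids
    pool = np.flatnonzero(norms >= np.median(norms))
    if pool.size < n_kernels:
        pool = np.arange(patches.shape[0])
    km = KMeans(n_clusters=min(n_kernels, pool.size), n_init=10,
                random_state=start_rank)
    km.fit(patches[pool])
    kernels = np.zeros((n_kernels, size * size))
    kernels[:km.cluster_centers_.shape[0]] = km.cluster_centers_
    kn = np.linalg.norm(kernels, axis=1, keepdims=True)
    kernels /= np.where(kn > 0, kn, 1.0)
    return recentre_kernels(kernels.reshape(n_kernels, size, size))


def _em_run(resp, images, rfs, init_kernels, n_kernels, kernel_size,
            max_iter, h, w, cov_cache):
    """One EM run: returns (kernels, assignment, correlation log).

    An iteration that lowers the mean assignment correlation is reverted
    and stops the run, so the log is non-decreasing; the run also stops
    when assignments stabilize.
    """
    kernels = init_kernels
    log: list[float] = []
    best_state = None
    for _ in range(max_iter):
        engine = _CorrEngine(images, kernels)
        assign, _ = _assign_best(engine, resp)
        mc = float(assign.correlation.mean())
        if log and mc < log[-1] - 1e-9:
            kernels, assign = best_state
            break
        log.append(mc)
        if best_state is not None and np.array_equal(
                np.c_[assign.x, assign.y, assign.kernel],
                np.c_[best_state[1].x, best_state[1].y, best_state[1].kernel]):
            best_state = (kernels, assign)
            break
        best_state = (kernels, assign)
        kernels = _refit_kernels(assign, resp, images, rfs, n_kernels,
                                 kernel_size, h, w, cov_cache)
    return best_state[0], best_state[1], log


def fit_kernel_bank(responses, images, n_kernels: int = 200,
                    kernel_size: int = 13, max_iter: int = 10,
                    seed: int = 0, init: str = "patches",
                    init_kernels=None, n_restarts: int = 3):
    """Fit the convolutional encoding model by EM-like alternation.

    Alternates (i) brute-force best (x, y, k, a) per neuron by maximum
    correlation over all kernels and positions and (ii) kernel refit from
    the assigned neurons' receptive fields aligned to their centres, with
    recentring after every refit.  Like any k-means-style alternation the
    loop can stall in a local optimum, so ``n_restarts`` runs from
    different deterministic seeds are fitted and the one with the highest
    mean assignment correlation is kept; each run stops early when its
    correlation stops improving, which keeps the reported iteration log
    non-decreasing.  ``init`` seeds kernels from dissimilar
    receptive-field patches (default) or Gaussian noise (``'random'``).
    """
    images = np.asarray(images, dtype=np.float32)
    resp = _average_repeats(responses)
    n_img, h, w = images.shape
    if n_img < n_kernels * kernel_size:
        warnings.warn("fewer images than kernel free parameters; "
                      "the fit may be ill-posed", stacklevel=2)
    rng = np.random.default_rng(seed)
    rfs = _neuron_rfs(resp.astype(np.float64), images.astype(np.float64))

    def make_init(r):
        if init_kernels is not None:
            return np.array(init_kernels, dtype=float, copy=True)
        if init == "patches":
            return _init_from_patches(rfs, n_kernels, kernel_size, h, w,
                                      start_rank=r)
        if init == "random":
            k = rng.standard_normal((n_kernels, kernel_size, kernel_size))
            k /= np.linalg.norm(k, axis=(1, 2), keepdims=True)
            return recentre_kernels(k)
        raise ValueError("init must be 'patches' or 'random'")

    if init_kernels is not None:
        n_restarts = 1
    best = None
    cov_cache: dict = {}
    for r in range(max(1, n_restarts)):
        kernels, assign, log = _em_run(resp, images, rfs, make_init(r),
                                       n_kernels, kernel_size, max_iter, h, w,
                                       cov_cache)
        if best is None or log[-1] > best[2][-1]:
            best = (kernels, assign, log)
        if log[-1] > 0.999:
            break
    kernels, assign, log = best
    return KernelBank(kernels, (h, w), log), assign


def assign_neurons_smoothed(responses, images, bank: KernelBank,
                            tissue_xy, n_neighbors: int = 50
                            ) -> NeuronRFAssignment:
    """Assign receptive fields using neighbourhood-averaged correlation maps.

    Each neuron's maximum-over-kernels correlation map is averaged with
    the maps of its ``n_neighbors`` nearest tissue neighbours (Euclidean
    distance, self included) and the argmax of the averaged map gives the
    position; the neuron's own best kernel and amplitude at that position
    complete the fit.  With ``n_neighbors=1`` this reduces to the plain
    per-neuron assignment.
    """
    resp = _average_repeats(responses)
    tissue_xy = np.asarray(tissue_xy, dtype=float)
    n = resp.shape[0]
    if n_neighbors > n:
        warnings.warn("n_neighbors exceeds the neuron count; clipping",
                      stacklevel=2)
        n_neighbors = n
    engine = _CorrEngine(np.asarray(images, np.float32), bank.kernels)
    corr = engine.correlations(resp)  # (n, K, P)
    corr_max = corr.max(axis=1)  # (n, P)
    nn = NearestNeighbors(n_neighbors=n_neighbors).fit(tissue_xy)
    _, nbrs = nn.kneighbors(tissue_xy)
    averaged = corr_max[nbrs].mean(axis=1)  # (n, P)
    pos_idx = averaged.argmax(axis=1)
    x, y = engine.pos_to_xy(pos_idx)
    own = corr[np.arange(n), :, pos_idx]  # (n, K)
    k_idx = own.argmax(axis=1)
    best_corr = own[np.arange(n), k_idx]
    slope = (best_corr * engine.resp_std
             / np.maximum(engine.map_std[k_idx, pos_idx], 1e-12))
    return NeuronRFAssignment(x, y, k_idx, np.maximum(slope, 1e-12), best_corr)


# ---------------------------------------------------------------------------
# kriging alignment


@dataclass
class KrigingAlignment:
    """Squared-exponential-kernel interpolator from tissue to retinotopy."""

    ref_tissue: np.ndarray
    ref_retino: np.ndarray
    sigma: float
    weights: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        z = np.asarray(self.ref_tissue, dtype=float)
        y = np.asarray(self.ref_retino, dtype=float)
        if z.shape[0] < 3:
            raise ValueError("need at least 3 reference points")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        gram = np.exp(-cdist(z, z, "sqeuclidean") / self.sigma ** 2)
        # squared-exponential Gram matrices are severely ill-conditioned;
        # an SVD-based minimal-norm solve keeps the interpolation property
        # where a Cholesky solve accumulates large residuals
        self.weights, _, rank, _ = np.linalg.lstsq(gram, y, rcond=None)
        if rank < z.shape[0]:
            resid = gram @ self.weights - y
            if np.abs(resid).max() > 1e-3 * max(np.abs(y).max(), 1.0):
                warnings.warn("degenerate kriging system: reference points "
                              "carry contradictory targets", stacklevel=2)
        self.ref_tissue = z
        self.ref_retino = y

    def predict(self, tissue) -> np.ndarray:
        """Interpolated retinotopic positions at arbitrary tissue points."""
        pts = np.atleast_2d(np.asarray(tissue, dtype=float))
        k = np.exp(-cdist(pts, self.ref_tissue, "sqeuclidean") / self.sigma ** 2)
        return k @ self.weights


def fit_kriging_transform(ref_tissue, ref_retino,
                          sigma: float = 200.0) -> KrigingAlignment:
    """Fit the tissue-to-retinotopy interpolator on a reference session."""
    return KrigingAlignment(np.asarray(ref_tissue), np.asarray(ref_retino), sigma)


@dataclass
class AffineFit:
    """Result of registering a session to the reference retinotopy."""

    a1: np.ndarray
    a2: np.ndarray
    cost: float
    cost_log: list
    converged: bool
    restricted: bool
    alternative: "AffineFit | None" = None


def _alignment_cost(alignment, tissue, retino, a1, a2, reg):
    mapped = tissue @ a1.T + a2
    pred = alignment.predict(mapped)
    data = float(np.mean(np.sum((pred - retino) ** 2, axis=1)))
    return data + reg * float(np.sum((a1 - np.eye(2)) ** 2))


def _centred_cost(alignment, centred, centroid, retino, a1, t, reg):
    # rotation about the tissue centroid decouples it from translation,
    # which keeps the descent well conditioned
    mapped = centred @ a1.T + t + centroid
    pred = alignment.predict(mapped)
    data = float(np.mean(np.sum((pred - retino) ** 2, axis=1)))
    return data + reg * float(np.sum((a1 - np.eye(2)) ** 2))


def _descend(cost_fn, theta0, max_iter, step0=0.05):
    """Backtracking gradient descent with an adaptive step.

    The recorded cost trajectory is non-increasing by construction: a
    proposal that does not lower the cost halves the step and is retried.
    """
    theta = np.asarray(theta0, dtype=float)
    c = cost_fn(theta)
    log = [c]
    step = step0
    eps = 1e-5
    for _ in range(max_iter):
        grad = np.empty_like(theta)
        for i in range(theta.size):
            up = theta.copy()
            dn = theta.copy()
            up[i] += eps
            dn[i] -= eps
            grad[i] = (cost_fn(up) - cost_fn(dn)) / (2 * eps)
        gnorm = np.linalg.norm(grad)
        if gnorm < 1e-14:
            break
        direction = grad / gnorm
        improved = False
        while step > 1e-12:
            cand = theta - step * direction
            cc = cost_fn(cand)
            if cc < c - 1e-15:
                theta, c = cand, cc
                log.append(c)
                step *= 1.4
                improved = True
                break
            step *= 0.5
        if not improved:
            break
    return theta, c, log


def align_session(new_tissue, new_retino, alignment: KrigingAlignment,
                  search_range: float = 500.0, grid_step: float = 50.0,
                  identity_reg: float = 1.0, max_iter: int = 500,
                  fixed_det: bool = False) -> AffineFit:
    """Find the affine transform registering a new session to the reference.

    Minimizes the mean squared distance between the kriging-predicted and
    measured retinotopic positions of the new session's neurons, over
    ``(z', t') -> A1 (z', t') + A2``.  A1 is initialized at the identity
    with A2 from a translation grid search within ±``search_range`` μm,
    then refined by backtracking gradient descent with a penalty pulling
    A1 toward the identity.  If the descent does not reduce the cost
    below its initialization, the fit is re-run with det(A1) fixed to 1
    (rotation + translation only) and the better candidate is returned
    with a non-convergence flag on the worse one.
    """
    tissue = np.asarray(new_tissue, dtype=float)
    retino = np.asarray(new_retino, dtype=float)
    # parameter scalings chosen so one unit of any parameter moves tissue
    # points by a comparable distance (descent conditioning)
    scale = 100.0  # μm per translation parameter unit
    mat_scale = 0.1  # A1 entry per parameter unit
    ang_scale = 0.2  # radians per parameter unit

    offsets = np.arange(-search_range, search_range + grid_step / 2, grid_step)
    best_a2 = np.zeros(2)
    best_c = np.inf
    eye = np.eye(2)
    for ox in offsets:
        for oy in offsets:
            c = _alignment_cost(alignment, tissue, retino, eye,
                                np.array([ox, oy]), identity_reg)
            if c < best_c:
                best_c, best_a2 = c, np.array([ox, oy])
    init_cost = best_c

    centroid = tissue.mean(axis=0)
    centred = tissue - centroid
    # the centred translation equivalent to the grid-search A2 (A1 = I)
    t0 = best_a2.copy()

    if fixed_det:
        def unpack(theta):
            ang = theta[0] * ang_scale
            a1 = np.array([[np.cos(ang), -np.sin(ang)],
                           [np.sin(ang), np.cos(ang)]])
            return a1, theta[1:3] * scale
        theta0 = np.array([0.0, t0[0] / scale, t0[1] / scale])
    else:
        def unpack(theta):
            return (np.eye(2) + mat_scale * theta[:4].reshape(2, 2),
                    theta[4:6] * scale)
        theta0 = np.array([0.0, 0.0, 0.0, 0.0, t0[0] / scale, t0[1] / scale])

    def cost_fn(theta):
        a1, t = unpack(theta)
        return _centred_cost(alignment, centred, centroid, retino, a1, t,
                             identity_reg)

    theta, cost, log = _descend(cost_fn, theta0, max_iter)
    a1, t = unpack(theta)
    a2 = t + centroid - a1 @ centroid
    converged = cost < init_cost - 1e-12 or init_cost < 1e-12
    fit = AffineFit(a1, a2, cost, log, converged, fixed_det)
    if not converged and not fixed_det:
        alt = align_session(new_tissue, new_retino, alignment, search_range,
                            grid_step, identity_reg, max_iter, fixed_det=True)
        if alt.cost < fit.cost:
            alt.alternative = fit
            return alt
        fit.alternative = alt
    return fit


# ---------------------------------------------------------------------------
# sign map


@dataclass
class SignMap:
    """Visual-field sign over the tissue grid with constant-sign parcels."""

    sign: np.ndarray
    labels: np.ndarray
    n_parcels: int


def compute_sign_map(x_field, y_field, threshold_frac: float = 0.3
                     ) -> SignMap:
    """Sign map and parcellation from two retinotopic coordinate fields.

    The signed field is the sine of the angle between the tissue
    gradients of x and y (their normalized cross product); it flips sign
    at visual-area boundaries.  Pixels whose |sign| is below
    ``threshold_frac`` of the maximum are ambiguous and are resolved by
    the nearest unambiguous parcel; pixels with vanishing gradients are
    masked (NaN, label 0).
    """
    xf = np.asarray(x_field, dtype=float)
    yf = np.asarray(y_field, dtype=float)
    gxr, gxc = np.gradient(xf)
    gyr, gyc = np.gradient(yf)
    cross = gxc * gyr - gxr * gyc
    norm = np.hypot(gxr, gxc) * np.hypot(gyr, gyc)
    with np.errstate(invalid="ignore", divide="ignore"):
        sgn = np.where(norm > 1e-12, cross / np.maximum(norm, 1e-300), np.nan)
    finite = np.isfinite(sgn)
    if not finite.any():
        return SignMap(sgn, np.zeros(sgn.shape, int), 0)
    thr = threshold_frac * np.nanmax(np.abs(sgn))
    labels = np.zeros(sgn.shape, dtype=int)
    pos_lab, n_pos = ndimage.label(finite & (sgn > thr))
    neg_lab, n_neg = ndimage.label(finite & (sgn < -thr))
    labels[pos_lab > 0] = pos_lab[pos_lab > 0]
    labels[neg_lab > 0] = neg_lab[neg_lab > 0] + n_pos
    ambiguous = finite & (labels == 0)
    if ambiguous.any() and (n_pos + n_neg) > 0:
        _, (ir, ic) = ndimage.distance_transform_edt(labels == 0,
                                                     return_indices=True)
        labels[ambiguous] = labels[ir[ambiguous], ic[ambiguous]]
    return SignMap(sgn, labels, n_pos + n_neg)
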