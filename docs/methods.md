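# Methods

This note documents the models and procedures vrcortex implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was genuinely
open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Session model

A session holds deconvolved event amplitudes (neurons × timepoints,
non-negative, a.u.), frame times (s), corridor position (m), running speed
(cm s⁻¹), per-timepoint trial ids (−1 between trials), per-neuron tissue
coordinates (μm) and cohort/phase labels. Each trial spans positions
[0, 6) m — texture in [0, 4), grey in [4, 6) — with the position origin at
corridor entry. Trials of one stimulus occupy contiguous time blocks.

**Running mask.** A timepoint is "running" if it lies in a maximal run of
frames with speed above the threshold (default 6 cm s⁻¹) whose duration —
the frame-time difference between the run's last and first frame — is at
least the minimum duration (default 66 ms, the threshold that moves the
virtual corridor). Using times rather than frame counts makes the rule
sampling-rate independent and idempotent.

**Position interpolation.** Per trial, activity is linearly interpolated
from (position, activity) samples at running timepoints onto bin centres of
a regular grid over [0, 6) m (default step 0.1 m). Frames sharing an exact
position (a stationary animal) are averaged first. Bins outside the
sampled range are NaN and excluded from all downstream averages — the
alternative (zero-filling) would invent activity where the animal never
ran. Interpolation is piecewise linear in position.

**Container.** One HDF5 file: `/activity`, `/frames/{times, position,
trial_id, speed}`, `/trials/{trial_index, stimulus, cue_position,
reward_position, rewarded}`, `/licks/{times, positions, trial_index}`,
`/neurons/tissue_xy`, `/meta` attributes. Write∘read is lossless.

## Selectivity index

For two corridors, per neuron, `d′ = (μ₁ − μ₂)/((σ₁ + σ₂)/2)` over raw
(uninterpolated) samples restricted to the texture zone and running
timepoints. Population standard deviations (ddof = 0) are used; at the
sample sizes involved the estimator choice is immaterial, but it is fixed
for reproducibility. Degenerate case: if both σ are zero the index is 0
for equal means and signed infinity otherwise; non-finite values can never
enter a selected set. Selection is two-sided at |d′| ≥ 0.3 with the
boundary included.

Density maps are 2-D histograms of selective-neuron tissue positions
(default bin 100 μm), Gaussian-smoothed (default σ = 200 μm; both exposed
in config — the analysis tradition fixes the construction but not the
widths), divided by the total recorded neuron count. Bins without recorded
neurons are NaN so that averaging maps across sessions never dilutes
regions only some sessions sampled. Regional percentages are
100 × selected/recorded per atlas region; the default atlas is a schematic
four-rectangle layout (V1, medial, lateral, anterior) standing in for a
real widefield atlas, which can be supplied instead as named rectangles.

## Sequence similarity

Selection uses a seeded random half of the reference-corridor trials
(train); a random rather than first/second-half split avoids slow-drift
confounds. The held-out half is split into odd/even interleaved trials;
stimuli not used for selection contribute all their trials to the odd/even
split. A neuron's preferred position is the argmax of its split-averaged
tuning curve, restricted to the texture zone (stimuli exist only there),
ties breaking toward the smaller position for determinism. Pearson
correlation of paired preferred positions (Spearman available as an
option) quantifies sequence transfer; a pairing-permutation null (default
1,000 shuffles) calibrates "no transfer".

## Coding direction and similarity index

Per neuron, activity is normalized bin-wise as
`r_norm = (r − μ_grey)/((σ_ref1 + σ_ref2)/2)`, where μ_grey is the mean
over running grey-zone timepoints of both reference corridors and the σ
are the standard deviations of the neuron's interpolated responses in each
reference corridor. Neurons with a zero denominator are excluded from axes
and projections. The axis is the top ⌈5%⌉ of the candidate pool by
train-trial d′ toward each reference (ties by neuron index; sets kept
disjoint; pools can be restricted per region). The per-trial projection is
the difference of the two populations' mean normalized activity —
numerically identical to projecting with weights 1/N₊, −1/N₋ and 0 — and
is always evaluated on trials excluded from axis fitting. `a_proj` is the
texture-zone mean. For a probe stimulus,
`dy = a_ref₊ − a_probe`, `dx = a_probe − a_ref₋`,
`SI = (dx − dy)/(dx + dy)`: +1 at the positive reference, −1 at the
negative one, 0 at the midpoint, and invariant to any affine rescaling
shared by all projections. A probe projecting outside the reference
interval yields SI outside [−1, 1]; the raw value is reported with an
`out_of_range` flag rather than clipped, since clipping would hide a
qualitatively different geometry.

## Reward-prediction detection

Rewarded-corridor trials are split at the median sound-cue position
(balanced groups under any cue distribution; odd counts favour the early
group). Per trial, the profile statistic is the mean interpolated activity
over positions [0, c_min) where c_min is the earliest late-group cue: this
window is pre-cue territory for every late trial while early trials are
already cue-suppressed inside it, which is what gives a ramp-and-reset
neuron its positive `d′_late_vs_early = (μ_late − μ_early)/((σ_late +
σ_early)/2)`. A neuron whose profile is a pure function of position has
identical expected statistics in both groups and converges to d′ = 0. The
full texture zone is available as an alternative window. Selection is
one-sided at d′ ≥ 0.3.

Population traces are k-fold cross-validated (default k = 10, seeded
shuffle): each fold's trials are scored as the mean over neurons selected
on the other folds only. On null data, neurons selected by chance show a
spurious late-vs-early contrast on their own selection trials; the CV
trace removes exactly that bias, which is why the non-CV trace is only a
diagnostic. Event-aligned averages centre activity and lick rate (100 ms
bins, 250 ms box smoothing) on the cue crossing or the first lick;
first-lick alignment includes only trials whose first lick came after 2 m,
excluding alignment artefacts of early consummatory licking. Window
overhangs beyond the recording are missing, never zero-filled.

## Behaviour

A trial counts as a response iff some lick lands inside the corridor
strictly before the sound cue (imaging task) or before the reward-zone
onset drawn per trial from [2, 3] m (behaviour-only task) — adding licks
after the boundary can never change the flag, which rules out responses
triggered by reward delivery itself. Discrimination is the response-rate
difference rewarded − unrewarded (antisymmetric under role swap).
First-lick histograms use the 0.1 m position grid, normalized over trials
with licks; lick-free trials are counted separately.

## Retinotopy

**Encoding model.** `F_n(img) = a_n · (K ∘ img)(k_n, x_n, y_n)`: neuron n
reads one filter of the bank K (default 13 × 13 coefficients) at one
position of the downsampled image frame (default 30 × 120), with a
positive amplitude. Repeats are averaged before fitting.

**Fitting.** An EM-like alternation: (E) brute-force assignment — Pearson
correlation of every neuron's response vector with every kernel's response
map at every interior position, argmax gives (x, y, k), the regression
slope gives a; (M) kernel re-estimation by least-squares regression of the
assigned neurons' responses onto their image patches. The regression is
the exact form of the often-quoted "average the aligned linear receptive
fields": the two coincide for infinitely many white-noise images, but at
the hundreds of images used here the receptive-field (spike-triggered
average) route carries enough sampling noise to destabilize the
alternation, whereas the regression recovers kernels exactly from
noise-free responses and pins the fixed point. Kernels are recentred by
the integer shift placing the centre of mass of |K| within half a pixel of
the frame centre after every refit.

Numerical safeguards, all standard k-means-style machinery: kernels are
seeded by KMeans clustering of energy-centred receptive-field patches (a
random seed bank often collapses two kernels onto one underlying filter);
the refit trims each kernel's members to the best-correlated 60% when
enough are available; each kernel's refit scores all nine coherent
one-pixel registrations of its members and keeps the best (whole-cluster
mis-registrations are otherwise self-stabilizing, because shifted patches
truncate the kernel); dead or duplicate (|corr| > 0.9) kernels are
re-seeded from strong, badly-fitted neurons; and a small number of
deterministic restarts keeps the run with the highest mean assignment
correlation. A run stops when assignments stabilize, when an iteration
fails to improve the mean correlation (the step is reverted, so the logged
correlation trace is non-decreasing), or at the iteration cap (default 10).

**Shift gauge.** The model is identifiable only up to per-kernel integer
shifts: moving a kernel one pixel while moving all its neurons' positions
the opposite way yields identical responses. `match_kernels` pairs a
fitted bank with a reference bank by Hungarian assignment on the
shift-maximized absolute correlation and returns the per-kernel shift;
positions are compared after applying it, exactly as clusterings are
compared up to label permutation.

**Smoothed assignment.** Each neuron's maximum-over-kernels correlation
map is averaged with those of its 50 nearest tissue neighbours (Euclidean
distance, self included) before the argmax; the neuron's own best kernel
and slope at that position complete the fit. With one neighbour this
reduces to the plain assignment. The procedure presumes retinotopically
homogeneous neighbourhoods — true in recordings of tens of thousands of
neurons, and emulated at desk scale by the generator's columnar clusters
(below).

**Kriging alignment.** The reference interpolator is simple kriging with a
squared-exponential kernel `F(a,b) = exp(−‖a−b‖²/σ²)`, σ = 200 μm:
weights `W = G⁻¹Y` on the reference Gram matrix G and retinotopic targets
Y, prediction `f(p) = F(p, Z)·W`. The Gram solve uses an SVD-based
least-squares solve: squared-exponential Gram matrices over dense
references are numerically singular, and a Cholesky solve leaves
pixel-scale residuals that break the interpolation property. A new
session's affine registration `(z′,t′) ↦ A₁(z′,t′) + A₂` minimizes the
mean squared distance between `f(A₁z′ + A₂)` and the session's measured
retinotopy, plus a penalty `λ‖A₁ − I‖²_F` (default λ = 1 in squared map
units) keeping the linear part near the identity. A₂ is initialized by a
translation grid search (±500 μm, 50 μm steps; both exposed), then refined
by backtracking gradient descent (central-difference gradients, adaptive
step, 500-iteration cap) whose accepted-cost trajectory never increases.
Descent conditioning: rotation is taken about the tissue centroid
(decoupling it from translation) and parameters are scaled so a unit step
in any of them moves tissue points comparably. If the descent fails to
beat its initialization the fit is re-run with det(A₁) fixed to 1
(rotation + translation only, preventing scaling) and the better candidate
is returned with the other attached.

**Sign map.** The signed field is the sine of the angle between the
tissue gradients of the two retinotopic coordinates (their normalized
cross product); it flips across visual-area boundaries. Pixels below 30%
of the maximum |sign| are ambiguous and inherit the nearest unambiguous
parcel (ties resolve toward larger parcels via the distance transform);
pixels with vanishing gradients are masked. Parcels are connected
components of constant sign.

## Synthetic-data generator

The generator is first-class, tested code; its defaults define the study
conditions used throughout the tests and the acceptance script.

**Sessions.** Trials of each stimulus (default 200 per stimulus — a
roughly two-hour session at ~10 s per traversal of two corridors) are
presented in a seeded random order; the mouse runs at the fixed 60 cm s⁻¹
virtual speed (10 Hz frames), with a brief sub-threshold pause inserted in
10% of trials; sound cues are uniform on [0.5, 3.5] m, and rewards in the
task group follow the cue in the rewarded corridor. Deconvolved amplitudes
are rectified Gaussians around a mean rate — non-negative like real
deconvolved traces, and with closed-form moments so every planted effect
has an analytic oracle. The mean rate is a baseline (0.2 a.u.) plus a
Gaussian position bump (amplitude uniform on [0.5, 1.5] a.u., width
0.4 m, centre uniform over the texture zone) plus condition terms; noise
σ = 0.3 a.u. per frame.

*Selectivity* is planted as an additive texture-zone drive in the
preferred corridor whose magnitude is calibrated per neuron — by bisection
on the analytic rectified-Gaussian position-mixture d′ — so the planted
population d′ equals `target_dprime` exactly in expectation. *Coding
regimes*: in the spatial regime a neuron's bump position is shared across
all stimuli; in the visual regime it is drawn independently per stimulus
while the category drive (leaf vs circle axis, per-stimulus drive weights)
is shared. *Novelty* adds a population-wide drive decaying exponentially
with stimulus repetitions. *Reward-prediction neurons* (a fraction of
anterior neurons) replace the bump with a ramp rising with position until
the trial's cue and collapsing to baseline after it, in the rewarded
corridor only. *Licking* follows a policy with a discrimination level:
rewarded-corridor trials always contain anticipatory licks; unrewarded
corridors are licked with probability 1 − discrimination. Multi-day
cohorts use saturating learning curves
`level·(1 − exp(−(day − 1 + prior)/τ))` whose `prior` term credits
pretraining.

**Image responses.** White-noise images; planted kernels are smoothed
Gaussian noise under a Gaussian spatial envelope (σ = size/4), unit norm,
centre of mass centred — localized like measured receptive fields, which
also keeps the shift gauge benign (border truncation from a one-pixel
re-registration costs almost nothing). Tissue positions form columnar
clusters (default 50 clusters, 30 μm scatter) whose members share a map
position given by a linear retinotopic gradient at the cluster centre:
this reproduces the dense-sampling regime in which nearest-neighbour
smoothing is meaningful, at a thousandth of the real neuron count.
Responses follow the encoding model exactly, plus optional Gaussian noise
scaled per neuron to its signal s.d. (`noise_scale = 1` is SNR 1), with
repeats sharing the mean. `reference_retinotopy` samples the planted
gradient on a dense regular grid, standing in for the reference session's
map in alignment tests; planted affine distortions are applied inversely
to the recorded tissue coordinates so recovery targets the planted (A₁, A₂)
directly.

**What passing tests do not show.** The generator's noise is white across
frames and neurons; real deconvolved traces have temporal kernels, shared
(population/behavioural) variability, and non-Gaussian event statistics.
Tuning curves are unimodal Gaussians; occupancy is nearly uniform by
construction. Retinotopic scatter within a cluster is zero and images are
white noise, not natural scenes (so image autocorrelations never blur
receptive-field estimates). Recovery at these conditions demonstrates
correctness of the estimators, not their robustness to every property of
real data. One subtlety the generator does expose: neurons whose bump sits
near a corridor edge in only one corridor acquire a genuine small
selectivity from tail truncation, so the "non-selective" class has a
slightly heavy-tailed true-d′ distribution — the oracle used by the tests
accounts for it analytically.

## Problem sizes and statistics

The default test and acceptance configurations are scaled to a single CPU:
sessions of 300–2,000 neurons and 60–500 trials per stimulus; retinotopy
at 20 kernels, 13 × 13, 30 × 120 images, 1,000 neurons, 500 images × 3
repeats; alignment grids of a few hundred reference points. Group
comparisons use two-sided Student's t-tests (paired or independent),
reported raw with no multiple-comparison adjustment; summaries use s.e.m.
Every random choice is seeded; the full demo pipeline is bit-for-bit
reproducible under a fixed seed, and all pipeline outputs (TSV/JSON with
fixed float formatting, no timestamps) are deterministic.

## Known limitations

- The schematic rectangular atlas supports regional summaries but not
  anatomical registration to a real atlas.
- Simple kriging with σ = 200 μm cannot exactly interpolate maps that vary
  by pixels over tens of micrometres; alignment accuracy therefore depends
  on a dense, consistent reference map (the dense reference grid used
  here), matching its intended use with a single well-mapped reference
  session.
- The encoding-model fit assumes one kernel per neuron and integer map
  positions; sub-pixel receptive-field centres are rounded by design.
- `SI` is reported un-clipped; downstream consumers must handle
  out-of-range values explicitly.
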