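# vrcortex

Population analysis of large-scale visual-cortex recordings from mice
running through virtual-reality corridors. The package is aimed at systems
neuroscientists who have deconvolved two-photon activity traces
(neurons × timepoints), per-frame corridor position and running speed,
per-trial stimulus labels with sound-cue positions, lick/reward events and
per-neuron tissue coordinates — and who want the standard battery of
corridor-learning analyses as a tested, reusable library rather than a
notebook. A first-class synthetic-session generator with full ground truth
makes every analysis a parameter-recovery problem, so the whole chain is
verifiable end to end.

## What it computes

Each corridor trial spans positions 0–6 m: a 4 m textured zone followed by
2 m of grey. Activity samples are restricted to running timepoints
(speed > 6 cm s⁻¹ sustained ≥ 66 ms) and interpolated onto a 0.1 m position
grid where an analysis needs position profiles.

- **Selectivity (`selectivity`)** — per-neuron index
  `d′ = (μ₁ − μ₂) / ((σ₁ + σ₂)/2)` between two corridors from raw
  texture-zone samples; selection at |d′| ≥ 0.3; smoothed cortical density
  maps with NaN coverage masking; selective percentages per visual region
  (V1 / medial / lateral / anterior, schematic atlas).
- **Sequences (`sequences`)** — spatial-vs-visual coding test: select
  neurons on train trials, take each neuron's preferred position (argmax of
  the held-out odd/even tuning curves), and correlate preferred positions
  across corridors against a permutation null.
- **Coding direction (`coding`)** — normalize activity by the grey-zone
  baseline and reference-corridor s.d., build the axis from the top-5%
  selective populations, project held-out trials as the difference of
  population means (weights 1/N₊, −1/N₋, 0), and locate a probe stimulus
  with the similarity index `SI = (dx − dy)/(dx + dy)` where
  `dy = a_ref₊ − a_probe`, `dx = a_probe − a_ref₋`.
- **Reward prediction (`reward`)** — median split of rewarded-corridor
  trials by sound-cue position; `d′_late_vs_early ≥ 0.3` detects neurons
  that ramp toward expected reward and are suppressed by it; tenfold
  cross-validated population traces; cue- and first-lick-aligned averages
  (first lick after 2 m only).
- **Behaviour (`behavior`)** — anticipatory lick responses (a lick inside
  the corridor before the cue/reward-zone onset), rewarded-minus-unrewarded
  response-rate differences, first-lick distributions.
- **Retinotopy (`retinotopy`)** — convolutional encoding model
  `F_n(img) = a_n · (K ∘ img)(k_n, x_n, y_n)` fitted by EM-like
  alternation; 50-nearest-neighbour smoothed assignment; kriging
  (squared-exponential kernel, σ = 200 μm) tissue-to-retinotopy alignment
  with a ±500 μm translation grid search plus identity-regularized descent;
  visual-field sign maps and constant-sign parcellation.
- **Simulation (`simulate`)** — sessions with planted selective fractions
  calibrated analytically to a target d′, spatial/visual coding regimes,
  novelty adaptation, reward-prediction ramps, lick policies with learning
  curves, and encoding-model image responses with a planted retinotopic
  gradient and affine distortions.

## Worked example

```bash
python examples/selectivity_maps.py
```

```
planted |d'| = 0.60, recovered mean |d'| of planted neurons = 0.603
93 of 1000 neurons selective (|d'| >= 0.3)
        V1:  5.50% selective (planted 5%)
    medial: 20.40% selective (planted 20%)
   lateral:  5.50% selective (planted 5%)
  anterior:  6.00% selective (planted 5%)
density map: 18x18 bins of 100 um, peak smoothed density 0.0007 per bin
```

The generator planted a d′ = 0.6 corridor preference in 20% of medial
neurons and 5% elsewhere; the analysis recovers the effect size to the
third decimal and the regional enrichment to within binomial error. The
other scripts in `examples/` walk through sequence similarity, the
similarity-index orthogonalization sweep, reward-prediction detection,
behavioural learning curves and the full retinotopy chain the same way.

A thin CLI covers end-to-end runs: `vrcortex simulate`, `vrcortex analyze`,
`vrcortex retino`, `vrcortex report` (see `--help`). Sessions travel as a
single HDF5 container (`vrcortex.write_session` / `read_session`).

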