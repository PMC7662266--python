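# Methods

## The signal model behind the synthetic cohorts

Real smart-shoe studies of gait abnormalities rarely deposit their raw
recordings, so `shoegait.simulate` generates cohorts whose structure
matches the acquisition protocol the pipeline targets: each participant
contributes one recording per gait class — 180 s of normal walking and
60 s of each abnormal gait by default (the tests and acceptance script
use 90 s / 30 s to keep runtimes small on one CPU; this changes segment
counts, not any per-segment property).

Each foot follows a strict alternating-gait clock: stride period
T = 60/cadence, left foot offset by T/2, stance occupying a fraction
`stance_fraction` of T. Within a stance starting at heel-strike time t₀:

* **Pressure** (ADC-like units, clipped to [0, 1023]): each of the four
  sensors is a burst with 20 ms cosine attack/release ramps and a gentle
  mid-stance hump. The heel sensor rises at t₀ and releases at 0.70 of
  stance; the midfoot/forefoot sensors rise `heel_metatarsal_gap`
  seconds later; the toe sensor holds until exactly t₀ + stance, so
  whole-foot contact spans [t₀, t₀ + stance) and the exported
  heel-strike/toe-off times are exact. The forefoot amplitude is split
  between the lateral and medial sensors by `lateral_weight_share`.
  Baseline is 8 units with Gaussian noise of SD 3·noise_scale, so at the
  default noise the baseline mean + 5 SD (≈ 23) sits well below the
  contact threshold of 40, while burst peaks (300–700) sit far above it.
  The sharp 20 ms ramps keep the threshold crossing within ~3 ms of the
  true event, which is what makes the ±2-sample event-recovery check at
  100 Hz meaningful.
* **Accelerometer**: a decaying-sinusoid impact transient at each
  heel-strike (25 Hz carrier, 50 ms decay) plus stride-locked
  oscillations; **gyroscope**: a raised-cosine sagittal angular-velocity
  peak spanning the swing phase plus oscillatory components. IMU noise
  SD is 0.05·noise_scale.

Class signatures encode only qualitative directions as moderate
(15–30%) parameter deviations, all overridable:

| class | stance L/R | gap (s) | lateral share | step scale L/R |
|---|---|---|---|---|
| normal | 0.60 / 0.60 | 0.12 | 0.50 | 1.00 / 1.00 |
| unstable_left | 0.54 / 0.60 | 0.12 | 0.50 | 0.75 / 1.00 |
| unstable_right | 0.60 / 0.54 | 0.12 | 0.50 | 1.00 / 0.75 |
| supination (toe-out) | 0.60 / 0.60 | 0.05 | 0.72 | 1.00 / 1.00 |
| pronation (toe-in) | 0.60 / 0.60 | 0.16 | 0.62 | 1.00 / 1.00 |

Pronation is conventionally described as medial loading, but toe-in gait
is also widely characterised by weight shifting to the outside of the
foot; this package follows the latter convention by default (both
toe-out and toe-in shift load laterally, by different amounts and with
opposite gap changes), and `lateral_weight_share` can simply be set
below 0.5 to flip it. So that inertial-only sensor subsets can separate
toe-in from toe-out, the transverse- and frontal-plane gyroscope
amplitudes are modulated by (share − 0.5) and (0.12 − gap): early
forefoot contact and lateral loading plausibly alter foot rotation
rates, and this coupling is what stands in for it.

Participant-level random effects (pure functions of the cohort seed):
cadence uniform on 55–65 strides/min, log-normal multiplicative
amplitude (σ = 0.10) and stance-fraction (σ = 0.03) perturbations, and a
per-participant noise multiplier. These are shared across a
participant's five recordings, which is exactly what makes
leave-one-participant-out evaluation non-trivial: a held-out subject has
a cadence and amplitude the classifier never saw.

**What the simulator does not emulate** — and hence what passing tests
do not show about real data: musculoskeletal dynamics, treadmill-speed
physics, within-recording fatigue or drift, sensor crosstalk and
saturation artifacts, and the irreducible difficulty of humans mimicking
abnormal gaits. Synthetic classes are cleanly parameterised, so absolute
accuracies here are upper bounds; only the *relative* patterns (sensor
combinations, segmentation lengths, permutation nulls) are meaningful
analogues.

## Segmentation conventions

Contact is any-of-four pressure ≥ threshold (default 40). Phases shorter
than 50 ms are merged before edge extraction (debouncing; boundary
phases are left alone as they are incomplete, not noise). All intervals
are half-open `[start, end)` in 0-based samples; incomplete leading and
trailing cycles are dropped, and segments shorter than 4 samples are
discarded (variance-bearing features need ≥ 2–4 points). Stride, stance
and swing are anchored on the right foot by default (configurable).

One geometric identity is worth noting: in ideal alternating gait, left
single-limb support *is* the right foot's swing interval, so their mean
durations coincide; the documented length ordering
stride > stance > step > swing ≥ single-limb support > double-limb
support is strict everywhere except that tie.

## Numerical choices

* Kurtosis and skewness use the conventional standardized central
  moments (Std⁴ denominator, cubed deviation). A `table1_literal` flag
  reproduces dimensionally inconsistent variants (Std² denominator,
  squared deviation) that appear in some published feature tables, for
  comparison only.
* Crest factor divides max(x) by an RMS with an N−1 denominator,
  matching the standard-deviation convention; a constant positive
  segment of length N therefore yields √((N−1)/N), not 1.
* Entropy uses a 10-bin equal-width histogram over the segment's own
  range with natural logarithm; information gain uses 10 equal-width
  bins and base-2 logarithm. Both choices are fixed for reproducibility;
  neither is canonical in the field.
* Degenerate (zero-variance) segments return 0 for correlation,
  skewness, kurtosis and entropy instead of NaN, so a single flat
  window cannot poison standardization or PCA downstream.
* PCA axes are oriented so each component's largest-magnitude loading is
  positive, making scores reproducible across linear-algebra backends.
  Zero-variance features standardize to 0 via a scale fallback of 1.
* Precision of a class that received no predictions is defined as 0
  (with a warning) so weighted averages stay defined in every fold.
* Paired t-tests with zero-variance differences report p = 0.5 when the
  mean difference is 0 and are flagged degenerate otherwise.
* Confusion-matrix error rates are **column-wise**: per predicted class,
  (column sum − diagonal)/column sum as a percentage, averaged
  unweighted over classes. The shipped worked-example matrices validate
  this convention exactly.

## Design choices where the design was open

* **Fit scope of standardization/PCA**: fitting once on all data leaks
  held-out participants into the training statistics, so the default
  fits both per training fold and picks k per fold by the 99% rule;
  `ReductionConfig(n_pcs=K)` fixes k globally for component sweeps.
* **Discard rule**: the 52-feature discard is hard-coded as a family
  rule (IMU power, all zero-crossings, all maxima) so the pipeline is
  deterministic and data-independent; `discard_bottom_k` offers the
  ranking-driven mechanism for experiments.
* **Class imbalance** (normal gait has ~3× the segments) is kept, not
  rebalanced — it reflects the acquisition protocol, and the
  support-weighted metrics absorb it. One consequence: weighted recall
  over a pooled confusion matrix equals overall accuracy, an algebraic
  identity the tests assert.
* **t-test pairing unit** is the participant (fold), the only unit that
  is exchangeable across classifiers and sensor sets.
* **Sampling rate** defaults to 100 Hz and **pressure units** to an
  ADC-like 0–1023 range, chosen so the contact threshold of 40 is
  meaningful out of the box; both are configurable.

## Known limitations

* The simulator's five classes are linearly well-separated at low noise;
  it cannot reproduce the 55–90% accuracy regimes of real cohorts
  without raising `noise_scale` or shrinking signature deviations.
* Event detection is pressure-only by design; IMU-based detection is out
  of scope.
* Correlation features are within-shoe only; cross-foot correlations are
  not computed (the per-sensor pair counts — 12 pressure, 6 + 6 IMU —
  are only consistent with within-shoe pairing).
* `information_gain` is a filter statistic with finite-sample bias of
  order (bins·classes)/n bits; the tests bound it empirically at
  n = 10⁴ rather than correcting it.
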