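# Methods

`emgkin` implements a complete surface-EMG-to-joint-angle pipeline for the
lower limb: signal decomposition and denoising, time-domain feature
extraction, quaternion-based hip/knee angle computation from body-worn
inertial sensors, and a metaheuristically tuned random-forest regression
from EMG features to joint angles.  This note records the models, the
parameters that matter, the numerical choices, and what the synthetic
data generator does and does not emulate.

## Signal decomposition (EMD / CEEMDAN)

Empirical mode decomposition extracts intrinsic mode functions (IMFs) by
*sifting*: subtracting the mean of the upper and lower cubic-spline
envelopes through the local extrema until the remainder satisfies the IMF
criteria (extrema and zero-crossing counts differing by at most one,
near-zero local mean).  Choices where the method itself is silent:

- **Sifting stop rule**: Cauchy-type criterion
  `SD = Σ(h_prev − h_new)² / Σ h_prev² < 0.2`, at most 100 sift
  iterations per mode — standard EMD practice.
- **Envelopes**: natural cubic splines through the extrema, with two
  extrema mirrored beyond each end of the series to suppress the endpoint
  effect.  Plateau extrema contribute their midpoint index
  (deterministic tie-break).
- **Mode cap**: `floor(log2(n)) − 1` modes for an n-sample signal, the
  number a broadband signal can support.

CEEMDAN (complete ensemble EMD with adaptive noise) stabilises EMD on
noisy broadband signals.  Stage 1 averages the first EMD mode of
`x + ε0·std(x)·G_i` over `k` white-noise realizations `G_i`; stage `j+1`
averages the first mode of `r_j + ε_j·std(x)·E_j(G_i)`, where `E_j(G_i)`
is the j-th EMD mode of the *same* noise realization, reused across
stages.  The residual is defined as the input minus the summed modes, so
reconstruction is exact by construction.  Defaults `k = 100`,
`ε0 = 0.2` (ratio to the signal standard deviation, constant across
stages unless a schedule is given); with `ε = 0` and `k = 1` the
procedure reduces bit-for-bit to plain EMD.  The noise realizations and
their decompositions are signal-independent, so one `NoiseEnsemble` can
be shared across channels of equal length — the pipeline does this.

A property of the ensemble decomposition worth knowing: on a *clean*
narrowband signal the added noise occupies the fastest one or two scales,
so the first one or two modes are low-energy noise remnants and the
signal's fastest component appears just below them.  On broadband surface
EMG (20–450 Hz) the first modes carry signal.

## Hybrid denoiser

Raw sEMG carries powerline interference, broadband noise, sub-5 Hz
baseline drift and impulsive motion artifacts.  The denoiser decomposes
the signal with CEEMDAN and classifies every mode (and the residual):

1. mean frequency below `drift_freq_hz` (default 5 Hz) → **baseline
   drift**, dropped.  The drift rule has precedence over the correlation
   rule: a slow mode is dropped even if well correlated with the raw
   signal, since sub-5 Hz content is not muscle activity.
2. otherwise `|Pearson r|` vs the raw signal below `corr_threshold`
   (default 0.5) → **noise-dominated**, wavelet-thresholded (db5, 4
   levels, soft shrinkage).  The absolute value is used: the sign of a
   correlation says nothing about noise content.
3. otherwise → **signal**, kept untouched.

Mean frequency is the zero-crossing rate, `(crossings/2)/duration` —
cheap, deterministic and adequate for the near-monochromatic modes EMD
produces.  The "heuristic" threshold rule is the SURE/universal hybrid:
the universal threshold `σ√(2 ln n)` when the detail coefficients are
sparse, otherwise the smaller of it and the SURE-minimising threshold;
`σ` is the MAD of the finest detail level divided by 0.6745.  Denoising
quality is scored with the mean squared error against a reference.

Because IMFs are not exactly orthogonal, summing a subset of modes can
exceed the input energy by a small cross-term (observed below 1%); the
energy-non-creation check therefore carries a 2% tolerance.  A second
denoising pass removes far less than the first (median well under 25% of
the first pass's removal across seeds), but individual seeds can exceed
that fraction, so idempotence is a tendency, not an identity.

Comparators for the denoiser (plain wavelet thresholding of the raw
signal; 4th-order zero-phase Butterworth band-pass 20–450 Hz, the
classical sEMG conditioning) are provided for protocol-level comparison;
their error ordering depends on the noise mix and is not asserted.

## Time-domain features

Channels are segmented into 10 ms windows (10 samples at the 1000 Hz
sampling rate), non-overlapping by default — the hop is configurable, but
non-overlap yields one independent target per window.  Per window and
channel: RMS, variance (N−1 denominator), waveform length (sum of
absolute successive differences) and mean absolute value, in that fixed
channel-major order; six muscles give 24 columns.  Targets are the means
of the angle series over the same windows, and each window inherits the
gait-cycle id of its first sample.

## Quaternion kinematics

Frames: global G (X north, Y east, Z down), body B per segment, sensor S.
Quaternions are Hamilton convention, scalar-first; `q_S^G` rotates
sensor-frame vectors into the global frame.  During a neutral static
stance facing north, B and G coincide, so the constant mounting rotation
is the conjugate of the sensor's time-averaged orientation,
`q_B^S = (q_{S,init}^G)*`; afterwards
`q_{B,t}^G = q_{S,t}^G ⊗ q_B^S`, which is the identity at calibration.
The calibration average is the chordal mean (sign-aligned component-wise
mean, renormalised) — adequate for sub-degree spreads, and a warning is
raised if the interval's orientation spread exceeds 2°.  The calibration
interval is half-open so its endpoint cannot leak the first moving
sample.

Segment axes (thigh U, shank L, trunk W) all point distally — hip→knee,
knee→ankle, cranial→caudal — so a straight neutral stance gives both
angles zero.  The hip angle is the angle between U and W, signed by the
thigh's component along the trunk's anterior axis (mediolateral × trunk,
both taken from the waist segment's orientation): flexion positive,
extension negative.  The knee angle is the angle between U and L, which
with distally-pointing axes directly returns flexion (straight leg 0°,
never negative).  Dot products are clamped to [−1, 1] before `arccos`.
The hip pairs thigh with waist, the knee pairs thigh with shank.

## Cuckoo search

A population of `n_nests` candidate parameter vectors is refined for
`n_iterations`.  Per iteration every non-best nest takes a Lévy-flight
step and keeps it only if it improves (greedy replacement); the best nest
is retained unchanged.  A second, discovery-gated round follows: each
non-best nest whose uniform draw exceeds the discovery probability `Pa`
receives another greedy Lévy update.  (The conventional reading — the
worst `Pa` fraction abandoned and re-seeded uniformly — is available via
`abandon_convention="standard"`.)  Defaults: 20 nests, 25 iterations,
`Pa = 0.25`, step factor α = 1, Lévy exponent β = 1.5.

Lévy steps use Mantegna's generator, `s = u/|v|^(1/β)` with
`u ~ N(0, σ²)`, `v ~ N(0, 1)` and the closed-form σ(β); an exact zero of
`v` is redrawn.  The raw step is scaled by 5% of each dimension's range:
unscaled steps on integer ranges of hundreds overshoot constantly, and a
scan on the sphere benchmark showed scales of 1% and below stall before
resolving the optimum while the whole 2–10% band converges reliably, so
the default sits mid-band.  Candidates are clamped to the bounds and
integer dimensions rounded after clamping; fitness ties break toward the
lower nest index; a failing or non-finite objective marks the nest
infeasible (infinite fitness) without stopping the search.  Objective
evaluations never exceed `n_nests × (2·n_iterations + 1)`.

## Angle regression

Gait cycles are the splitting unit: whole cycles are randomly assigned
4:1 to train/test (160/40 of 200), so within-cycle correlation never
leaks across the split; the remainder after the exact ratio goes to
training.  Cuckoo search tunes `n_estimators ∈ [10, 300]` and
`max_features ∈ [1, 24]` of a random-forest regressor (scikit-learn, all
other hyperparameters at library defaults, seeded).  The fitness of a
parameter vector is the RMSE on a fixed seeded hold-out of 20% of the
*training* cycles; `max_fitness_rows` optionally subsamples the fitness
split's rows as a surrogate-fitness speed-up on large window counts.  The
best parameters are refit on the full training set.  One model is fitted
per joint, matching per-joint reporting.

Predictions are smoothed with the five-point cubic filter
(Savitzky–Golay, window 5, order 3; interior weights
(−3, 12, 17, 12, −3)/35, asymmetric five-point cubic fits at the ends),
which reproduces polynomials up to degree 3 exactly and is linear.
Metrics: RMSE, MAE, the standard coefficient of determination
`R² = 1 − Σ(p−a)²/Σ(a−ā)²` (headline), and a variant that replaces the
residual sum with the predictions' deviations from their own mean,
`1 − Σ(p−p̄)²/Σ(a−ā)²`, reported alongside for completeness.  Note the
variant scores 0, not 1, for a perfect prediction — it compares spreads,
not errors — which is why the standard form is the headline.  Constant
actuals make both undefined (reported as NaN with a flag).

## Synthetic gait generator

The generator emulates the statistical structure the pipeline assumes:

- **Angles**: periodic waveforms in cycle phase; hip a ±30° sinusoid,
  knee a non-negative double bump (small stance flexion near phase 0.15,
  large swing peak near 0.72) scaled to a 60° maximum — magnitudes
  typical of level walking.  Cycle duration 1 s, 1000 Hz sampling, 200
  cycles by default; per-cycle amplitude jitter of 5% relative standard
  deviation keeps cycles from being identical (so the cycle-wise split is
  meaningful), clipped to ±50%.
- **Poses**: the waist holds the neutral orientation; the thigh flexes by
  the hip angle about the mediolateral axis and the shank additionally by
  the (negated) knee angle — a sagittal-plane skeleton.  Each segment
  orientation is composed with a uniformly random fixed mounting
  quaternion, a 2 s static neutral interval is prepended for calibration,
  and optional small random rotations model orientation noise.
- **EMG**: each channel is a band-limited (20–450 Hz, zero-phase
  Butterworth-filtered white noise) unit-variance Gaussian carrier
  multiplied by a muscle-specific activation envelope — a circular
  Gaussian bump in cycle phase over a 0.1 baseline, phased so knee
  extensors load in early stance, plantarflexors at push-off,
  dorsiflexors in swing and hamstrings in late swing; peak amplitude
  1 mV.  Contamination defaults: 50 Hz powerline at 0.3 mV, sub-5 Hz
  drift (low-pass-filtered noise, 1 Hz bandwidth) at 0.5 mV RMS, white
  noise at 0.1 mV, and impulsive artifacts (short decaying transients,
  exponential amplitudes around 2 mV) at 0.5 events/s.

Everything is reproducible bit-for-bit from a single seed.  What the
generator does **not** emulate: motor-unit physiology (recruitment,
firing statistics, action-potential shapes), electrode-shift
non-stationarity, crosstalk between muscles, ECG contamination,
out-of-sagittal-plane kinematics, soft-tissue artifact on the sensors,
and between-subject variability.  Passing tests therefore demonstrate
that the pipeline's machinery is correct and self-consistent under the
assumed signal model — not that its accuracy numbers transfer to real
recordings.

## Problem sizes used by the tests and the acceptance script

Simulation sizes are chosen so the whole suite runs comfortably on one
CPU: decomposition checks use 512-sample mixtures with an ensemble of
k = 6; denoiser trials use two-cycle single-channel signals with k = 12;
the tuned-vs-default forest comparison uses 12-cycle feature sets with a
6-nest/6-iteration search over trees ≤ 100; and the full-protocol
end-to-end run keeps the study's data size (200 cycles, 6 channels,
1000 Hz, 4:1 split) while using k = 6 for the per-channel decomposition,
an 8-nest/10-iteration search over trees in [20, 120], and a
2000-row surrogate fitness subsample.  The paper-scale search settings
(20 nests, 25 iterations, Pa = 0.25) are exercised on the sphere
benchmark, where the objective is free.

## Known limitations

- EMD has no uniqueness guarantee; mode mixing can move content between
  adjacent modes, which the classification absorbs but does not undo.
- The correlation-based noise rule inherits the raw signal as its
  reference: when noise dominates the raw signal's variance, a clean mode
  can correlate weakly and be (harmlessly) thresholded.
- The knee angle is reported as flexion only (non-negative) by
  construction; hyperextension is not represented.
- The printed-convention abandonment step is a second greedy update
  round, so it explores less than the conventional re-seeding; use
  `abandon_convention="standard"` for harder, multimodal objectives.
- Offline processing only; no streaming/real-time path.
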