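# Methods

This note documents the models, conventions and numerical choices in
`accmet`, and what the synthetic-data generator does and does not
emulate.

## Signal processing

Raw triaxial acceleration (nominally 100 Hz, ±16 g; other uniform rates
accepted, no resampling — the corner frequencies are absolute) is
filtered per axis with a Butterworth band-pass, high-pass 0.69 Hz and
low-pass 10 Hz, 4th order, applied forward–backward (zero phase,
effective 8th order, squared magnitude response). Zero-phase filtering
preserves waveform timing, which matters because epochs are later
aligned to calorimetry minutes. Each axis is filtered **before** the
vector magnitude is taken; the reverse order is not equivalent, since
the Euclidean norm is nonlinear and would mix the gravity component
into the passband.

Edge handling: the signal is reflect-padded by `3 / high_pass_hz`
seconds (~4.3 s at defaults) before filtering — the high-pass warm-up
transient is governed by the lowest passband frequency, so padding by a
multiple of the filter order alone (a dozen samples) would be far too
short. A recording shorter than the pad length is rejected.
Independently, the first and last 2 s of a processed series are flagged
as transient; an epoch consisting *entirely* of transient samples is
dropped, while epochs merely touching the transient zone keep their
full mean (at the default 60 s epochs this only ever affects
sub-2-second edge fragments).

Intensity is the per-sample vector magnitude in mg (milli-g), averaged
over half-open epochs `[start, start + length)`; a trailing partial
epoch is dropped. Internal computation is in g; all reported
intensities are mg.

## Energy expenditure

Breath-level VO₂ (mL/min) is averaged per clock minute with an
unweighted mean over the breaths in the minute — duration-weighted
alternatives were considered and rejected: breath durations covary with
ventilation, so weighting would bias minutes containing deep recovery
breaths, and the simple mean is what a breath-table export supports
robustly. METs = VO₂ / (3.5 mL·min⁻¹·kg⁻¹ × body mass); resting
metabolic rate is the conventional 3.5 estimate, not measured.

Laboratory bouts last 4 minutes to reach VO₂ steady state. The
steady-state MET of a bout is the mean over its final window, 60 s by
default; the window is a parameter because reasonable analyses also use
the final two minutes. The matching intensity value is the mean of the
epochs fully inside that same window, so both sides of a calibration
pair describe the same interval.

## Calibration

The calibration curve is the penalized natural cubic smoothing spline
(Reinsch algorithm, banded second-derivative parametrization) minimizing

    sum_i w_i (y_i − f(x_i))² + λ ∫ f″(t)² dt .

Replicate x sites are merged to their mean with weight equal to the
replicate count, which leaves the objective unchanged. The solver is
implemented in `accmet.smoothing` rather than taken from a library: the
contract admits fits from as few as 4 distinct sites, and the
normalization of the smoothing parameter — to which published
cut-points are sensitive — must be pinned exactly. scipy's independent
penalized-spline solver is used as a cross-check oracle in the tests
(same λ, agreement to ~1e-13), never as the implementation.

**Normalized smoothing parameter.** The user-facing `p ∈ [0, 1]` maps to

    λ = ((1 − p) / p) · (span / 6)³ ,   span = max(x) − min(x),

so `p = 0` yields the weighted least-squares line exactly (special-
cased), `p = 1` the interpolating natural spline (λ = 0), and the
default `p = 0.2` a smooth curve with a handful of equivalent degrees
of freedom, growing only like n^¼ with sample size. The reference
spacing span/6 is the characteristic level spacing of a designed
calibration protocol with five to seven activity intensities. The
widely used alternative — rescaling by the cube of the *observed* mean
knot spacing — was rejected after measurement: under it a fixed p
drifts toward interpolation as data density grows, giving in-sample
R² ≈ 0.4 on entirely unrelated series at any n, so minute-level
free-living calibrations would fit noise instead of a monotone curve
(and reported association R² values below that floor would be
impossible). The span-based constant was chosen by measuring both
failure modes before freezing it: a much stiffer setting biases
genuinely concave calibration curves (3-MET cut-point off by ~20% on a
saturating truth), a much softer one raises the noise floor; (span/6)³
recovers saturating-curve cut-points to ~5% while keeping the
independent-noise R² near 0.01 at n = 500.

R² is 1 − SSE/SST on the training observations. Because a straight
line is penalty-free, the fitted spline never has larger SSE than the
least-squares line, so R² is guaranteed to land in [0, 1].

**Prediction.** Inputs outside the calibrated intensity range are
clamped to the range endpoints (with a warning) — the spline carries no
information beyond its data, and cubic extrapolation diverges. Negative
predictions are floored at 0 METs with a warning; they can only arise
from edge wiggle on noisy data.

**Cut-points.** For threshold T, the cut-point is the smallest x in the
calibrated range with f(x) = T: bracketing on a 1 mg grid, then Brent
refinement to 1e-9 mg (finer than the nominal 1e-3 mg working
precision so that the round-trip f(cut-point) = T holds to 1e-6 METs
even on steep curves). A threshold below the curve's minimum or above
its maximum is reported as undefined with a status — a calibration
with no data at an intensity defines no cut-point there, which is
exactly the free-living situation above 3 METs.

**Calibration pairs.** Laboratory: one steady-state pair per
participant × activity (per-activity means, not pooled minutes — the
protocol's point design). Free-living: pooled minute-level pairs on the
same two-minute 50%-overlap alignment used for validation, so the model
is fitted at exactly the alignment at which it is evaluated.

## Validation

Measured EE is averaged per minute; estimated EE (or intensity, for
free-living calibration) per minute t is the mean of minutes t−1 and t.
This compensates the VO₂ response lag: oxygen uptake needs tens of
seconds to follow a workload change, so the estimate must look slightly
into the past. The first minute is never paired, and a gap in the
estimate unpairs the following minute too.

Agreement: Pearson r; RMSE = √mean((est − meas)²); Bland–Altman bias
and limits of agreement at bias ± 2 SD of the differences (exactly
2, not 1.96 — the convention of the agreement plots this mirrors).
The identity rmse² = bias² + ((n−1)/n)·var(diff) is enforced by test.
Zero variance in either series leaves r undefined (NaN, with a
warning). Confidence intervals: Fisher-z for r; seeded nonparametric
bootstrap (2000 resamples) for RMSE and bias, resampling participants
for subject-mean statistics and whole participants' minutes (cluster
bootstrap) for minute-level statistics, since minutes within a
participant are not independent.

Leave-one-participant-out: N folds, fold k fits the free-living
calibration on all other participants' minutes and predicts participant
k; predictions from all folds are pooled into one statistic per
resolution (matching the single-figure-per-condition reporting
convention). Held-out minutes beyond a fold's training range are
clamped silently — expected in LOO, and warnings per fold would be
noise. A fold with fewer than 4 distinct training intensities raises an
error naming the left-out participant. On noise-free linear data the
pooled LOO error is zero *up to clamping*: a held-out extreme minute
gets the endpoint prediction, leaving residuals of order 1e-2 METs.

## Full-body workload

Nine segment sensors (shank, thigh, upper arm, forearm L/R; trunk with
head) are processed identically to the study positions, weighted by
segment mass fractions of total body mass, and summed per epoch. The
default fractions are standard anthropometry — shank 0.0465, thigh
0.100, upper arm 0.028, forearm 0.016 each; trunk+head+neck 0.578
(sum 0.959; feet and hands carry no sensor) — and are user-overridable
via a JSON table, since published segment tables differ at the second
decimal. The association of a single sensor with the full-body channel
reuses the calibration spline (full-body intensity as response) and
reports its R².

## Synthetic data generator

The generator defines the study conditions; its defaults are fixed, not
tuning knobs.

* **Laboratory mode**: five 4-minute bouts — sit, stand, slow walk,
  brisk walk, run — with nominal full-body intensities 10 / 18 / 300 /
  600 / 1500 mg, log-normally jittered per bout (σ = 0.1) and per
  participant (σ = 0.1).
* **Free-living mode**: 60 one-minute activity states drawn i.i.d.
  from sit 0.45 / stand 0.37 / slow walk 0.18 — stationary work
  dominates (~82% of minutes), and no free-living activity reaches the
  intensity of brisk laboratory walking, the regime in which
  laboratory-calibrated models are known to struggle. Workplace
  sitting/standing carries more metabolic cost per unit of lower-body
  movement than quiet lab sitting (nominal 60 / 120 mg on the
  metabolic side), and the *emitted* movement is additionally scaled by
  `free_living_intensity_scale = 0.6`: a free-living minute produces
  0.6× the movement of a laboratory minute at the same MET level, which
  is the mechanism behind the negative bias of laboratory calibrations.
* **Ground truth**: MET = g(intensity) with the saturating default
  g(x) = 1 + a·x/(1 + x/b), a = 0.009 MET/mg, b = 2000 mg (concave,
  levelling at 19 METs — the empirical calibration shape); a linear
  option (slope 0.004 MET/mg) is retained for analytic tests.
* **Raw signals**: gravity as a unit vector with slow sway (0.02 Hz,
  far below the high-pass corner) plus axis-weighted white noise;
  locomotor blocks add a stride harmonic (1.6–2.7 Hz fundamental plus
  first overtone). Each block is rescaled so that its band-pass
  vector-magnitude mean equals the target intensity — the generator
  controls the *measured* intensity by construction, so recovery tests
  exercise the epoch machinery, spline fit, inversion and alignment
  rather than an arbitrary gain constant.
* **Positions**: per-position gains scale movement amplitude
  (shoe 2.0 > thigh 1.3 > hip 1.0 ≈ wrist 0.9; impacts grow toward the
  ground), with analogous gains for the nine segment sensors. The wrist
  additionally receives movement during stationary blocks (half-normal
  target, σ = 40 mg) that is independent of EE — the "decoupling" that
  degrades wrist-based estimation during deskwork (in the laboratory
  protocol this emulates the Sudoku task given during sit/stand bouts).
* **VO₂**: body_mass × 3.5 × g(intensity), passed through a first-order
  lag (τ = 30 s, giving within-bout steady state well before minute 4),
  sampled at a participant-specific Poisson breath rate (15–30/min) with
  Gaussian noise of 0.3 MET per breath.
* **Determinism**: every purpose (schedule, traits, breaths, each
  position) draws from its own seed-sequence stream keyed by
  (seed, participant, stream), so identical inputs are bit-identical
  and restricting the generated positions does not perturb anything
  else.

What passing tests on this generator do **not** show: robustness to
real gait waveforms, device miscalibration, non-wear, posture-dependent
orientation, or metabolic heterogeneity beyond a body-mass draw. The
generator validates the statistics, not the biomechanics.

## Problem sizes

The test suite runs laboratory cohorts of 5–30 participants and
free-living cohorts of 6–10; the stochastic recovery check uses 100
replicate cohorts of n = 30 (laboratory, hip) and 100 replicate
free-living cohorts of n = 6. The acceptance script uses the study's
own sizes: 34 laboratory and 15 free-living participants with all 13
sensor streams, plus 100 recovery replicates. These sizes give
sampling noise well below the tolerances being checked while keeping a
full run in minutes on one CPU.
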