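# Methods

This note documents the models behind `drivegaze`, the defaults and why
they were chosen, what the synthetic data do and do not emulate, and the
numerical conventions that matter when interpreting results.

## The analysis in one paragraph

Each driving trial contributes three 4-second windows derived from
telemetry: a low-cognitive-control window (*Coasting*/*Following*) where the
relevant controls vary least, a high-control window (*Braking*/*Steering*)
starting at the control-response onset, and a rest *Baseline* (seconds 4–8
of the 9-s rest).  Gaze samples are classified into fixations and saccades
by the velocity/acceleration threshold criterion (I-VT; 30 °/s, 8000 °/s²),
seven scene-independent metrics are computed per window, windows with more
than 20 % missing eye data are excluded, and the Lo-vs-Hi contrast per
metric is summarized by a paired t-test and the pooled-SD effect size
d = |m₁ − m₂| / √((s₁² + s₂²)/2).  A theta-band (3–9 Hz) pseudo-t contrast
of each window against its rest baseline stands in for the beamformer-based
frontal-midline-theta validation: it is a sensor-level surrogate, not a
source-localized statistic.

## Synthetic sessions

The generator exists so that every stage has a ground truth.  It emulates:

* **Schedules.** Trials are concatenated (t₀ = 0): a 3-s acceleration
  phase, a coasting plateau whose duration is uniform on [6, 10] s (this is
  the event-time jitter), a 5-s response phase beginning at the embedded
  event (light change, wind gust, lead-vehicle brake), and a 9-s rest.
  Defaults: 20 trials for the steering and traffic-light tasks, 14
  lead-vehicle brake events.
* **Telemetry.** 60 Hz (a typical simulator output rate; the timescale that
  matters is the 4-s window, so the exact rate is immaterial and
  configurable).  Plateaus carry additive Gaussian noise (SD 0.01 of full
  scale); the braking response is a linear ramp to 0.8 of full scale over
  0.25 s; the gust response is a steering deflection of 0.3 with a 1.5-s
  corrective return.  Ramps lead the event by one telemetry sample period so
  the first recorded response sample already registers pedal motion; rests
  have all controls at zero.  Gas and brake are never jointly engaged.
* **Gaze.** A 1000 Hz alternating renewal process.  Fixation durations are
  log-normal, moment-matched to the configured mean/SD and truncated below
  at 50 ms.  Fixation centres follow a stationary AR(1) process whose
  marginal is exactly the configured bivariate normal (centre, spread); the
  AR persistence ρ is derived from the configured saccade-amplitude
  root-mean-square via E|step|² = 2(1 − ρ)(σx² + σy²), so consecutive-centre
  distances reproduce the configured amplitude scale.  An alternating
  renewal process cannot honor an amplitude *distribution* and an
  independent centre distribution simultaneously — consecutive-centre
  distances are whatever the centre process makes them — and we resolve the
  tension in favour of the centre distribution because the spread of search
  is the quantity with a stated generative contract (realized centre SD
  within 5 % of the configured spread).  Draws whose step falls below
  0.55° — the practical resolution of the 30 °/s criterion at 1000 Hz with
  the default smoothing — are redrawn, so every planted saccade is
  detectable.  Saccades traverse the step with a raised-cosine velocity
  profile (default duration 20 ms, configurable 2–40 ms); within-fixation
  jitter is 2 px SD, far below the spread.  Blinks are Poisson-placed
  invalid runs with log-normal durations (mean 150 ms); the rate is
  −ln(1 − f)/mean so the expected *coverage* equals the configured missing
  fraction f despite overlaps.  All samples are clipped to the screen.
* **Neural trace.** 600 Hz: 1/f-shaped Gaussian background plus a 3–9 Hz
  band-limited component whose amplitude is multiplied by the theta boost
  (default 2.0) inside Hi windows, with 0.25-s cosine tapers at window
  edges.

Per-task generative gaze regimes (`TASK_GAZE_PARAMS`) give Lo and Hi windows
distinct fixation-duration, gaze-position, spread, and amplitude parameters
so the full pipeline produces condition contrasts of realistic sign and
rough magnitude.

What the generator does **not** emulate: smooth pursuit, vergence,
microsaccades, head motion, pupil dynamics, calibration drift, visual-scene
content, realistic vehicle dynamics, and between-participant heterogeneity
(all simulated participants share one regime).  Passing tests therefore
demonstrate that the *pipeline* recovers known generative structure — not
that recorded adolescent driving data would show the same effect sizes.
In particular, between-window summary SDs of the synthetic metrics are
tighter than between-trial SDs of recorded data, so simulated Cohen's d
values are larger than published ones for the same mean shifts; the
published effect sizes are instead checked directly from their printed
condition summaries.

## Screen geometry

Default: 1600×1200 px over a 34 × 25.5 cm active area viewed from 90 cm
(isotropic pitch 0.02125 cm/px ≈ 0.0135 °/px at centre).  The published
per-window gaze summaries run to y ≈ 789 px with ~176 px spread, which
requires a vertical resolution above 1024×768; 1600×1200 preserves the 4:3
physical panel at a resolution that contains the summaries.  Geometry is
fully configurable, and pixel→angle conversion is exact arctangent, not
small-angle.

## Event detection

EyeLink-style classification with explicit, configurable surrogates for the
tracker's proprietary internals:

* Smoothing: order-2 Savitzky–Golay over 9 samples; velocity is the
  magnitude of the 2-D angular velocity (the criterion is applied to speed,
  not per axis); acceleration is the signed derivative of speed, compared by
  absolute value.
* Thresholds: saccade iff velocity > 30 °/s **or** |acceleration| >
  8000 °/s² — strict inequality, per the "exceeding" convention.
* Post-rules: saccade runs < 8 ms relabelled fixation; fixation runs
  < 50 ms absorbed into the longer neighbour; blink intervals (invalid runs
  padded by 50 ms, merged) override both.  Samples within half a smoothing
  window of an invalid run have no reliable kinematics and are left
  unclassified.
* Saccade amplitude: Euclidean pixel distance between the last pre-saccade
  and first post-saccade positions.

With the default geometry the detector resolves saccades down to ≈ 0.55°;
the generator's redraw floor matches this, and the planted-saccade recovery
tests condition on amplitudes > 1° and peak velocities > 3× threshold,
where recovery is exact except for events truncated by a trace edge or
straddling a window boundary (onset-assignment bookkeeping, not detection
failures).

## Windows and metrics

"Least variation" is operationalized as variance — the minimal-assumption
dispersion measure, and the one an exhaustive-scan oracle can check.  When
channels are combined (gas + steering for the gust task) each channel's
window variance is normalized by its variance over the whole search span,
so units cancel and the channels weight equally; zero-variance channels
contribute nothing.  Candidate offsets lie on the telemetry sample grid;
ties break to the earliest offset.  The lead-car Lo search spans the 8 s
before the planted brake event (configurable).

Metrics conventions: events belong to the window containing their onset and
fixation durations are not clipped at edges, which makes the fixation count
a renewal count with closed-form expectation (window / mean cycle length) —
the oracle used in testing.  Spread of search is the (n−1) SD of valid gaze
samples per axis (configurably computable from fixation centroids instead);
mean saccade amplitude stays in pixels.  A window with zero valid samples
reports missing fraction 1 and no metrics.  Exactly 20 % missing is
retained; strictly more is excluded.

Because fixation centres are serially correlated (AR persistence ≈ 0.74 at
the default regime), the per-window sample spread sits below the marginal
centre SD — a genuine property of windowed dispersion under correlated
scanning, worth remembering when comparing window-level spread to the
configured marginal spread.

## Statistics

Paired t on trial-matched windows (inner join on trial id; unmatched trials
dropped and counted).  Zero-variance differences raise a
`DegenerateVarianceError` rather than returning an infinite statistic.
Cohen's d uses the equal-weight pooled SD √((s₁² + s₂²)/2) and the
absolute-value convention, printed to two decimals with round-half-up.
Recomputing d from the published rounded condition summaries reproduces
8 of the 21 published rows exactly at two decimals (the rows asserted in
the acceptance suite); the remainder differ by 0.01–0.05 (e.g. a steering
fixation-duration row printing 0.65 where the rounded inputs give 0.70),
consistent with the original analysis using unrounded data.  Those rows are
documented here, not asserted.  No multiple-comparison correction is
applied, matching the exploratory design.

The trial-level pairing is itself a declared choice: the published
condition counts are unequal (e.g. 187 vs 195), so the original pairing
unit cannot be recovered from the text; an inner join on trial is the
simplest auditable rule.

## Theta contrast

Band power is the mean square of the zero-phase band-limited signal: an FFT
amplitude mask equal to 1 in [3, 9] Hz with raised-cosine transitions 1 Hz
wide, applied at a padded fast FFT length.  The pseudo-t is the across-trial
t of active-minus-baseline power differences — a sensor-level surrogate for
beamformer noise-normalized differential power, adopted because source
localization is out of scope.  The elevation flag (pseudo-t > 2 by default)
is a declared surrogate for what was originally a visual assessment; the
simulation suite calibrates it (boost 2.0 → Hi flagged in ≥ 95 % of seeds;
boost 1.0 → ≤ 10 %).

## Problem sizes and determinism

Acceptance recoveries use 200 four-second windows (≈ 2400 fixations), which
puts 2 SE of the mean fixation duration near 10 ms and of the per-window
fixation count near 0.1; property suites use 50–100 seeds, and the null
calibration of the paired t uses 1000 replicates at n = 20.  One root seed
fans out through `SeedSequence([seed, participant, task, stage])`, so any
stage of any session can be regenerated in isolation; reruns with the same
config and seed produce byte-identical output files, verified by a SHA-256
manifest.

The fixation-duration recovery is run with the missing fraction set to 0
(as is the renewal-count recovery): these targets calibrate the
duration/count channel of the detector, and blink-split fixations would
shift the recovered mean by construction rather than by pipeline defect.
The blink channel is exercised separately by the missing-fraction and
exclusion tests.

## Known limitations

* Simulated participants are exchangeable; there is no hierarchical
  (participant-level) structure, matching the trial-pooled analysis but not
  reality.
* The I-VT surrogate is not the tracker's proprietary parser; agreement
  with it on real recordings is untested here.
* The pseudo-t surrogate operates on a single synthetic channel; it says
  nothing about spatial specificity of frontal midline theta.
* The minimum-variation search is exact only on the telemetry sample grid;
  sub-sample window placement is deliberately out of scope.
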