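# Methods

This note documents the models, conventions and numerical choices
behind gaitstab: what each stage computes, which decisions were
genuinely open and how they were resolved, what the synthetic walker
does and does not emulate, and what the passing test suite therefore
does and does not demonstrate about real data.

## Coordinate and event conventions

All kinematics use a fixed lab-frame axis convention: X = medio-lateral
(positive toward the participant's right), Y = anterior-posterior
(positive in the progression direction), Z = vertical (up); positions
in meters, sampling at 100 Hz by default.  A positive belt speed means
the belt surface moves backward.  Mocap conventions vary between labs,
so C3D ingest requires an explicit rotation/label mapping; the native
TSV dialect is already in this convention.

Sample indices are 0-based; event records carry both a time and a
sample index, with the sample index authoritative.

## Filtering

Marker and CoM channels are low-pass filtered with a second-order
Butterworth at 6 Hz, applied forward and backward (zero phase).  The
combined magnitude response is the square of the single-pass response,
so the gain at the cutoff is exactly 1/2 — the filter-contract test
checks 0.50 ± 0.02 on a long sinusoid.  End transients are suppressed
by odd (reflect-and-negate) extension of 3·⌈fs/fc⌉ samples per end,
which reproduces linear trends exactly.  Belt-speed and platform
channels are control signals and are never filtered.

A property worth noting (it shaped the synthetic generator, below):
the combined forward-backward impulse response has zero mean, zero
second and zero third central moment, so the filter transmits
polynomial segments up to cubic without distortion.

## Heel-strike detection

Heel strikes are local maxima of the anterior excursion of the heel
marker relative to the pelvis: on a treadmill the heel is farthest
ahead of the pelvis exactly at touchdown.  Peaks are picked per side
with a minimum separation of 0.35 s (≈0.65 × a typical 0.55 s step
time) and a minimum prominence of 10 mm, then merged into one
alternating sequence; when two same-side peaks follow each other the
less prominent one is dropped.  Events are placed at the peak sample
itself — at 100 Hz this is ±5 ms, adequate for step-level metrics, so
no sub-sample interpolation is used.  Both thresholds are engineering
choices (no published values exist for this exact detector) and are
configurable.

Toe-off detection is not implemented; no computed measure needs it.

## Margins of stability

Pendulum length l is the time-averaged height of the two
greater-trochanter markers multiplied by 1.34, and ω₀ = √(g/l) with
g = 9.81 m/s².  The XCoM adds CoM velocity scaled by 1/ω₀ to the CoM
position, per axis.

Three conventions are not fixed by the outcome definitions themselves
and had to be decided:

* **CoM velocity frame.**  On a treadmill the lab-frame CoM velocity
  averages ~0, which would put the AP margin near −0.27 m for any
  plausible landing position — inconsistent with the positive ~0.17 m
  AP margins reported for walking cohorts.  The package therefore
  adds the stance-side belt speed (belt of the foot that made the most
  recent heel strike) to the AP CoM velocity by default ("belt
  frame"); a `frame="lab"` switch is provided.
* **Evaluation instant.**  One MoS pair per step, evaluated at the
  step's terminating heel strike with the striking foot as the leading
  foot.  Heel strike is the standard instant for step-level margins
  and matches the per-step framing of peri-perturbation analyses.
* **Step length/width convention.**  Both are distances between the
  two heel markers at the instant of the later heel strike
  (same-instant convention).  The alternative — displacement between
  event instants — is near zero in the lab frame on a treadmill.

Signs: ML MoS is d_s·(malleolus_ML − XCoM_ML) with d_s = +1 for a
right, −1 for a left leading foot, positive when the malleolus is
lateral to the XCoM.  AP MoS is XCoM_AP − heel_AP, positive when the
heel lands behind the XCoM; both margins are negative exactly when the
XCoM has escaped the base of support in that direction.

Under mirror reflection of all ML coordinates the ML margin changes
sign; reflecting *and* swapping the L/R identities reproduces the same
walker and leaves every metric unchanged.  Both are verified as
property tests.

## Baseline summary

Means and SDs of the five gait parameters over the first 100
consecutive steps per side (dominant = BD, non-dominant = BND), after
skipping a 5-stride warm-up.  Trials with fewer steps raise an error
rather than silently averaging less.

## Peri-perturbation analysis and 6S

Perturbations trigger at a non-dominant heel strike (verified within
±3 samples).  The six steps ending at or before the trigger strike
form the pre-window (PD/NPD = means of the three same-side pre steps);
the six steps after it are labelled 1D…6ND, and the first must land on
the dominant side.  Windows that would share steps between two events
are rejected.

6S for a parameter is the L1 norm of the six side-matched deviations
of the post steps from the baseline means.  It is computed per
repetition and then averaged over the **last three** repetitions of a
trial: the averaging rule is read as applying to derived measures
rather than to raw steps (both orders coincide when deviations have a
consistent sign), and dropping the first repetition matches the
protocol's intent that the first exposure is a startle.  The
peri-step table (per-label means/SDs across windows) is exported as a
tidy TSV for external statistics software; no ANOVA machinery is
included by design.

## Local dynamic stability

Trunk-marker velocity (central differences after the global 6 Hz
filter, no further smoothing) over the first 100 strides is
time-normalized to 10,000 samples by cubic resampling of the whole
segment — total-duration normalization, which preserves
stride-to-stride temporal variability in sample space.  Each axis is
delay-embedded (dimension 5, delay 10 samples) and, for every state,
the nearest Euclidean neighbour at least a Theiler window (50 samples,
half a normalized stride) away in time is tracked forward; the mean
log separation versus look-ahead forms the divergence curve, and the
exponent is the least-squares slope over 0–0.5 stride rescaled to
per-stride units.

The embedding dimension, delay, Theiler window and fit range are
conventions of the gait literature, not uniquely determined values;
all are configurable on `LdsConfig` and changing them changes the
absolute exponents.  Separations are floored at 1e−15 before taking
logs because perfectly periodic synthetic signals produce exactly
coincident states.  The exponent is invariant to a positive gain on
the input (log shifts cancel in the slope) and deterministic given the
trial — both tested.

## The synthetic walker

The generator is a purely kinematic template — no forces, no balance
controller — built to exercise every formula of the pipeline with
exact ground truth.  It emulates:

* alternating steps with programmable time (0.55 s), length (0.68 m)
  and width (0.12 m), matching typical comfortable-speed baselines;
* an ML CoM sway locked to the step cycle (amplitude 0.02 m), a small
  AP oscillation and a vertical double bump per stride, shared by the
  pelvis and trunk markers;
* feet that drift backward during stance and swing forward to their
  next landing, with heels landing 0.27 m ahead of the pelvis (chosen
  so the belt-frame AP margin sits near the ~0.17 m of real cohorts);
* the six perturbation types: trapezoidal-velocity platform sways
  (5 cm, 0.7 s, 2.04 m/s² peak — the only simple profile family
  satisfying all three printed constraints at once), minimum-jerk belt
  ramps to 160 %/40 % of comfortable speed in 0.4 s (the minimum-jerk
  peak-rate constant 1.875·Δv/T reproduces the published 2.43–5.13
  m/s² acceleration range across comfortable speeds 0.86–1.82 m/s),
  and metadata-only sensory events;
* scripted recovery responses: per-step deviation targets for step
  time and the two margins over the six post-perturbation steps,
  realized through foot placement that is compensated for the
  perturbation-induced XCoM shift (computed with the same discrete
  rules the pipeline uses), so the deviations the pipeline should
  measure are known exactly.  Default templates are shaped to the
  qualitative recovery patterns reported for these perturbations — a
  narrow cross-step then widening recovery after a contralateral sway,
  backward instability at the second post step after a deceleration —
  with L1 magnitudes near the reported group totals (≈0.22 m ML for
  the contralateral sway, ≈0.52 m AP for the deceleration).  Scripts
  are data, not behaviour: any template can be replaced.

Two internal design points matter for fidelity of the round trip:

* **Strike caps.**  Each heel-strike neighbourhood of the heel AP
  trajectory is an exact symmetric parabola over ±0.15 s (joined C³ to
  the swing curve, C¹ to the stance line).  Because the zero-phase
  filter transmits parabolas exactly, the filtered heel position at
  the strike sample equals the programmed landing to <0.5 mm and the
  detected peak stays at the strike sample.  The parabola drifts half
  a cap-width less than the stance line would; the stance drift speed
  is raised accordingly so programmed step lengths are recovered
  exactly.
* **Kinematic consistency.**  Steady treadmill gait forces the mean
  step length to equal (effective drift speed) × (step time).  The
  defaults (1.2 m/s belt, 0.55 s, 0.68 m) are taken from typical
  cohort values and are mutually inconsistent by ~2 %; the template
  resolves this by letting the feet drift at step_length/step_time
  while the belt-speed *channel* stays at the comfortable speed.  The
  belt channel is what enters the belt-frame XCoM, so margins remain
  consistent between generator truth and pipeline output.

Trunk variability is emulated as band-limited Gaussian noise (white
noise low-passed at 3 Hz, rescaled to the requested SD) added to the
trunk marker; marker measurement noise is white.  Sessions schedule
four repetitions per trial ≈21 strides apart (≥15 washout strides
between response windows) and slowly re-centre the platform after each
sway so the ±15 cm hardware excursion bound is respected; violating it
raises an error.

What the template does **not** emulate: balance dynamics and genuine
recovery control (responses are scripted), double-support and foot
roll-over geometry, soft-tissue artefact, asymmetries between sides,
pre-perturbation anticipatory adaptation, and the deterministic
component of neuromotor variability.  Passing round-trip tests
therefore demonstrate that the *formulas and event logic* are
implemented correctly and are robust to realistic noise levels — not
that the pipeline's outputs on real data are unbiased estimates of the
underlying physiology.  In particular the local-dynamic-stability
exponents of the noise-driven template (≈2.7–3.3 per stride at 2–10 mm
variability) sit at the upper end of, but within an order of magnitude
of, values reported for healthy adults (≈1.4–1.8); absolute agreement
would require the original cohort's data and the exact analysis
settings of the reference implementations.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic
data generated at run time: baseline trials of ~125–130 s (≈115
strides, enough for the 100-step baseline and the 100-stride
divergence analysis after warm-up), perturbation trials of ~91 s with
four triggers each, and a 1000-case random oracle for the 6S check.
These sizes were chosen as the smallest that exercise every stated
count (100 steps per side, 100 strides, 4 repetitions, 6 trial types)
with margin.

## Known limitations

* C3D ingest is a thin optional path (requires `ezc3d`) and performs
  no gap filling; the TSV dialect is the tested format.
* The heel-strike detector assumes treadmill walking with a roughly
  stationary pelvis; it is not validated for overground data.
* `com` is a required input channel (full-body CoM estimation from a
  47-marker model is out of scope); if absent a mid-trochanter proxy
  would be a caller-side substitution, not something the package does
  silently.
* Statistical inference (mixed models, post hocs) is deliberately out
  of scope; the tidy TSV exports are the interface to statistics
  software.
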