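# Methods

## Model

The chest wall is a two-compartment lumped-parameter system: the rib
cage and the abdomen, separated by the diaphragm, each a first-order
resistance–compliance element, coupled to the lung through the pleural
cavity. The abdomen is treated as incompressible and bounded except at
the ventral wall and diaphragm, so inward ventral-wall motion displaces
an equal diaphragmatic volume; diaphragm displacement is that volume
over the body cross-sectional area `A_di` (approximately weight over
height, m²), with explicit L→m³ and m→cm conversions. The model is
linear: superposition holds exactly, which the tests exploit.

Default mechanical constants (healthy adult): `R_rc = R_ab = 1`,
`R_l = 2` cmH2O/(L·s); `C_rc = C_l = 0.2`, `C_pl = 0.25`, `C_ab = 0.4`
L/cmH2O; `A_di = 0.08` m². The corresponding time constants are
0.08–0.4 s.

### Sign conventions

Volumes are deviations from the end-expiratory (functional residual
capacity) baseline. Positive `V_ab` means caudal diaphragm displacement
(abdominal wall outward). The robot compresses the abdomen during
expiration and pushes the diaphragm cranially, so robotic assistance is
a *negative-signed* `P_rex` trace during the expiratory window while the
abdominal driving pressure keeps its additive form
`P_ab = P_dimus + P_rex`. Direction lives in the waveform sign; the
compartment algebra is unchanged.

### Integration

Classical fixed-step 4th-order Runge–Kutta with drives interpolated
linearly between grid points; the step divides the drive grid step
evenly and defaults to 1 ms. The system is linear and stiff-free at the
default time constants, so RK4 at 1 ms matches the closed-form
first-order step response to ~1e-13 L, and even at a 20 ms step (one
step per sample of a 50 Hz recording, used in fitting and session
generation for speed) the relative error is ~1e-5 — far below
measurement noise. Fixed-step integration gives bit-stable, reproducible
trajectories; adaptive steppers would not.

## Drive waveforms

Muscle pressures are half-rectified sines over the inspiratory window
(fraction `f_insp`, default 0.5, of the breath period `T`, default 6 s);
amplitude, rectification and phase are package choices exposed as
configuration — only the trigonometric form is prescribed. The robot
inflates during expiration (default 3 s) with a unit square, symmetric
triangle, or half-sine profile at a set actuator pressure (kPa). The
actuator pressure scale (30–50 kPa) and the effective abdominal pressure
scale (cmH2O) are reconciled by an explicit transmission gain
`k_transmission` (default 0.1 cmH2O/kPa, so 30 kPa ⇒ 3 cmH2O — the
reference effective robotic pressure). This gain is a documented free
constant, not a physical prediction. Because cohort subjects draw breath
periods from the typical 3–6 s adult range, the robot program is
synchronized per subject: the inflation is clipped to the subject's
expiratory window.

The Yoshimura origami helper solves the closure condition
`tan γ · cos(θ/2) = tan(π/M)` for the pre-fold angle θ; the reference
actuator geometry (γ = 60°, M = 4) gives θ ≈ 109.47°.

## Pneumatic control

The controller is the classic supply/exhaust dead band: below
target − threshold the supply valve opens, above target + threshold the
exhaust valve opens, inside the band both close (valves are never open
together, by construction of the command type). The plant — not
prescribed anywhere, so invented here — is a single first-order chamber
with separate fill and vent time constants (0.25 s / 0.35 s, supply
100 kPa), integrated exactly between control evaluations (100 Hz).
These defaults place the simulated full-scale 0→50 kPa step inside the
envelope expected of the hardware class (settling well under 0.75 s,
negligible overshoot); this is a plausibility envelope of the simulated
loop, not a hardware reproduction. Rise/settling times use the
±10%-of-target band; "rise" is read as first entry into that band,
consistent with the settling definition.

## Synthetic data

A participant is the reference mechanics times independent unit-mean
lognormal factors (default coefficient of variation 0.2 — enough to make
cohort waveforms visibly heterogeneous while keeping parameters
positive), plus a breath period uniform on 3–6 s. A session samples
displacement (ultrasound surrogate) and flow (spirometer surrogate) on
one shared grid (default 50 Hz); flow is the first difference of lung
volume, so its cumulative integral telescopes exactly to the volume
trace. Measurement noise is additive zero-mean Gaussian per channel
(defaults 0.05 cm and 0.02 L/s; no noise characteristics are published,
these are plausible instrument scales). Everything is a pure function of
(inputs, seed).

What the generator does **not** emulate: ultrasound speckle,
attenuation, probe geometry, cardiac artifacts, breath-to-breath
variability of muscle drive, or flow-sensor drift. Passing tests
therefore demonstrate the correctness and self-consistency of the
processing chain, not performance on clinical recordings.

### Calibration

Muscle amplitudes are unobservable and unpublished, so they are
calibrated: the diaphragm amplitude comes directly from the excursion
target through the linear abdominal gain, then the rib-cage amplitude is
found by a bracketed root search on the measured mean tidal volume
(targets default to a typical subject's quiet breathing: 1.14 cm,
0.83 L). For sampled cohort subjects the targets can be infeasible (a
compliance draw can make the diaphragm-only tidal volume exceed the
target); the pipeline then clamps the rib-cage amplitude to the nearest
attainable value rather than failing.

The assisted condition is calibrated with two decoupled knobs: the
robot's effective pressure sets the assisted/spontaneous excursion fold
change (excursion depends only on the abdominal channel), then the
assisted rib-cage amplitude sets the tidal-volume fold change (defaults
1.95× and 2.14×, the cohort-average targets). These are explicit
calibration constructs standing in for unavailable raw recordings, not
model predictions. The two single-subject assisted reference values
(4.02× excursion with only 2.45× volume) are jointly unattainable in
this model — matching the excursion ratio already over-doubles the
volume — so single-subject assisted calibration uses the excursion knob
alone.

### M-mode images

One image column per time sample; the diaphragm is a Gaussian bright
band (FWHM 0.4 cm, level 220 on background 30) centered at the depth
mapped from the displacement (toward the probe = shallower; row 0
shallowest). Default geometry: 6 cm depth over 256 rows (0.23 mm/pixel).
The tracer smooths each column with a 3-pixel moving average, takes the
argmax refined by a three-point parabolic vertex (sub-pixel, invariant
to uniform intensity offsets), enforces continuity with a 5-column
median filter (nearest-edge padding), and interpolates contrast-free
columns from neighbours, counting them against the quality fraction.

## Measurement chain

Breath cycles are segmented from flow by negative-to-positive zero
crossings with a hysteresis band of ±2% of peak magnitude, plus a
refractory interval of half the nominal period (the band alone is
narrower than the default flow noise); displacement cycles start at
local minima of a lightly smoothed copy, separated by at least half the
nominal period. Tidal volume is the trapezoidal integral of inspiratory
(positive) flow per cycle; excursion is the per-cycle peak-to-trough
displacement. Cycle-shape comparisons resample each cycle to 20 points
of normalized phase and average 3 consecutive cycles.

Session-level summaries first low-pass both channels (Gaussian, 0.15 s).
Peak-to-trough statistics on raw noisy samples carry an extreme-value
bias (about +0.25 cm at the default noise and rate), which would distort
fold changes and fit scores; the smoothing is part of the measurement
procedure and is applied identically during calibration, cohort
analysis, and fit scoring, so calibration absorbs the (percent-level)
signal distortion it introduces.

NRMSE is RMSE over the observed peak-to-peak range (no normalization
convention is standard; range is the one used throughout), in percent.
The paired spontaneous-vs-assisted comparison uses the exact two-sided
Wilcoxon signed-rank test (no normality assumption at n = 8); both
mean(assisted)/mean(spontaneous) and the mean of per-subject ratios are
reported, the former as the default, since either convention is
defensible for a cohort fold change.

## Fitting

Bounded trust-region least squares on the concatenated residuals of the
displacement trace and the flow-integrated volume trace, each normalized
by its observed peak-to-peak range (units cannot dominate), after
cycle alignment by the cross-correlation lag of the displacement
channel. The simulated volume channel is routed through the same
measurement operations as the recording (volume → first-difference flow
→ trapezoidal integral), so on noiseless self-generated data the
generating parameters are an exact global optimum and recovery is exact
to optimizer tolerance. Multi-starts (bound-box center plus seeded
uniform draws; 5 by default, 2 in the pipeline where the amplitude
problem is effectively convex) make the result deterministic given the
seed. Free parameters: muscle amplitudes, effective robot pressure
magnitude, and compartment compliances; which to free per session is a
user choice (the pipeline frees amplitudes, plus the robot pressure for
assisted sessions, with mechanics fixed).

The recovery experiment samples truth (mechanics around the reference
values, amplitudes uniform over realistic ranges), generates 10-breath
sessions at chosen noise levels (relative to each channel's range), fits,
and reports per-parameter bias, RMSE, and median absolute relative
error over seeded replicates.

## Problem sizes and numerical choices

Default sessions are 6 breaths at 50 Hz (10 breaths for recovery
studies); cohorts are 8 subjects; recovery uses 20 replicates per noise
level; integration is RK4 at the sampling step for session work and
1 ms for oracle comparisons. These sizes were chosen to keep the full
test suite and the acceptance script fast on a single CPU while leaving
wide margins on every property. Root searches use Brent's method with
1e-8 absolute tolerance; ties in the M-mode argmax resolve to the first
row and are then refined sub-pixel; degenerate inputs (constant traces,
flat observations, zero-variance correlations, identical Wilcoxon pairs)
raise explicit errors or return the exact null value as documented per
function.

## Known limitations

- The model is linear; real chest-wall mechanics are not (no posture or
  gravity terms, no gas compressibility, atmospheric airway boundary).
- The actuator-to-abdomen transmission gain is a free constant; absolute
  robotic-pressure predictions are only as good as its calibration.
- The pneumatic plant is a stylized first-order chamber without sensor
  noise or valve latency; its metrics characterize the simulation.
- The M-mode tracer is built for the package's synthetic images; no
  performance guarantees on clinical ultrasound are implied.
- Cohort fold changes are calibrated, not predicted; the pipeline
  demonstrates that the measurement and estimation chain recovers what
  was put in, under the stated noise model.
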