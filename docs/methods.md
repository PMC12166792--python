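# Methods

## The stabilization scheme

`nanolock` implements image-based active stabilization of a microscope
sample in all three axes.  A dedicated widefield camera images a static
reference structure in the sample (holey carbon film, immobilized beads, or
a calibration tile target).  At engagement the software stores a *setpoint
frame*, then steps the piezo stage over a small symmetric range per axis
(default ±100 nm in 20 nm steps, 11 planes) and records a *reference stack*:
raw normalized frames for x and y, sorted pixel-intensity profiles for z.
During the feedback loop each camera frame is matched against every plane of
each stack:

- **Lateral (x, y):** the match statistic is the unshifted cross-correlation
  CC(a, b) = Σᵢⱼ aᵢⱼ bᵢⱼ between the normalized current frame and each
  stack frame.
- **Axial (z):** the frame is flattened and sorted; the statistic is the
  mean squared error MSE(a, b) = (1/n) Σᵢ (aᵢ − bᵢ)² between sorted
  profiles.  The shape of the intensity histogram changes smoothly with
  defocus, so its distance to the recorded profiles encodes z without
  astigmatic optics; sorting makes the readout independent of lateral
  position and of any spatial permutation of the pixels.

The per-plane values are scaled to [0, 1] (after multiplying the MSE curve
by −1 so its minimum becomes a peak) and a four-parameter Gaussian
A·exp(−(u−µ)²/(2w²)) + c is fitted over the full curve; the fractional
center index µ times the stack step is the displacement in nanometers.  The
four-parameter form (rather than a bare three-parameter Gaussian) absorbs
the nonzero baseline that min–max scaling leaves under the peak.

Frames are intensity-normalized (each pixel divided by the pixel sum) before
any comparison; for z this happens before flattening and sorting.

### Setpoint referencing and calibration

Errors are referenced to the setpoint frame, not the stack centers: the
setpoint's own displacement against each stack is measured once at
engagement and subtracted from all subsequent estimates.  This cancels drift
accumulated while the stacks were being acquired as well as any constant
estimator bias.  Residual proportionality errors of the estimator are
absorbed by per-axis calibration factors determined from an open-loop
staircase: the stage is stepped back and forth by 20 nm, plateau levels are
detrended with a per-plateau linear term and extrapolated to each transition
time, and the scale is the mean of (commanded step)/(measured amplitude)
with a 95% t confidence interval.  On the default simulated scene the
estimator's intrinsic amplitude response is ≈0.985, i.e. the calibration
factors sit near 1, inside the 0.85–1.1 band typical for this estimator
class.  Automating the plateau analysis replaces manual tuning of the same
quantity.

### Feedback law

The controller is a discrete-time PI law with a small second-order
integrator, applied per iteration (the loop is iteration-clocked, so gains
are dimensionless):

    Sₖ  = Sₖ₋₁ + eₖ            (integral)
    Tₖ  = Tₖ₋₁ + Sₖ            (double integral)
    uₖ  = −(kp·eₖ + ki·Sₖ + kii·Tₖ), clamped to ±output_limit

The double integrator improves rejection of persistent accelerating drifts
(e.g. thermally driven); kii is kept well below ki.  It is exposed as an
independent gain rather than as a fixed fraction of ki — the "small portion"
formulation is ambiguous, and an explicit gain is strictly more general.
Defaults kp = 0.75, ki = 0.2, kii = 0.005 were tuned on the idealized
discrete plant (position integrator with one frame of delay) to settle a
20 nm step within ~7 iterations at < 30% overshoot.  Axes whose fit failed
this iteration contribute zero correction with frozen integrators; if every
axis stays invalid for more than `max_invalid_streak` iterations the loop
aborts with the partial log attached.  Integrators are clamped at
`stage_limit_nm` (anti-windup).

## The virtual microscope

The simulator exists so that every stage of the pipeline is testable without
hardware, with exact ground truth.

**Patterns.**  `holey_carbon`: a square lattice of discs of reduced
reflectivity, 2 µm diameter and 2 µm edge-to-edge spacing (4 µm period),
random lattice phase per seed.  `bead_field`: seeded random isolated
Gaussian spots (~150 nm scale).  `tile_target`: a 10 µm square grid of dark
lines.  Patterns are rendered on a 4× supersampled grid and area-binned to
camera pixels (default 75 nm, anisotropic sizes supported), with a rendered
margin (default 32 px per side) so lateral shifts and blur never expose an
edge.

**Image formation.**  Lateral sample displacement is applied as an *exact
Fourier-domain translation* of the binned map.  Real-space interpolation
(spline shifting, even on the supersampled grid) low-passes the image by an
amount that depends on the fractional part of the shift; because the CC
statistic compares sum-normalized frames whose L2 norms differ, that
phase-dependent smoothing masquerades as displacement and can dominate the
curve.  Fourier translation is norm-preserving and bias-free for the
band-limited binned map; the margin keeps periodic wrap out of the ROI.

Axial position enters through an isotropic Gaussian blur of width
w(z) = w0·√(1 + (z/z_R)²), defaults w0 = 250 nm, z_R = 1000 nm.  This is a
Gaussian-beam-style surrogate, not a physical diffraction PSF: the axial
estimator only needs a smooth, monotone dependence of the intensity
histogram on |z|, which this provides — including the physically relevant
feature that dw/dz = 0 exactly in focus, so histogram sensitivity vanishes
at z = 0 and is restored at moderate defocus.  Consequently the working
position defaults to 2 µm defocus, and simulated axial precision at 2 µm
defocus is ~2× better than in focus (the optimum sits near z_R; on real
systems it is reported in the 2–3 µm range and depends on sample and
objective).  The surrogate does not model the scattering-intensity
redistribution that produces the effect physically, only its monotone
histogram signature.

**Noise.**  Poisson shot noise at a photon scale putting the brightest pixel
near 70% of a 16-bit sensor's saturation (within the 60–80% band used in
practice), Gaussian read noise (σ = 10 counts), constant offset, clipped to
the sensor range.  Every random element (scene phase, bead placement, noise,
drift) draws from an explicit seed; identical configurations reproduce
frame streams and loop logs bit-identically.

**Stage and drift.**  The virtual stage tracks commanded and actual
positions with a per-call relaxation factor (default 1.0 = instant settle
within one iteration, as with a piezo plus settle buffer) and a travel clamp
that warns rather than raises.  Drift models: none, linear (nm/iteration),
random walk, sinusoidal (emulating periodic temperature-coupled drift), or
a composite sum; one drift tick elapses per acquired frame.

## Default problem sizes

The default ROI is **160 × 160 px** (12 µm at 75 nm/px).  This equals
exactly three periods of the 4 µm hole lattice, which makes the
ROI-integrated intensity invariant under lateral shifts.  With an
incommensurate ROI this small, holes crossing the ROI boundary change the
frame sum to first order in the shift, while the autocorrelation signal the
CC curve rides on is second order; the edge flux then biases — and for small
fields can dominate — the lateral match curve.  (Large real ROIs with many
boundary features average this down, and what survives lands in the
calibration factor.)  Choosing a commensurate reference ROI is therefore
the simulated analogue of choosing a well-conditioned reference region, and
300 × 300 px operation remains a config option.

Reference stacks default to 11 planes at 20 nm for all axes.  Closed-loop
experiments in the tests and the acceptance script use 400-iteration runs
(drift rejection), 525-iteration staircases (10 steps per direction every
25 iterations), 200 estimator trials (noisy recovery), and 25-frame
precision probes — sizes chosen to make sampling error small relative to
the margins being tested while keeping a full run in minutes on one core.

## Numerical choices

- **Gaussian peak fit:** initialized at the curve argmax (ties → lowest
  index) with width = plane_count/4; solved by unbounded Levenberg–Marquardt
  with an analytic Jacobian.  Broad match curves make (A, w, c) jointly
  near-degenerate, where bounded trust-region iterations crawl; LM traverses
  the flat valley quickly and the center constraint 0 ≤ µ ≤ plane_count − 1
  is enforced after the fit (violations → `converged = False`).  An argmax
  at either end of the curve raises an out-of-range error (drift beyond the
  stack range) before any fit is attempted.
- **Step-response fit:** segments are aligned at each disturbance, folded by
  disturbance sign, truncated to the shortest gap and averaged; the model
  α·e^(−(t−t0)/τ) (defined 0 before t0) is fitted by grid-searching t0 —
  which enters non-smoothly — with (α, τ) solved by least squares at each
  candidate.  Because the sampled model is exactly invariant to moving t0
  within an inter-sample gap (α re-absorbs the change), the reported t0 is
  the *largest* onset consistent with the minimal residual, located by
  bisecting the residual jump.  A non-decaying averaged response (tail above
  half the peak) is a fit-failure diagnostic, not a number.
- **Recovery definition:** after a step disturbance the loop is considered
  recovered when |e| < 3σ of the steady-state error signal.
- **Rolling statistics:** centered window, shrink-at-edges
  (`min_periods = 1`), so the rolling series has the log's length; invalid
  samples are excluded from σ and treated as missing in rolling series.
- **Drift-reduction factors:** per-axis rms of mean-centered tracks of equal
  length; a numerically zero stabilized rms flags the factor as a lower
  bound instead of returning infinity.
- **Degenerate inputs:** all-zero frames, constant match curves, staircases
  with zero amplitude, and plateaus indistinguishable from noise raise
  typed errors rather than returning numbers.

## What passing tests do and do not show

The simulator reproduces the *mechanisms* the estimator relies on —
shift-dependent cross-correlation, defocus-dependent histograms, shot/read
noise at realistic sensor fill, drift shapes — with exact ground truth, so
the tests demonstrate that the estimation → control → actuation chain is
correct, unbiased at the sub-step level, and stable.  They do not
demonstrate hardware-grade performance: there is no vibration, no camera
fan, no optical-path drift between stabilization and imaging paths, no
warm-up transients, no real PSF, and the virtual stage settles ideally.
Quantities such as the in-loop σ of a few tenths of a nanometer are
properties of these simulated conditions, not predictions for any physical
instrument.

## Known limitations

- The defocus surrogate is symmetric in z about focus; real systems break
  this symmetry, which typically *helps* axial estimation near focus.
- The estimator is validated on scenes with shift-invariant ROI intensity;
  strongly incommensurate small ROIs reduce lateral sensitivity (see above).
- The controller is tuned for the instant-settle stage; much slower settle
  fractions would require retuning.
- No GPU path and no learned estimators; the estimator is O(planes × pixels)
  per axis per iteration on one core.
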