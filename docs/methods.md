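# Methods

This note documents the models, conventions, defaults and limitations of
`servonav`. It is the authoritative description of what the simulator
does and does not emulate.

## Signal model

The navigator is treated as an encoding-only probe: for object pose
(R, T), field state (φ₀, f₀, g) and trajectory sample (kᵢ, tᵢ) the
noise-free signal on channel c is

    s_c,i = S_c(Rᵀ k_eff,i) · exp(−i k_eff,i·T) · exp(i(φ₀ + 2π f₀ tᵢ)),
    k_eff,i = kᵢ − 2π γ̄ g tᵢ,

with γ̄ = 42.5774 MHz/T and the Fourier convention
s(k) = ∫ρ(r) e^(−i k·r) dr (k in rad/m, r in m). The gradient-offset
term is an exact time-proportional k-shift for a constant offset, not a
per-voxel phase sum. The sign pairing between the f₀ phase (+i 2π f₀ t)
and the gradient k-shift (−2π γ̄ g t) is one self-consistent choice of
the demodulation convention; physical scanners differ in these signs,
and the only binding requirement — that the estimator return each
injected parameter with the correct sign — is enforced by test.

Not modeled during the 2.3 ms readout: relaxation (T2* decay), spatially
varying off-resonance within the object, chemical shift, concomitant
fields, channel noise correlations. These all perturb real navigators;
their absence means the simulator's noise floors are optimistic relative
to a scanner.

## Phantom

An analytic phantom built from uniform ellipsoids: each has closed-form
k-space signal amplitude·V·3(sin κ − κ cos κ)/κ³ with
κ = |diag(a,b,c) Rᵀ k|, times exp(−i k·center). The default phantom is a
five-ellipsoid asymmetric "head" (one envelope, four off-center internal
features, mixed-sign amplitudes, overall DC ≈ 1 signal unit). Asymmetry
is load-bearing: a spherically symmetric object has rotation-invariant
spectra on the navigator sphere and makes the rotation columns of the
model exactly zero (this degenerate case raises a rank error, also by
test).

Coil sensitivities are synthetic low-order (≤2) complex polynomials over
the bounding sphere, applied as one complex weight per
(channel, ellipsoid) evaluated at the ellipsoid center. This
piecewise-constant approximation keeps the forward model closed-form
while giving channels distinct spatial weightings — the property that
conditions the estimates. It is not a Biot–Savart coil model; absolute
per-channel SNR ratios are not meaningful.

## Trajectory

Three sequential orthogonal great circles (XY, YZ, ZX planes) on the
sphere of radius 400 rad/m, 96 samples, 2.3 ms, uniform angular
sampling, equal time per circle. The scanner navigator this emulates is
a single-shot orbital waveform whose exact parametrization is not
public; the three-circle design is a documented stand-in that probes all
three rotation axes and both transverse k-components per axis.
Trajectories are geometric — no slew/amplitude limits — because all
physics enters through the sampled (k, t) pairs.

Trapezoid spectral shaping: a trapezoid (ramp–flat–ramp) is the
convolution of a rect of width flat+ramp with a normalized rect of width
ramp, giving spectrum amplitude·(flat+ramp)·sinc(f(flat+ramp))·sinc(f·ramp).
`align_first_zero` solves flat+ramp = 1/f_res with the **roll-off factor
defined as ramp/flat** (the stated 2/3 value is ambiguous between
ramp/flat, ramp/(ramp+flat) and total-ramps/flat; ramp/flat is fixed
here and documented), preserving the gradient moment by rescaling the
amplitude. Only these spectral analytics are implemented — no impulse
response measurement or acoustic-resonance identification.

## Calibration and estimation

Eight calibration shots: ref1, ref2, three trajectory rotations (+0.5°
about X, Y, Z), three gradient offsets (+5 μT/m on Gx, Gy, Gz). Rotation
and gradient columns are single-sided finite differences against ref1;
because a trajectory rotation by +δ is signal-equivalent to an object
rotation by −δ, the rotation differences are divided by −δ so all
columns are per unit of *object* motion. Translation (−i kⱼ s per mm),
phase (i s per rad) and frequency (i 2π t s per Hz) columns are
analytic. Complex rows are stacked as [Re; Im]; the pseudo-inverse uses
SVD with relative cutoff 1e-10 and raises on rank < 11, naming the
weakly observable directions.

Estimates are θ = A⁺(s − s_ref₂). Using a second reference (not the one
baked into the columns) makes the noise-only estimate offset a zero-mean
random variable over the calibration ensemble rather than a systematic
bias; the test suite demonstrates both halves of this.

Calibration noise has a second effect worth knowing about: it perturbs
the finite-difference columns themselves (an errors-in-variables
problem), which *attenuates* estimates by roughly the inverse
column-level SNR. At the default noise floor this is a 10–20%
multiplicative shrinkage of rotation/gradient estimates. It is left
uncorrected because the closed loop integrates through it (an attenuated
gain-1 loop still converges, just over a few more shots), which is the
same mechanism a scanner implementation relies on.

`conditioning_report` propagates i.i.d. complex input noise through A⁺
(row norms × σ) to predict per-parameter floors; `noise_sd_for_floor`
inverts this to pick the signal noise giving prescribed floors (defaults
5 mdeg on rotations, 2 μm on translations — the level used by the
closed-loop experiments).

## Servo loop

Per shot: the navigator is simulated at the residual state (truth
composed with the inverse of the corrections in force — what a scanner
sees after updating trajectory, RF frequency and shim); the model
estimates the residual; the residual is composed with the correction in
force to form the **absolute** (reference-relative) prediction; bias
correction and the run-time moving average act on that absolute series;
the filtered absolute value is the new correction target (gain 1).

This "filter the absolute prediction, apply as target" arrangement is a
deliberate design choice: filtering residual *increments* and
accumulating them puts the moving average's phase lag inside an
integrator and makes the gain-1 loop ring; filtering absolute
predictions is unconditionally stable (the correction is a smoothed
estimate of the disturbance itself). With the filter disabled the two
are identical.

Actuators: pose corrections compose exactly; frequency corrections
accumulate; shim corrections accumulate exactly but are *applied*
quantized to the 0.14 μT/m hardware lattice (ties away from zero), with
the sub-increment remainder visible to the next estimate. φ₀ is
estimated and logged but not fed back — there is no actuator for a
global receive phase. A correction computed from shot n takes effect at
shot n + latency (default 1, configurable): the real system's total
latency of a few ms is below one TR (~43–54 ms). Corrections are
absolute targets, so a late-arriving update supersedes rather than
stacks on pending ones.

Rotation convention everywhere: extrinsic rotations about the fixed
device axes in the order X, Y, Z (matrix Rz·Ry·Rx), degrees, about the
iso-center. At the ≤2° working range the convention choice is a
second-order effect, but it is fixed and used consistently; off-center
rotations are expressible as rotation+translation in disturbance
scripts. PRS (gradient-logical) coordinates appear only at the
`prs_to_xyz` boundary, which maps the rotation-angle, translation and
gradient 3-vectors through the slab orientation matrix (small-angle
treatment of the angle triple).

## Bias correction and filters

The ETS bias table is the per-in-plane-index mean of the last 4
partitions of uncorrected predictions (ring buffer, recomputed every new
partition). **Only the zero-mean periodic part is subtracted**: the
common level across the S indices is current true motion/field, not an
acquisition artifact, and subtracting it would permanently absorb
sustained motion into the table. This centering is what produces the
characteristic symmetric transient when a motion ramp enters the window:
a ramp of magnitude M over one partition contributes (ramp(s) − M/2)/4
to the centered table, i.e. a ±M/8 deviation band (±0.25 mm for
M = 2 mm) that decays to zero within exactly 4 partitions after the
event leaves the window.

The run-time filter is a trailing (causal) moving average — window 10
shots for motion parameters (0.54 s at TR 54.1 ms), 14 for field
parameters (0.76 s) — applied after bias subtraction. No outlier or
motion-event exclusion is performed in the bias estimation.

Precision metric: sample standard deviation after a second-order
Butterworth high-pass applied forward-backward (zero phase) at
1/(TR·S) — low enough to keep the period-S ETS band, high enough to
reject drifts. The filter family is a fixed, documented choice; only the
threshold is prescribed by the protocol. `precision_report` excludes the
first 4 partitions (the bias-initialization window, during which
correction is off) from all stages so the stage comparison reflects
steady-state operation.

## Scenarios and defaults

Disturbance scripts prescribe per-shot true pose/field built from steps,
linear ramps, drifts and sinusoids, plus a period-S prediction-bias
pattern (applied to the *estimates*, as ETS does on a scanner — it is an
acquisition artifact, not a physical field) and a navigator noise level.
All scenario output is reproducible from (config, seed).

Protocol presets: protocol-I (TR 54.1 ms, S 48, PE bandwidth 93 Hz/mm)
and protocol-II (TR 43 ms, S 30, PE bandwidth 120 Hz/mm).

The parameter-domain bias-correction study (`bias_transient_scenario`) uses
S = 48, 16 partitions, motion onset at partition 8, pattern amplitude
0.05 mm, Gaussian prediction noise sd 0.01 mm. The noise default keeps
the corrected-trace noise floor below ~5% of the 0.25 mm transient, so
the reported peak is dominated by the window arithmetic; the test suite
verifies the transient is stable over a 4× range of noise levels and
multiple seeds, and exactly ±M/8 in the noise-free limit. The peak
metric is the literal maximum absolute deviation of the corrected trace
from the truth after onset, so it inflates slowly with the noise level
(max over ~400 samples).

The closed-loop experiments (abrupt step Rx = −1.9°, Tz = −2.3 mm;
field-step "bottle" scenario) run 4 partitions of protocol-II (120
shots), onset at shot 40, residuals evaluated from 20 shots after the
event. A frequency offset's image-domain effect is summarized as the
apparent shift f₀ / (PE bandwidth per mm).

## Problem sizes

Defaults were chosen as the smallest sizes that exercise every mechanism
with clean statistics: 96 navigator samples × 8 channels (1536 real rows
against 11 columns), 120-shot closed-loop runs, 270-shot precision runs,
768-shot bias-correction runs, and a 1000-shot null-stability run. A
full loop shot costs well under a millisecond, so all studies complete
in seconds on one CPU.

## Known limitations

* No image formation: effects are quantified in parameter space (plus
  the apparent-shift summary), not as image artifacts.
* The coil model's center-evaluated sensitivities underrate the
  shading-induced coupling between rotations and translations that real
  arrays exhibit.
* The ETS bias is injected as a stationary period-S pattern; real biases
  drift with the slice-encoding rewinder amplitude (the sliding window
  exists to track exactly that, but the drift itself is not scripted by
  default — `make_script` drift rates can emulate it).
* Open-loop estimates beyond ~2°/2 mm are biased by linearization, as
  they are on a scanner; only the closed loop restores accuracy there.
* Higher-order (beyond linear) field terms, physiological field
  fluctuations with realistic spectra, and retrospective f₀ demodulation
  are out of scope.
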