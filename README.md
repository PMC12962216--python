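# servonav

Desk-scale simulator and estimator library for **servo navigation**:
closed-loop prospective correction of rigid-body head motion and
zeroth/first-order field changes in MRI, driven by short 3D orbital
k-space navigators.

## Who this is for

MR-physics researchers and sequence developers who want to study the
estimation and control layer of navigator-based prospective motion/field
correction — model conditioning, servo stability, echo-time-shifting
(ETS) bias correction, run-time filtering, precision metrics — without a
scanner. Everything runs on an analytic digital phantom whose k-space
signal is available in closed form, so there is no reconstruction, no
gridding, and no discretization error between the "physics" and the
estimator.

## The model

A short single-shot orbital navigator (radius 400 rad/m, 2.3 ms) is
acquired every shot of a segmented 3D-EPI sequence. Small rigid-body
motion and low-order field changes perturb its complex multi-channel
signal linearly, so an 11-parameter vector

θ = [Rx, Ry, Rz, Tx, Ty, Tz, φ₀, f₀, Gx, Gy, Gz]

(deg, mm, rad, Hz, μT/m) can be read off a single shot as

θ = A⁺ · (s − s_ref₂),

where the model matrix A is calibrated from **eight shots**: two
references, three with the trajectory rotated 0.5° about X/Y/Z, and
three with 5 μT/m gradient offsets (finite differences against the first
reference); translation, phase and frequency columns are analytic
(−i k s, i s, i 2π t s). Estimates are differenced against the *second*
reference, which keeps the estimator offset-free under calibration
noise.

A gain-1 servo applies the (bias-corrected, moving-average-filtered)
estimates as corrections before each shot — trajectory frame, RF
frequency, and quantized linear shim (0.14 μT/m increments) — so the
object stays close to the reference state and the linear model's
validity range (~2°, 2 mm) is continually re-centered.

ETS leaves a systematic prediction bias repeating every S shots
(S = in-plane segmentation factor). The bias table is the per-index mean
of the last 4 partitions of uncorrected predictions, updated each
partition in a sliding window, and its periodic (zero-mean) part is
subtracted at run time. Precision is reported as the standard deviation
of a parameter trace after zero-phase high-pass filtering at 1/(TR·S).

## Worked example

```python
import numpy as np
import servonav as sv

# calibrate the linear model on the default asymmetric phantom
phantom = sv.default_head_phantom()
coil = sv.CoilModel.synthetic(n_channels=8)
traj = sv.make_orbital()                      # 400 rad/m, 2.3 ms
cal = sv.acquire_calibration(phantom, coil, traj, noise_sd=0.0, seed=0)
model = sv.build_model(cal, traj)
print(f"model rank: {model.rank}")

# inject a small combined motion/field change and read it back
sig = sv.simulate_navigator(
    phantom, coil, traj,
    pose=sv.Pose(rx=0.2, tz=-0.3),
    field=sv.FieldState(f0=5.0, gx=1.0),
)
theta = sv.estimate(model, sig)
for name, value in zip(sv.PARAM_NAMES, theta.values):
    if abs(value) > 0.01:
        print(f"  {name:5s} = {value:+.3f}")

# close the loop on an abrupt-step scenario (Rx −1.9°, Tz −2.3 mm)
sched = sv.ShotSchedule(S=30, P=4, tr_ms=43.0)
scenario = sv.step_motion_scenario(
    sv.Pose(rx=-1.9, tz=-2.3), onset=40, schedule=sched, seed=1)
traces = sv.run_closed_loop(scenario, sv.ServoConfig(seed=1))
rot, trans = traces.residual_pose_magnitudes()
print(f"post-step residual: {np.mean(rot[60:]):.3f} deg, "
      f"{np.mean(trans[60:]):.3f} mm")
```

prints

```
model rank: 11
  rx    = +0.194
  tz    = -0.300
  f0    = +5.021
  gx    = +0.991
  gy    = +0.011
  gz    = +0.053
post-step residual: 0.010 deg, 0.001 mm
```

The injected rotation/translation/frequency/gradient offsets come back
with the correct sign within a few percent (the small rx shortfall and
gz cross-talk are the expected linearization residue at 0.2–0.3 of the
linear range), and after an abrupt out-of-range pose step the closed
loop settles to ~0.01° / 0.001 mm residual — the servo re-centers the
model each shot, so accuracy is restored even though the single-shot
estimate of a 1.9°/2.3 mm jump is biased.

There is also a CLI for the canned experiments:

```
servonav --protocol II --seed 1 --out out/ step        # abrupt-step correction
servonav --seed 1 --out out/ bias-transient                    # bias-correction transient
servonav --protocol I --out out/ bottle                # field step / apparent shift
servonav --out out/ precision                          # stage-wise precision report
```

Each command writes tidy CSV traces plus a JSON report/manifest with
seeds and configuration.

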