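"""Closed-loop servo controller for pose, frequency and shim corrections.

Each shot: the navigator is simulated at the *residual* state (true
disturbance composed with the inverse of the corrections currently in
force -- exactly what a scanner sees after updating the trajectory frame,
RF frequency and shim); the linear model estimates the residual; the
residual is composed with the correction in force to give the *absolute*
(reference-relative) prediction; bias correction and the run-time moving
average operate on that absolute series; and the filtered absolute value
becomes the new correction target (gain 1).  With the filter disabled
this is exactly classic gain-1 accumulation of residual estimates;
filtering the absolute predictions rather than the residual increments is
what keeps the loop free of integrator ringing.  A correction computed
from shot n first takes effect at shot n + latency (default 1: the few-ms
compute latency is below one TR).

The phase offset phi0 is estimated and logged but not fed back -- there
is no actuator for a global receiver phase.  Shim corrections are
accumulated exactly but *applied* on the hardware quantization lattice
(default 0.14 uT/m increments); the unapplied remainder stays visible to
the next estimate and is mopped up once it crosses half an increment.

Open-loop mode runs the identical pipeline with corrections never
applied, for comparison (this is how uncorrected scans still log motion).
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import dataclass, field as dc_field, replace

import numpy as np

from .core import (
    FieldState,
    ParameterVector,
    Pose,
    compose_pose,
    inverse_pose,
    quantize_shim,
    PARAM_NAMES,
)
from .phantom import CoilModel, EllipsoidPhantom, default_head_phantom
from .trajectory import NavigatorTrajectory, make_orbital
from .forward import simulate_navigator
from .estimator import (
    LinearModel,
    acquire_calibration,
    build_model,
    estimate,
    noise_sd_for_floor,
)
from .biasfilt import (
    BiasTable,
    FIELD_FILTER_WINDOW,
    MOTION_FILTER_WINDOW,
    WINDOW_PARTITIONS,
    apply_bias_correction,
    init_bias,
    slide_bias,
)
from .scenarios import DisturbanceScript

__all__ = ["ServoConfig", "ControllerState", "LoopTraces", "controller_step", "run_closed_loop", "run_open_loop"]


@dataclass(frozen=True)
class ControllerState:
    """Cumulative corrections plus actuator constraints.

    pose_corr tracks the object pose (the trajectory/FoV follows it);
    f0_corr and shim_accum cancel field offsets additively; applied shim
    values are always integer multiples of the quantization increment.
    """

    pose_corr: Pose = dc_field(default_factory=Pose)
    f0_corr: float = 0.0
    phi0_last: float = 0.0  # logged only, no actuator
    shim_accum: np.ndarray = dc_field(default_factory=lambda: np.zeros(3))
    shim_increment: float = 0.14
    latency: int = 1
    log: tuple = ()

    def __post_init__(self):
        if self.latency < 1:
            raise ValueError("latency must be >= 1 shot")
        object.__setattr__(self, "shim_accum", np.asarray(self.shim_accum, float))

    @property
    def shim_applied(self) -> np.ndarray:
        """Shim correction actually in force: accumulator snapped to the lattice."""
        return quantize_shim(self.shim_accum, self.shim_increment)

    def as_applied_array(self) -> np.ndarray:
        """Applied correction as an 11-vector (phi0 entry 0: logged only)."""
        return np.concatenate(
            [
                self.pose_corr.as_array(),
                [0.0, self.f0_corr],
                self.shim_applied,
            ]
        )


def controller_step(state: ControllerState, filtered_estimate: ParameterVector) -> ControllerState:
    """Gain-1 negative-feedback update from one (filtered) residual estimate.

    A non-finite estimate skips the update (state unchanged, event logged).
    """
    theta = filtered_estimate.as_array()
    if not np.all(np.isfinite(theta)):
        return replace(state, log=state.log + ("skipped non-finite estimate",))
    est_pose = filtered_estimate.pose
    est_field = filtered_estimate.field
    return replace(
        state,
        pose_corr=compose_pose(est_pose, state.pose_corr),
        f0_corr=state.f0_corr + est_field.f0,
        phi0_last=est_field.phi0,
        shim_accum=state.shim_accum + est_field.g,
    )


@dataclass(frozen=True)
class LoopTraces:
    """Per-shot series of a loop run; all (n_shots, 11) on a shared shot axis.

    raw / bias_corrected / filtered are absolute (reference-relative)
    predictions, so they track the true motion in both loop modes;
    applied is the correction in force; residual = truth - applied.
    """

    truth: np.ndarray
    raw: np.ndarray
    bias_corrected: np.ndarray
    filtered: np.ndarray
    applied: np.ndarray
    residual: np.ndarray  # truth - applied, componentwise
    schedule: object
    manifest: dict
    events: tuple = ()

    def residual_pose_magnitudes(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-shot residual rotation (deg) and translation (mm) magnitudes.

        Computed from the proper pose composition truth o applied^-1, not
        the componentwise difference.
        """
        n = self.truth.shape[0]
        rot = np.empty(n)
        trans = np.empty(n)
        for i in range(n):
            res = compose_pose(Pose(*self.truth[i, :6]), inverse_pose(Pose(*self.applied[i, :6])))
            rot[i] = res.rotation_magnitude()
            trans[i] = res.translation_magnitude()
        return rot, trans

    def to_dataframe(self):
        """Tidy frame: one row per shot per parameter per series."""
        import pandas as pd

        n = self.truth.shape[0]
        frames = []
        for series_name in ("truth", "raw", "bias_corrected", "filtered", "applied", "residual"):
            arr = getattr(self, series_name)
            df = pd.DataFrame(arr, columns=list(PARAM_NAMES))
            df["shot"] = np.arange(n)
            df = df.melt(id_vars="shot", var_name="parameter", value_name="value")
            df["series"] = series_name
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def write_manifest(self, path) -> None:
        with open(path, "w") as f:
            json.dump(self.manifest, f, indent=2, default=str)


@dataclass(frozen=True)
class ServoConfig:
    """Everything needed to calibrate and run a loop.

    noise_sd = None picks the largest signal noise keeping the predicted
    parameter floors at 5 mdeg / 2 um (see estimator.noise_sd_for_floor).
    """

    phantom: EllipsoidPhantom | None = None
    coil: CoilModel | None = None
    trajectory: NavigatorTrajectory | None = None
    n_channels: int = 8
    noise_sd: float | None = None
    seed: int = 0
    latency: int = 1
    shim_increment: float = 0.14
    use_bias_correction: bool = True
    use_filter: bool = True
    motion_window: int = MOTION_FILTER_WINDOW
    field_window: int = FIELD_FILTER_WINDOW

    def resolve(self):
        ph = self.phantom if self.phantom is not None else default_head_phantom()
        coil = self.coil if self.coil is not None else CoilModel.synthetic(self.n_channels)
        tr = self.trajectory if self.trajectory is not None else make_orbital()
        return ph, coil, tr


def _filter_tail(history: np.ndarray, motion_window: int, field_window: int) -> np.ndarray:
    """Causal per-group moving average over the estimate history."""
    out = np.empty(11)
    mw = history[-motion_window:, :6]
    fw = history[-field_window:, 6:]
    out[:6] = mw.mean(axis=0)
    out[6:] = fw.mean(axis=0)
    return out


def _run_loop(scenario: DisturbanceScript, config: ServoConfig, closed: bool) -> LoopTraces:
    ph, coil, tr = config.resolve()
    noise_sd = scenario.noise_sd if scenario.noise_sd is not None else config.noise_sd

    # calibrate (noise-matched to the run)
    cal_noise = noise_sd if noise_sd is not None else 0.0
    # two-pass when the floor-derived default is requested: calibrate
    # noise-free to size the floor, then recalibrate with that noise
    cal = acquire_calibration(ph, coil, tr, noise_sd=0.0, seed=config.seed)
    model = build_model(cal, tr)
    if noise_sd is None:
        noise_sd = noise_sd_for_floor(model)
    if noise_sd > 0:
        cal = acquire_calibration(ph, coil, tr, noise_sd=noise_sd, seed=config.seed)
        model = build_model(cal, tr)

    sched = scenario.schedule
    n = sched.n_shots
    s_factor = sched.S
    rng = np.random.default_rng(config.seed + 1)
    shot_seeds = rng.integers(0, 2**31 - 1, size=n)

    truth = scenario.truth()
    raw = np.zeros((n, 11))
    corrected = np.zeros((n, 11))
    filtered = np.zeros((n, 11))
    applied = np.zeros((n, 11))
    events = []

    state = ControllerState(shim_increment=config.shim_increment, latency=config.latency)
    pending: deque = deque()  # (effective_shot, ControllerState)
    current = state

    bias_table: BiasTable | None = None
    partition_raw: list = []

    for shot in range(n):
        while pending and pending[0][0] <= shot:
            _, current = pending.popleft()
        applied[shot] = current.as_applied_array()

        p_true = scenario.pose_at(shot)
        f_true = scenario.field_at(shot)
        resid_pose = compose_pose(p_true, inverse_pose(current.pose_corr))
        shim = current.shim_applied
        resid_field = FieldState(
            f_true.phi0,
            f_true.f0 - current.f0_corr,
            f_true.gx - shim[0],
            f_true.gy - shim[1],
            f_true.gz - shim[2],
        )
        sig = simulate_navigator(
            ph, coil, tr, resid_pose, resid_field, noise_sd=noise_sd,
            seed=int(shot_seeds[shot]), shot_index=shot, schedule=sched,
        )
        resid_est = estimate(model, sig).as_array() + scenario.prediction_bias(shot)
        # absolute (reference-relative) prediction: correction in force
        # composed/added with the estimated residual; in open loop the
        # correction is identity so this is the direct estimate
        abs_pose = compose_pose(Pose(*resid_est[:6]), current.pose_corr)
        theta = np.concatenate(
            [
                abs_pose.as_array(),
                [resid_est[6], current.f0_corr + resid_est[7]],
                shim + resid_est[8:11],
            ]
        )
        raw[shot] = theta

        # sliding-window bias correction on the uncorrected predictions
        if config.use_bias_correction:
            s_idx = sched.in_plane(shot)
            if bias_table is not None:
                corrected[shot] = apply_bias_correction(theta, bias_table, s_idx)
            else:
                corrected[shot] = theta
            partition_raw.append(theta)
            if len(partition_raw) == s_factor:
                if bias_table is None:
                    if sched.partition(shot) == WINDOW_PARTITIONS - 1:
                        bias_table = init_bias(
                            raw[: WINDOW_PARTITIONS * s_factor], s_factor
                        )
                else:
                    bias_table = slide_bias(bias_table, np.asarray(partition_raw))
                partition_raw = []
        else:
            corrected[shot] = theta

        if config.use_filter:
            filtered[shot] = _filter_tail(
                corrected[: shot + 1], config.motion_window, config.field_window
            )
        else:
            filtered[shot] = corrected[shot]

        if closed:
            # the filtered absolute estimate is the new correction target;
            # controller_step consumes the increment from the state in
            # force for this shot (with the filter disabled the increment
            # is exactly the residual estimate: pure gain-1 feedback).
            # Corrections are reference-relative, so a later pending state
            # simply supersedes an earlier one.
            target = filtered[shot]
            if np.all(np.isfinite(target)):
                inc_pose = compose_pose(Pose(*target[:6]), inverse_pose(current.pose_corr))
                inc = np.concatenate(
                    [
                        inc_pose.as_array(),
                        [target[6], target[7] - current.f0_corr],
                        target[8:11] - current.shim_accum,
                    ]
                )
            else:
                inc = target  # non-finite: let controller_step log the skip
            new_state = controller_step(current, ParameterVector.from_array(inc))
            if len(new_state.log) > len(current.log):
                events.append((shot, new_state.log[-1]))
            pending.append((shot + config.latency, new_state))

    manifest = dict(
        closed_loop=closed,
        noise_sd=noise_sd,
        seed=config.seed,
        latency=config.latency,
        shim_increment=config.shim_increment,
        use_bias_correction=config.use_bias_correction,
        use_filter=config.use_filter,
        motion_window=config.motion_window,
        field_window=config.field_window,
        n_channels=coil.n_channels,
        n_shots=n,
        S=s_factor,
        tr_ms=sched.tr_ms,
        scenario_seed=scenario.seed,
    )
    return LoopTraces(
        truth, raw, corrected, filtered, applied, truth - applied, sched, manifest, tuple(events)
    )


def run_closed_loop(scenario: DisturbanceScript, config: ServoConfig | None = None) -> LoopTraces:
    """Run the scenario with servo corrections applied before each shot."""
    return _run_loop(scenario, config or ServoConfig(), closed=True)


def run_open_loop(scenario: DisturbanceScript, config: ServoConfig | None = None) -> LoopTraces:
    """Run the identical pipeline with corrections never applied."""
    return _run_loop(scenario, config or ServoConfig(), closed=False)
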