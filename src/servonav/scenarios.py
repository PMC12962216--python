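"""Synthetic disturbance scripts and canned parameter-domain experiments.

A :class:`DisturbanceScript` is the stand-in for scanner physics and
subject behavior: it prescribes, per shot, the true object pose and field
state, a repeating period-S prediction-bias pattern (emulating the
echo-time-shifting bias, which is an acquisition artifact added to the
*predictions*, not a physical field), and the navigator noise level.
Everything is reproducible from (config, seed).

:func:`bias_transient_scenario` replicates the parameter-domain simulation of the
bias-correction pipeline under rapid motion: predictions = truth + pattern
+ noise, run through the sliding-window bias estimator directly, with no
MR signal simulation involved.  This isolates the window arithmetic: a
motion ramp entering the 4-partition window leaves a transient in the
corrected trace that is pure bookkeeping, independent of the noise level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import FieldState, Pose, PARAM_NAMES
from .forward import ShotSchedule
from .biasfilt import (
    WINDOW_PARTITIONS,
    apply_bias_correction,
    init_bias,
    slide_bias,
)

__all__ = [
    "MotionEvent",
    "DisturbanceScript",
    "make_ets_pattern",
    "make_script",
    "null_scenario",
    "step_motion_scenario",
    "bottle_scenario",
    "bias_transient_scenario",
    "BiasTransientResult",
]

LINEAR_RANGE_DEG = 2.0
LINEAR_RANGE_MM = 2.0


@dataclass(frozen=True)
class MotionEvent:
    """Step or linear-ramp disturbance on one parameter.

    param: name from PARAM_NAMES; magnitude in the parameter's native
    unit; onset in shots; duration_shots = 0 for a step, > 0 for a ramp
    reaching the magnitude over that many shots.
    """

    param: str
    magnitude: float
    onset: int
    duration_shots: int = 0

    def series(self, n_shots: int) -> np.ndarray:
        out = np.zeros(n_shots)
        n = np.arange(n_shots)
        if self.duration_shots <= 0:
            out[n >= self.onset] = self.magnitude
        else:
            ramp = np.clip((n - self.onset) / self.duration_shots, 0.0, 1.0)
            out = self.magnitude * ramp
            out[n < self.onset] = 0.0
        return out


@dataclass(frozen=True)
class DisturbanceScript:
    """Per-shot ground truth plus prediction-bias pattern and noise level."""

    schedule: ShotSchedule
    pose: np.ndarray  # (n_shots, 6)
    field: np.ndarray  # (n_shots, 5)
    bias_pattern: np.ndarray  # (S, 11), zero-mean over the period
    noise_sd: float | None = None  # navigator signal noise; None -> config default
    seed: int = 0

    def __post_init__(self):
        n = self.schedule.n_shots
        p = np.asarray(self.pose, dtype=float)
        f = np.asarray(self.field, dtype=float)
        b = np.asarray(self.bias_pattern, dtype=float)
        if p.shape != (n, 6) or f.shape != (n, 5):
            raise ValueError(
                f"series lengths must equal S x P = {n}: pose {p.shape}, field {f.shape}"
            )
        if b.shape != (self.schedule.S, 11):
            raise ValueError(f"bias pattern must be (S, 11), got {b.shape}")
        object.__setattr__(self, "pose", p)
        object.__setattr__(self, "field", f)
        object.__setattr__(self, "bias_pattern", b)

    @property
    def n_shots(self) -> int:
        return self.schedule.n_shots

    def pose_at(self, shot: int) -> Pose:
        return Pose(*self.pose[shot])

    def field_at(self, shot: int) -> FieldState:
        return FieldState(*self.field[shot])

    def truth(self) -> np.ndarray:
        """(n_shots, 11) ground-truth parameter series."""
        return np.concatenate([self.pose, self.field], axis=1)

    def prediction_bias(self, shot: int) -> np.ndarray:
        return self.bias_pattern[shot % self.schedule.S]


def make_ets_pattern(S: int, amplitudes, seed: int = 0) -> np.ndarray:
    """Random period-S prediction-bias pattern, zero-mean over the period.

    One fixed random vector per in-plane index, scaled per parameter by
    ``amplitudes`` (scalar or length-11); the same S values repeat every
    partition, emulating the shot-to-shot echo-time-shifting bias.
    """
    if S < 2:
        raise ValueError(f"segmentation factor must be >= 2, got {S}")
    amp = np.broadcast_to(np.asarray(amplitudes, dtype=float), (11,))
    rng = np.random.default_rng(seed)
    pattern = rng.standard_normal((S, 11)) * amp
    return pattern - pattern.mean(axis=0, keepdims=True)


def make_script(
    schedule: ShotSchedule,
    events=(),
    drift_rates=None,
    sinusoids=(),
    bias_amplitudes=0.0,
    noise_sd: float | None = None,
    seed: int = 0,
) -> DisturbanceScript:
    """Compose a disturbance script from standard components.

    events : MotionEvents; drift_rates : per-parameter rates (units/s),
    length 11; sinusoids : (param, amplitude, frequency_hz, phase) tuples
    (respiration-like); bias_amplitudes : per-parameter ETS pattern scale.
    """
    n = schedule.n_shots
    t_s = np.arange(n) * schedule.tr_ms / 1000.0
    series = np.zeros((n, 11))
    idx = {name: i for i, name in enumerate(PARAM_NAMES)}
    for ev in events:
        series[:, idx[ev.param]] += ev.series(n)
    if drift_rates is not None:
        rates = np.broadcast_to(np.asarray(drift_rates, float), (11,))
        series += rates[None, :] * t_s[:, None]
    for param, amp, freq, phase in sinusoids:
        series[:, idx[param]] += amp * np.sin(2 * np.pi * freq * t_s + phase)
    pattern = make_ets_pattern(schedule.S, bias_amplitudes, seed=seed)
    return DisturbanceScript(
        schedule, series[:, :6], series[:, 6:], pattern, noise_sd, seed
    )


def null_scenario(schedule: ShotSchedule, noise_sd: float | None = None, seed: int = 0) -> DisturbanceScript:
    """No disturbance at all: truth identically zero, no bias pattern."""
    return make_script(schedule, noise_sd=noise_sd, seed=seed)


def step_motion_scenario(
    pose_step: Pose = Pose(rx=-1.9, tz=-2.3),
    onset: int = 40,
    schedule: ShotSchedule | None = None,
    noise_sd: float | None = None,
    seed: int = 0,
) -> DisturbanceScript:
    """Abrupt pose step (default Rx = -1.9 deg, Tz = -2.3 mm).

    Emulates a phantom knocked by a stick mid-scan.  Steps beyond the
    ~(2 deg, 2 mm) linear range are allowed but flagged, since open-loop
    estimation degrades there (closed-loop servo correction does not).
    """
    if schedule is None:
        schedule = ShotSchedule(S=30, P=4, tr_ms=43.0)
    if max(abs(np.asarray(pose_step.angles))) > LINEAR_RANGE_DEG or max(
        abs(np.asarray(pose_step.translation))
    ) > LINEAR_RANGE_MM:
        warnings.warn(
            "step exceeds the ~(2 deg, 2 mm) linear range; open-loop estimates "
            "will be biased",
            stacklevel=2,
        )
    events = []
    for name, val in zip(PARAM_NAMES[:6], pose_step.as_array()):
        if val != 0.0:
            events.append(MotionEvent(name, val, onset))
    return make_script(schedule, events=events, noise_sd=noise_sd, seed=seed)


def bottle_scenario(
    f0_step: float = 93.0,
    g_step=(0.0, 0.0, 0.0),
    onset: int = 40,
    schedule: ShotSchedule | None = None,
    noise_sd: float | None = None,
    seed: int = 0,
) -> DisturbanceScript:
    """Step change in field only (frequency and/or gradient offsets).

    Emulates a field disturbance moved toward the object from outside the
    imaging volume; the pose stays fixed.
    """
    if schedule is None:
        schedule = ShotSchedule(S=30, P=4, tr_ms=43.0)
    events = []
    if f0_step != 0.0:
        events.append(MotionEvent("f0", f0_step, onset))
    for name, val in zip(("gx", "gy", "gz"), np.asarray(g_step, float)):
        if val != 0.0:
            events.append(MotionEvent(name, float(val), onset))
    return make_script(schedule, events=events, noise_sd=noise_sd, seed=seed)


@dataclass(frozen=True)
class BiasTransientResult:
    """Parameter-domain bias-correction run under a motion ramp."""

    truth: np.ndarray  # (n,) true motion
    raw: np.ndarray  # (n,) uncorrected predictions
    corrected: np.ndarray  # (n,) bias-corrected predictions (raw before table ready)
    pattern: np.ndarray  # (S,) bias pattern
    onset: int
    motion_end: int
    peak_deviation: float  # max |corrected - truth| after onset
    persistence_shots: int  # last above-noise deviation after motion end
    manifest: dict


def bias_transient_scenario(
    magnitude: float = 2.0,
    interval: int = 48,
    S: int = 48,
    noise_sd: float = 0.01,
    seed: int = 0,
    pattern_amplitude: float = 0.05,
    onset_partition: int = 8,
    n_partitions: int | None = None,
) -> BiasTransientResult:
    """Sliding-window bias correction under a linear motion ramp.

    Predictions of a single translation parameter are simulated directly
    in the parameter domain as truth + period-S bias pattern + Gaussian
    noise; the run-time pipeline (4-partition initialization, per-shot
    subtraction, per-partition sliding update from *uncorrected*
    predictions) is then applied, and the transient the motion leaves in
    the corrected trace is measured.

    magnitude (mm) and interval (shots) outside the studied sets
    {0.5, 1, 2} and {48, 384} are allowed but flagged.
    """
    if magnitude != 0.0 and (magnitude not in (0.5, 1.0, 2.0) or interval not in (48, 384)):
        warnings.warn(
            f"magnitude={magnitude} mm over {interval} shots is outside the "
            "studied conditions {0.5, 1, 2} mm x {48, 384} shots",
            stacklevel=2,
        )
    if onset_partition < WINDOW_PARTITIONS:
        raise ValueError(
            f"motion onset must come after the {WINDOW_PARTITIONS}-partition "
            "bias initialization"
        )
    if n_partitions is None:
        n_partitions = onset_partition + int(np.ceil(interval / S)) + WINDOW_PARTITIONS + 3
    n = n_partitions * S
    onset = onset_partition * S
    motion_end = onset + interval
    if motion_end + WINDOW_PARTITIONS * S > n:
        raise ValueError("run too short to observe the full transient window")

    rng = np.random.default_rng(seed)
    shots = np.arange(n)
    truth = magnitude * np.clip((shots - onset) / interval, 0.0, 1.0) if interval > 0 else np.zeros(n)
    pattern = make_ets_pattern(S, pattern_amplitude, seed=seed)[:, 5]  # one translation axis
    raw = truth + pattern[shots % S] + noise_sd * rng.standard_normal(n)

    corrected = raw.copy()  # first 4 partitions run uncorrected
    table = init_bias(raw[: WINDOW_PARTITIONS * S], S)
    for p in range(WINDOW_PARTITIONS, n_partitions):
        lo, hi = p * S, (p + 1) * S
        for i, shot in enumerate(range(lo, hi)):
            corrected[shot] = float(apply_bias_correction(np.array([raw[shot]]), table, i)[0])
        table = slide_bias(table, raw[lo:hi])

    dev = corrected - truth
    # measure from motion onset; with no motion, from the first corrected shot
    start = onset if magnitude != 0.0 else WINDOW_PARTITIONS * S
    peak = float(np.max(np.abs(dev[start:])))
    # persistence: last shot after motion end whose deviation exceeds the
    # pre-onset corrected noise floor
    pre = dev[WINDOW_PARTITIONS * S : onset]
    floor = float(np.std(pre)) if pre.size else 0.0
    thresh = max(6.0 * floor, 1e-12)
    above = np.nonzero(np.abs(dev[motion_end:]) > thresh)[0]
    persistence = int(above[-1] + 1) if above.size else 0
    manifest = dict(
        magnitude_mm=magnitude,
        interval_shots=interval,
        S=S,
        noise_sd=noise_sd,
        pattern_amplitude=pattern_amplitude,
        onset_shot=onset,
        n_shots=n,
        seed=seed,
        window_partitions=WINDOW_PARTITIONS,
    )
    return BiasTransientResult(
        truth, raw, corrected, pattern, onset, motion_end, peak, persistence, manifest
    )
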