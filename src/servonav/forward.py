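"""Forward model: multi-channel navigator signals under motion and field offsets.

For object pose (R, T), field state (phi0, f0, g) and trajectory sample
(k_i, t_i) the noise-free signal on channel c is

    s_c,i = S_c(R^T k_eff,i) * exp(-i k_eff,i . T)
            * exp(i (phi0 + 2 pi f0 t_i))

where S_c is the coil-weighted static phantom spectrum and

    k_eff,i = k_i - 2 pi gamma_bar g t_i

is the nominal sample shifted by the k accrued under a constant gradient
offset g (the sign matches the +i 2 pi f0 t convention of the
zeroth-order term: both are the spatially-constant and linear parts of
the same off-resonance phase).  A rotated object is equivalent to
evaluating the static spectrum at R^T k; a translated object multiplies
by the linear phase ramp.  No relaxation or intra-object off-resonance is
modeled during the short (~2.3 ms) readout: the navigator is treated as
an encoding-only probe.

Complex Gaussian noise is i.i.d. across channels and samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import GAMMA_BAR_HZ_PER_T, FieldState, Pose
from .phantom import CoilModel, EllipsoidPhantom, ellipsoid_ft
from .trajectory import NavigatorTrajectory

__all__ = [
    "Protocol",
    "PROTOCOLS",
    "ShotSchedule",
    "NavigatorSignal",
    "simulate_navigator",
    "reference_pair",
    "signal_to_hdf5",
    "signal_from_hdf5",
]

# Gradient offsets enter as a time-proportional k-shift with this sign.
# Fixed once; consistency with the estimator is guaranteed because the
# calibration shots are simulated with the same convention.
K_GRAD_SIGN = -1.0


@dataclass(frozen=True)
class Protocol:
    """Named protocol constants of the segmented 3D-EPI host sequence."""

    name: str
    tr_ms: float
    segmentation: int  # S, in-plane segments per partition
    pe_bandwidth_hz_per_mm: float

    @property
    def threshold_frequency_hz(self) -> float:
        """High-pass threshold 1/(TR x S) in Hz used by the precision metric."""
        return 1000.0 / (self.tr_ms * self.segmentation)

    def window_duration_s(self, window_shots: int) -> float:
        """Duration (s) of a moving-average window of the given shot count."""
        return window_shots * self.tr_ms / 1000.0

    def ramp_velocity(self, magnitude: float, duration_shots: int) -> float:
        """Velocity (units/s) of a linear ramp of given magnitude and length."""
        return magnitude / (duration_shots * self.tr_ms / 1000.0)


#: Protocol presets (segmented 3D-EPI at 0.3 mm iso): I = 7 T, II = 11.7 T.
PROTOCOLS = {
    "I": Protocol("I", tr_ms=54.1, segmentation=48, pe_bandwidth_hz_per_mm=93.0),
    "II": Protocol("II", tr_ms=43.0, segmentation=30, pe_bandwidth_hz_per_mm=120.0),
}


@dataclass(frozen=True)
class ShotSchedule:
    """Shot ordering of the segmented acquisition.

    S in-plane segments per partition, P partitions, one navigator per
    shot every TR.  The in-plane index cycles with period S (shot n maps
    to in-plane index n % S, partition n // S), which is what makes the
    echo-time-shifting bias pattern periodic with period S.
    """

    S: int
    P: int
    tr_ms: float

    def __post_init__(self):
        if self.S < 1 or self.P < 1 or self.tr_ms <= 0:
            raise ValueError("need S >= 1, P >= 1, TR > 0")

    @property
    def n_shots(self) -> int:
        return self.S * self.P

    def in_plane(self, shot: int) -> int:
        return shot % self.S

    def partition(self, shot: int) -> int:
        return shot // self.S

    def time_ms(self, shot: int) -> float:
        return shot * self.tr_ms

    @classmethod
    def from_protocol(cls, protocol: Protocol, partitions: int) -> "ShotSchedule":
        return cls(protocol.segmentation, partitions, protocol.tr_ms)


@dataclass(frozen=True)
class NavigatorSignal:
    """Complex (channels x samples) navigator data plus shot metadata."""

    data: np.ndarray
    t_ms: np.ndarray
    shot_index: int = 0
    in_plane: int = 0
    partition: int = 0
    acq_time_ms: float = 0.0

    def __post_init__(self):
        d = np.asarray(self.data, dtype=complex)
        t = np.asarray(self.t_ms, dtype=float)
        if d.ndim != 2 or d.shape[1] != t.shape[0]:
            raise ValueError(f"data {d.shape} inconsistent with timestamps {t.shape}")
        if not np.all(np.isfinite(d.view(float))):
            raise ValueError("non-finite signal entries")
        object.__setattr__(self, "data", d)
        object.__setattr__(self, "t_ms", t)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def _coil_ellipsoid_weights(ph: EllipsoidPhantom, coil: CoilModel) -> np.ndarray:
    """(channels x ellipsoids) complex sensitivity weights at ellipsoid centers."""
    w = np.empty((coil.n_channels, len(ph.ellipsoids)), dtype=complex)
    for c in range(coil.n_channels):
        for j, e in enumerate(ph.ellipsoids):
            w[c, j] = coil.sensitivity(c, np.asarray(e.center, float))
    return w


def simulate_navigator(
    ph: EllipsoidPhantom,
    coil: CoilModel,
    tr: NavigatorTrajectory,
    pose: Pose = Pose(),
    field: FieldState = FieldState(),
    noise_sd: float = 0.0,
    seed: int | None = None,
    shot_index: int = 0,
    schedule: ShotSchedule | None = None,
) -> NavigatorSignal:
    """Synthesize one navigator shot for the given object pose and field state.

    noise_sd is the per-component standard deviation of the additive
    complex Gaussian noise; the realization is reproducible from ``seed``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    t_s = tr.t_ms[:, None] * 1e-3  # (N,1) s
    g_t_per_m = field.g * 1e-6
    k_eff = tr.k + K_GRAD_SIGN * 2.0 * np.pi * GAMMA_BAR_HZ_PER_T * g_t_per_m * t_s
    r = pose.matrix()
    k_body = k_eff @ r  # row-wise R^T k_eff
    # per-ellipsoid spectra at the body-frame k, then coil weighting
    spectra = np.stack(
        [ellipsoid_ft(e, k_body) for e in ph.ellipsoids], axis=0
    )  # (E, N)
    weights = _coil_ellipsoid_weights(ph, coil)  # (C, E)
    data = weights @ spectra  # (C, N)
    t_m = pose.translation * 1e-3
    data = data * np.exp(-1j * (k_eff @ t_m))
    data = data * np.exp(1j * (field.phi0 + 2.0 * np.pi * field.f0 * t_s[:, 0]))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        data = data + noise_sd * (
            rng.standard_normal(data.shape) + 1j * rng.standard_normal(data.shape)
        )
    meta = {}
    if schedule is not None:
        meta = dict(
            in_plane=schedule.in_plane(shot_index),
            partition=schedule.partition(shot_index),
            acq_time_ms=schedule.time_ms(shot_index),
        )
    return NavigatorSignal(data, tr.t_ms, shot_index=shot_index, **meta)


def reference_pair(
    ph: EllipsoidPhantom,
    coil: CoilModel,
    tr: NavigatorTrajectory,
    noise_sd: float = 0.0,
    seeds: tuple[int, int] = (0, 1),
) -> tuple[NavigatorSignal, NavigatorSignal]:
    """Two independent-noise navigator realizations at the reference state.

    Using two separate references decorrelates the noise baked into the
    model columns from the noise in the subtraction baseline, which is
    what removes the parameter-estimation offset a single shared
    reference would create.
    """
    if seeds[0] == seeds[1]:
        raise ValueError(
            "reference seeds must differ: identical noise would defeat the "
            "two-reference design"
        )
    ref1 = simulate_navigator(ph, coil, tr, noise_sd=noise_sd, seed=seeds[0])
    ref2 = simulate_navigator(ph, coil, tr, noise_sd=noise_sd, seed=seeds[1])
    return ref1, ref2


def signal_to_hdf5(sig: NavigatorSignal, path, name: str = "navigator") -> None:
    import h5py

    with h5py.File(path, "a") as f:
        if name in f:
            del f[name]
        grp = f.create_group(name)
        grp.create_dataset("data", data=sig.data)
        grp.create_dataset("t_ms", data=sig.t_ms)
        grp.attrs["shot_index"] = sig.shot_index
        grp.attrs["in_plane"] = sig.in_plane
        grp.attrs["partition"] = sig.partition
        grp.attrs["acq_time_ms"] = sig.acq_time_ms


def signal_from_hdf5(path, name: str = "navigator") -> NavigatorSignal:
    import h5py

    with h5py.File(path, "r") as f:
        grp = f[name]
        return NavigatorSignal(
            grp["data"][()],
            grp["t_ms"][()],
            shot_index=int(grp.attrs["shot_index"]),
            in_plane=int(grp.attrs["in_plane"]),
            partition=int(grp.attrs["partition"]),
            acq_time_ms=float(grp.attrs["acq_time_ms"]),
        )
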