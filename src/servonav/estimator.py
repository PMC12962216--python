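"""Linear perturbation model: calibration and per-shot parameter estimation.

Small rigid-body motion and low-order field changes perturb the navigator
signal linearly (first-order Taylor expansion of the signal equation), so
the 11 parameters [rx, ry, rz, tx, ty, tz, phi0, f0, gx, gy, gz] can be
read off a single navigator shot by multiplying the signal difference to
a second reference with the pseudo-inverse of a calibrated model matrix.

Calibration uses eight shots: two references, three with the trajectory
rotated by 0.5 deg about X, Y, Z, and three with 5 uT/m gradient offsets
on Gx, Gy, Gz.  Rotation and gradient columns come from single-sided
finite differences against the first reference; translation, phase and
frequency columns are analytic:

    d s / d T_j  = -i k_j s          (per mm, k in rad/mm)
    d s / d phi0 =  i s              (per rad)
    d s / d f0   =  i 2 pi t s       (per Hz, t in s)

A trajectory rotation by +delta is signal-equivalent to an object
rotation by -delta (the sampled spectrum is the static one at R k versus
R^T k), so the finite difference is divided by -delta to express the
column per unit of *object* rotation; the estimator then recovers an
injected object rotation with the correct sign.

Complex rows are split into stacked real and imaginary parts so the
least-squares problem is real; the pseudo-inverse uses an SVD with
relative cutoff 1e-10.  Estimates are differences to the *second*
reference, which keeps the estimator unbiased under calibration noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ParameterVector, Pose, FieldState, PARAM_NAMES
from .phantom import CoilModel, EllipsoidPhantom
from .trajectory import NavigatorTrajectory, rotate_trajectory
from .forward import NavigatorSignal, simulate_navigator, reference_pair

__all__ = [
    "CalibrationSet",
    "LinearModel",
    "acquire_calibration",
    "build_model",
    "estimate",
    "conditioning_report",
    "noise_sd_for_floor",
    "save_model",
    "load_model",
]

SVD_RCOND = 1e-10
DEFAULT_ROT_DELTA_DEG = 0.5
DEFAULT_GRAD_DELTA_UT_M = 5.0


@dataclass(frozen=True)
class CalibrationSet:
    """The eight calibration shots and their perturbation deltas."""

    ref1: NavigatorSignal
    ref2: NavigatorSignal
    rot_shots: tuple  # 3 NavigatorSignals, trajectory rotated about X, Y, Z
    rot_delta_deg: float
    grad_shots: tuple  # 3 NavigatorSignals, gradient offset on Gx, Gy, Gz
    grad_delta_ut_m: float

    def __post_init__(self):
        if len(self.rot_shots) != 3 or len(self.grad_shots) != 3:
            raise ValueError("calibration needs 3 rotation and 3 gradient shots")
        if self.rot_delta_deg == 0 or self.grad_delta_ut_m == 0:
            raise ValueError("perturbation deltas must be nonzero")


@dataclass(frozen=True)
class LinearModel:
    """Calibrated sensitivity matrix, its pseudo-inverse and second reference."""

    A: np.ndarray  # (2*C*N, 11) real
    A_pinv: np.ndarray  # (11, 2*C*N)
    s_ref2: NavigatorSignal
    t_ms: np.ndarray
    singular_values: np.ndarray
    param_names: tuple = PARAM_NAMES

    @property
    def rank(self) -> int:
        sv = self.singular_values
        return int(np.sum(sv > SVD_RCOND * sv[0]))


def _stack(x: np.ndarray) -> np.ndarray:
    """Stack a complex (C, N) array into a real vector [Re; Im]."""
    x = np.asarray(x)
    return np.concatenate([x.real.ravel(), x.imag.ravel()])


def acquire_calibration(
    ph: EllipsoidPhantom,
    coil: CoilModel,
    tr: NavigatorTrajectory,
    noise_sd: float = 0.0,
    seed: int = 0,
    rot_delta_deg: float = DEFAULT_ROT_DELTA_DEG,
    grad_delta_ut_m: float = DEFAULT_GRAD_DELTA_UT_M,
) -> CalibrationSet:
    """Simulate the eight calibration shots.

    Order: ref1, ref2, rotations about X/Y/Z (trajectory rotated by
    +rot_delta), gradient offsets on Gx/Gy/Gz (+grad_delta).
    """
    if rot_delta_deg == 0 or grad_delta_ut_m == 0:
        raise ValueError("perturbation deltas must be nonzero")
    base = int(seed) * 16
    ref1, ref2 = reference_pair(ph, coil, tr, noise_sd, seeds=(base, base + 1))
    rot_shots = []
    for i, axis in enumerate("xyz"):
        dp = Pose(**{f"r{axis}": rot_delta_deg})
        rot_shots.append(
            simulate_navigator(
                ph, coil, rotate_trajectory(tr, dp), noise_sd=noise_sd, seed=base + 2 + i
            )
        )
    grad_shots = []
    for i, axis in enumerate("xyz"):
        fs = FieldState(**{f"g{axis}": grad_delta_ut_m})
        grad_shots.append(
            simulate_navigator(ph, coil, tr, field=fs, noise_sd=noise_sd, seed=base + 5 + i)
        )
    return CalibrationSet(
        ref1, ref2, tuple(rot_shots), rot_delta_deg, tuple(grad_shots), grad_delta_ut_m
    )


def build_model(cal: CalibrationSet, tr: NavigatorTrajectory) -> LinearModel:
    """Assemble the (2 C N) x 11 model matrix and its pseudo-inverse."""
    s1 = cal.ref1.data  # (C, N)
    n_ch, n_s = s1.shape
    for shot in (cal.ref2, *cal.rot_shots, *cal.grad_shots):
        if shot.data.shape != s1.shape:
            raise ValueError("calibration shots have inconsistent dimensions")
    if tr.n_samples != n_s:
        raise ValueError("trajectory length does not match calibration shots")

    cols = []
    # rotations: finite difference, per deg of *object* rotation (see module doc)
    for shot in cal.rot_shots:
        cols.append((shot.data - s1) / (-cal.rot_delta_deg))
    # translations: analytic, per mm (k rad/m -> rad/mm via 1e-3)
    for j in range(3):
        cols.append(-1j * (tr.k[:, j] * 1e-3)[None, :] * s1)
    # phase offset: per rad
    cols.append(1j * s1)
    # frequency offset: per Hz, t in s
    cols.append(1j * 2.0 * np.pi * (tr.t_ms * 1e-3)[None, :] * s1)
    # gradient offsets: finite difference, per uT/m
    for shot in cal.grad_shots:
        cols.append((shot.data - s1) / cal.grad_delta_ut_m)

    a = np.stack([_stack(c) for c in cols], axis=1)  # (2CN, 11)
    u, sv, vt = np.linalg.svd(a, full_matrices=False)
    rank = int(np.sum(sv > SVD_RCOND * sv[0]))
    if rank < 11:
        deficient = [PARAM_NAMES[int(np.argmax(np.abs(vt[r])))] for r in range(rank, 11)]
        raise np.linalg.LinAlgError(
            f"model matrix rank {rank} < 11; weakly observable directions involve "
            f"{deficient} (e.g., a symmetric phantom makes rotations unobservable)"
        )
    a_pinv = (vt.T / sv) @ u.T
    return LinearModel(a, a_pinv, cal.ref2, np.asarray(tr.t_ms, float), sv)


def estimate(m: LinearModel, s: NavigatorSignal) -> ParameterVector:
    """Estimate the 11 parameters from one navigator shot.

    theta = A+ . stack(s - s_ref2).
    """
    if s.data.shape != m.s_ref2.data.shape:
        raise ValueError(
            f"signal shape {s.data.shape} incompatible with model {m.s_ref2.data.shape}"
        )
    theta = m.A_pinv @ _stack(s.data - m.s_ref2.data)
    return ParameterVector.from_array(theta)


def conditioning_report(m: LinearModel, noise_sd: float) -> np.ndarray:
    """Predicted per-parameter noise standard deviations.

    Propagates i.i.d. complex Gaussian input noise (per-component sd
    noise_sd) through the pseudo-inverse: sigma_p = ||row_p(A+)|| x
    noise_sd (the real/imag stacking makes each real row entry carry sd
    noise_sd).  This is the precision floor the servo loop can reach in
    the absence of systematic bias.
    """
    if m.rank < 11:
        raise np.linalg.LinAlgError("conditioning report requires a full-rank model")
    return np.linalg.norm(m.A_pinv, axis=1) * float(noise_sd)


def noise_sd_for_floor(
    m: LinearModel, rot_floor_deg: float = 5e-3, trans_floor_mm: float = 2e-3
) -> float:
    """Largest signal noise sd keeping the predicted parameter floors.

    Chooses noise_sd so every rotation parameter's predicted sd is at most
    rot_floor_deg and every translation's at most trans_floor_mm.
    """
    per_unit = np.linalg.norm(m.A_pinv, axis=1)  # sd per unit noise_sd
    bounds = []
    for i in range(3):
        bounds.append(rot_floor_deg / per_unit[i])
    for i in range(3, 6):
        bounds.append(trans_floor_mm / per_unit[i])
    return float(min(bounds))


def save_model(m: LinearModel, path) -> None:
    import h5py

    from .forward import signal_to_hdf5

    with h5py.File(path, "w") as f:
        f.create_dataset("A", data=m.A)
        f.create_dataset("A_pinv", data=m.A_pinv)
        f.create_dataset("t_ms", data=m.t_ms)
        f.create_dataset("singular_values", data=m.singular_values)
        f.attrs["param_names"] = ",".join(m.param_names)
    signal_to_hdf5(m.s_ref2, path, name="s_ref2")


def load_model(path) -> LinearModel:
    import h5py

    from .forward import signal_from_hdf5

    with h5py.File(path, "r") as f:
        a = f["A"][()]
        a_pinv = f["A_pinv"][()]
        t_ms = f["t_ms"][()]
        sv = f["singular_values"][()]
        names = tuple(f.attrs["param_names"].split(","))
    s_ref2 = signal_from_hdf5(path, name="s_ref2")
    return LinearModel(a, a_pinv, s_ref2, t_ms, sv, names)
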