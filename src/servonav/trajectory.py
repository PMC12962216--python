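"""Orbital navigator trajectory and trapezoid-gradient spectral analytics.

The navigator is a short single-shot 3D k-space readout on a sphere
(default 400 rad/m radius, 2.3 ms duration).  The exact waveform of the
scanner implementation is not reproduced here; the documented stand-in is
three sequential orthogonal great circles (XY, YZ, ZX planes), which
probes every rotation axis and both transverse k-components per axis --
the property that gives the navigator its angular sensitivity.

The trapezoid analytics model the slice-direction phase-encoding rewinder
gradient whose mechanical/eddy-current response perturbs the navigator:
its frequency response is shaped so the first spectral zero lands on the
gradient system's lowest acoustic resonance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Pose

__all__ = [
    "NavigatorTrajectory",
    "TrapezoidGradient",
    "make_orbital",
    "rotate_trajectory",
    "trapezoid_spectrum",
    "align_first_zero",
    "trajectory_to_csv",
    "trajectory_from_csv",
]

DEFAULT_RADIUS = 400.0  # rad/m
DEFAULT_DURATION = 2.3  # ms


@dataclass(frozen=True)
class NavigatorTrajectory:
    """Timed k-space sample locations.

    k : (N, 3) rad/m; t_ms : (N,) ms from excitation, strictly increasing;
    radius : rad/m (|k| = radius on the orbital portion).
    """

    k: np.ndarray
    t_ms: np.ndarray
    radius: float

    def __post_init__(self):
        k = np.asarray(self.k, dtype=float)
        t = np.asarray(self.t_ms, dtype=float)
        if k.ndim != 2 or k.shape[1] != 3 or k.shape[0] != t.shape[0]:
            raise ValueError(f"inconsistent trajectory arrays: k {k.shape}, t {t.shape}")
        if np.any(np.diff(t) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        object.__setattr__(self, "k", k)
        object.__setattr__(self, "t_ms", t)

    @property
    def n_samples(self) -> int:
        return self.k.shape[0]

    @property
    def duration(self) -> float:
        return float(self.t_ms[-1] - self.t_ms[0])

    @property
    def dwell(self) -> float:
        return self.duration / (self.n_samples - 1)


def make_orbital(
    radius: float = DEFAULT_RADIUS,
    duration: float = DEFAULT_DURATION,
    n_samples: int = 96,
) -> NavigatorTrajectory:
    """Three orthogonal great circles on the k-space sphere.

    Equal time per arc, uniform angular sampling, timestamps spanning
    [0, duration].  Each device axis reaches |k_axis| = radius on at least
    one arc.
    """
    if radius <= 0 or duration <= 0:
        raise ValueError("radius and duration must be positive")
    if n_samples < 30:
        raise ValueError(
            f"n_samples = {n_samples} < 30: too few samples to condition an "
            "11-parameter model"
        )
    n_arc = [n_samples // 3] * 3
    for i in range(n_samples - sum(n_arc)):
        n_arc[i] += 1
    arcs = []
    for plane, n in zip(("xy", "yz", "zx"), n_arc):
        theta = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
        c, s = np.cos(theta), np.sin(theta)
        zero = np.zeros(n)
        if plane == "xy":
            arcs.append(np.stack([c, s, zero], axis=1))
        elif plane == "yz":
            arcs.append(np.stack([zero, c, s], axis=1))
        else:
            arcs.append(np.stack([s, zero, c], axis=1))
    k = radius * np.concatenate(arcs, axis=0)
    t = np.linspace(0.0, duration, n_samples)
    return NavigatorTrajectory(k, t, radius)


def rotate_trajectory(tr: NavigatorTrajectory, dp: Pose) -> NavigatorTrajectory:
    """Rotate every sample location by the rotation part of ``dp``.

    The translation part of the pose is ignored (a trajectory has no
    position); timestamps and radius are preserved.
    """
    r = dp.matrix()
    return NavigatorTrajectory(tr.k @ r.T, tr.t_ms, tr.radius)


@dataclass(frozen=True)
class TrapezoidGradient:
    """Trapezoidal gradient lobe: amplitude (mT/m), ramp and flat-top (ms)."""

    amplitude: float
    ramp: float
    flat: float

    def __post_init__(self):
        if self.ramp < 0 or self.flat < 0 or self.ramp + self.flat <= 0:
            raise ValueError(
                f"need ramp >= 0, flat >= 0, ramp + flat > 0; got ramp={self.ramp}, flat={self.flat}"
            )

    @property
    def area(self) -> float:
        """Gradient moment (mT/m * ms): amplitude x (flat + ramp)."""
        return self.amplitude * (self.flat + self.ramp)


def trapezoid_spectrum(g: TrapezoidGradient, f) -> np.ndarray:
    """Fourier spectrum of the trapezoid at frequency f (kHz).

    The trapezoid (ramp-flat-ramp) is the convolution of a rect of width
    flat+ramp with a unit-area rect of width ramp, so the spectrum is
    ``amplitude (flat+ramp) sinc(f (flat+ramp)) sinc(f ramp)`` with
    sinc(x) = sin(pi x)/(pi x).  ramp = 0 reduces to the rect spectrum.
    """
    f = np.asarray(f, dtype=float)
    out = g.amplitude * (g.flat + g.ramp) * np.sinc(f * (g.flat + g.ramp)) * np.sinc(f * g.ramp)
    return out if out.size > 1 else float(out)


def align_first_zero(
    g: TrapezoidGradient, f_res: float, rolloff: float = 2.0 / 3.0
) -> TrapezoidGradient:
    """Reshape the trapezoid so its first spectral zero sits at f_res (kHz).

    Solves flat + ramp = 1/f_res with roll-off factor ramp/flat = rolloff,
    rescaling the amplitude to preserve the gradient moment (area).  Used
    to park the lowest acoustic resonance of the gradient chain on a
    spectral null and (via the roll-off) suppress side lobes.
    """
    if f_res <= 0:
        raise ValueError("resonance frequency must be positive")
    if not 0 < rolloff <= 1:
        raise ValueError(f"roll-off factor must be in (0, 1], got {rolloff}")
    total = 1.0 / f_res
    flat = total / (1.0 + rolloff)
    ramp = rolloff * flat
    if flat <= 0 or ramp < 0:
        raise ValueError("infeasible trapezoid durations")
    amplitude = g.area / total
    return TrapezoidGradient(amplitude, ramp, flat)


def trajectory_to_csv(tr: NavigatorTrajectory, path) -> None:
    """Write the trajectory as CSV with columns t_ms, kx, ky, kz."""
    import pandas as pd

    df = pd.DataFrame(
        {"t_ms": tr.t_ms, "kx": tr.k[:, 0], "ky": tr.k[:, 1], "kz": tr.k[:, 2]}
    )
    df.to_csv(path, index=False)


def trajectory_from_csv(path, radius: float | None = None) -> NavigatorTrajectory:
    """Read a trajectory from CSV (columns t_ms, kx, ky, kz)."""
    import pandas as pd

    df = pd.read_csv(path)
    k = df[["kx", "ky", "kz"]].to_numpy(float)
    if radius is None:
        radius = float(np.max(np.linalg.norm(k, axis=1)))
    return NavigatorTrajectory(k, df["t_ms"].to_numpy(float), radius)
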