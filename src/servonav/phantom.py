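"""Analytic ellipsoid phantom with closed-form k-space signal.

A uniform ellipsoid has an analytic 3D Fourier transform, so the
navigator signal of a multi-ellipsoid phantom can be evaluated exactly at
arbitrary k-space locations -- no gridding, no FFT, no discretization
error.  Synthetic multi-channel coil sensitivities are modeled as
low-order spatial polynomials and folded in as per-ellipsoid complex
weights (sensitivity evaluated at the ellipsoid center).  That
piecewise-constant approximation keeps the forward model closed-form
while still giving the channels distinct spatial weightings, which is
what conditions the rotation/translation estimates.

Fourier convention: ``s(k) = integral rho(r) exp(-i k.r) dr`` with k in
rad/m and r in m.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import Pose

__all__ = [
    "Ellipsoid",
    "EllipsoidPhantom",
    "CoilModel",
    "ellipsoid_ft",
    "phantom_signal_at_k",
    "default_head_phantom",
    "rasterize",
]


@dataclass(frozen=True)
class Ellipsoid:
    """Uniform ellipsoid: center (mm), semi-axes (mm, >0), orientation, complex amplitude."""

    center: tuple = (0.0, 0.0, 0.0)
    semi_axes: tuple = (1.0, 1.0, 1.0)
    rotation: Pose = field(default_factory=Pose)
    amplitude: complex = 1.0 + 0.0j

    def __post_init__(self):
        if not np.all(np.asarray(self.semi_axes, float) > 0):
            raise ValueError(f"semi-axes must be strictly positive, got {self.semi_axes}")
        if not np.isfinite(self.amplitude):
            raise ValueError("amplitude must be finite")

    @property
    def volume_m3(self) -> float:
        a = np.asarray(self.semi_axes, float) * 1e-3
        return float(4.0 / 3.0 * np.pi * np.prod(a))


@dataclass(frozen=True)
class EllipsoidPhantom:
    """Non-empty collection of ellipsoids inside a bounding sphere (mm)."""

    ellipsoids: tuple
    bounding_radius: float = 100.0

    def __post_init__(self):
        if len(self.ellipsoids) == 0:
            raise ValueError("phantom must contain at least one ellipsoid")
        for e in self.ellipsoids:
            extent = np.linalg.norm(e.center) + max(e.semi_axes)
            if extent > self.bounding_radius + 1e-9:
                raise ValueError(
                    f"ellipsoid at {e.center} (extent {extent:.1f} mm) exceeds "
                    f"bounding radius {self.bounding_radius} mm"
                )

    def translated(self, t_mm) -> "EllipsoidPhantom":
        """Phantom with every ellipsoid shifted by t (mm)."""
        t = np.asarray(t_mm, float)
        return EllipsoidPhantom(
            tuple(
                Ellipsoid(tuple(np.asarray(e.center) + t), e.semi_axes, e.rotation, e.amplitude)
                for e in self.ellipsoids
            ),
            self.bounding_radius + float(np.linalg.norm(t)),
        )


def _sphere_kernel(kappa: np.ndarray) -> np.ndarray:
    """3(sin k - k cos k)/k^3, the unit-sphere form factor, stable near 0."""
    kappa = np.asarray(kappa, dtype=float)
    out = np.empty_like(kappa)
    small = np.abs(kappa) < 1e-3
    ks = kappa[small]
    # Taylor series: 1 - k^2/10 + k^4/280
    out[small] = 1.0 - ks**2 / 10.0 + ks**4 / 280.0
    kl = kappa[~small]
    out[~small] = 3.0 * (np.sin(kl) - kl * np.cos(kl)) / kl**3
    return out


def ellipsoid_ft(e: Ellipsoid, k) -> np.ndarray:
    """Closed-form FT of a uniform ellipsoid at k (rad/m; shape (...,3)).

    Returns ``amplitude * V * 3(sin K - K cos K)/K^3 * exp(-i k.c)`` with
    ``K = |diag(semi_axes) R^T k|`` (semi-axes and center in meters, R the
    ellipsoid's orientation matrix).
    """
    k = np.atleast_2d(np.asarray(k, dtype=float))
    axes_m = np.asarray(e.semi_axes, float) * 1e-3
    center_m = np.asarray(e.center, float) * 1e-3
    r = e.rotation.matrix()
    k_body = k @ r  # row-wise R^T k
    kappa = np.linalg.norm(k_body * axes_m, axis=-1)
    phase = np.exp(-1j * (k @ center_m))
    out = e.amplitude * e.volume_m3 * _sphere_kernel(kappa) * phase
    return out if out.size > 1 else out.reshape(())


@dataclass(frozen=True)
class CoilModel:
    """Synthetic receive array: per-channel low-order polynomial sensitivities.

    Each channel's complex sensitivity over the bounding sphere is
    ``sum_j c_j * b_j(r / R)`` with monomial basis b up to order 2 in the
    normalized coordinates.  Emulates a multi-channel head array at a
    configurable channel count.
    """

    coeffs: np.ndarray  # (n_channels, 10) complex
    reference_radius: float = 100.0  # mm

    # monomial exponents for (1, x, y, z, x^2, y^2, z^2, xy, xz, yz)
    _EXP = np.array(
        [
            [0, 0, 0],
            [1, 0, 0],
            [0, 1, 0],
            [0, 0, 1],
            [2, 0, 0],
            [0, 2, 0],
            [0, 0, 2],
            [1, 1, 0],
            [1, 0, 1],
            [0, 1, 1],
        ]
    )

    def __post_init__(self):
        c = np.atleast_2d(np.asarray(self.coeffs, dtype=complex))
        if c.shape[0] < 1 or c.shape[1] != 10:
            raise ValueError(f"coeffs must be (n_channels, 10), got {c.shape}")
        if np.all(np.abs(c) == 0):
            raise ValueError("all-zero coil sensitivities")
        object.__setattr__(self, "coeffs", c)

    @property
    def n_channels(self) -> int:
        return self.coeffs.shape[0]

    @classmethod
    def uniform(cls, n_channels: int = 1, reference_radius: float = 100.0) -> "CoilModel":
        """Unit constant sensitivity on every channel."""
        c = np.zeros((n_channels, 10), complex)
        c[:, 0] = 1.0
        return cls(c, reference_radius)

    @classmethod
    def synthetic(
        cls, n_channels: int = 8, reference_radius: float = 100.0, seed: int = 7
    ) -> "CoilModel":
        """Random smooth array: unit mean term plus O(1) linear and quadratic terms."""
        rng = np.random.default_rng(seed)
        c = np.zeros((n_channels, 10), complex)
        c[:, 0] = 1.0 + 0.3 * (rng.standard_normal(n_channels) + 1j * rng.standard_normal(n_channels))
        c[:, 1:4] = 0.6 * (rng.standard_normal((n_channels, 3)) + 1j * rng.standard_normal((n_channels, 3)))
        c[:, 4:] = 0.25 * (rng.standard_normal((n_channels, 6)) + 1j * rng.standard_normal((n_channels, 6)))
        return cls(c, reference_radius)

    def sensitivity(self, channel: int, r_mm) -> np.ndarray:
        """Complex sensitivity of one channel at positions r (mm; shape (...,3))."""
        if not 0 <= channel < self.n_channels:
            raise IndexError(f"channel {channel} out of range [0, {self.n_channels})")
        x = np.atleast_2d(np.asarray(r_mm, float)) / self.reference_radius
        basis = np.prod(x[..., None, :] ** self._EXP, axis=-1)  # (..., 10)
        out = basis @ self.coeffs[channel]
        return out if out.size > 1 else out.reshape(())


def phantom_signal_at_k(
    ph: EllipsoidPhantom, coil: CoilModel, channel: int, k
) -> np.ndarray:
    """Coil-weighted phantom k-space signal at arbitrary k (rad/m).

    Sum over ellipsoids of ``sens_c(center_e) * ellipsoid_ft(e, k)``.
    """
    if not 0 <= channel < coil.n_channels:
        raise IndexError(f"channel {channel} out of range [0, {coil.n_channels})")
    k = np.asarray(k, dtype=float)
    total = None
    for e in ph.ellipsoids:
        w = coil.sensitivity(channel, np.asarray(e.center, float))
        term = w * ellipsoid_ft(e, k)
        total = term if total is None else total + term
    return total


def default_head_phantom() -> EllipsoidPhantom:
    """Five-ellipsoid asymmetric head stand-in.

    One large envelope plus four off-center internal features at mixed
    amplitudes.  The asymmetry is deliberate: a spherically symmetric
    object makes rotations unobservable from k-space magnitude/phase on a
    sphere, so the internal structure is what gives the orbital navigator
    its angular sensitivity.  Amplitudes are scaled so the DC signal is
    order unity.
    """
    a = 500.0  # amplitude scale: envelope volume ~2e-3 m^3 -> DC ~ 1
    ells = (
        Ellipsoid((0.0, 0.0, 0.0), (85.0, 65.0, 75.0), Pose(), a * 1.0),
        Ellipsoid((30.0, 10.0, 20.0), (25.0, 18.0, 22.0), Pose(rz=20.0), a * -0.5),
        Ellipsoid((-25.0, -30.0, 10.0), (15.0, 25.0, 12.0), Pose(rx=10.0), a * 0.8),
        Ellipsoid((10.0, 25.0, -30.0), (18.0, 12.0, 20.0), Pose(ry=-15.0), a * -0.3),
        Ellipsoid((-15.0, 20.0, 35.0), (10.0, 14.0, 8.0), Pose(), a * 0.6),
    )
    return EllipsoidPhantom(ells, bounding_radius=100.0)


def rasterize(ph: EllipsoidPhantom, shape=(64, 64, 64), fov_mm: float = 220.0):
    """Rasterize the phantom to a NIfTI image (RAS+, mm) for inspection.

    Returns a ``nibabel.Nifti1Image`` of the real part of the summed
    amplitudes on a regular grid.
    """
    import nibabel as nib

    shape = tuple(int(n) for n in shape)
    vox = fov_mm / np.asarray(shape, float)
    grids = [
        (np.arange(n) - (n - 1) / 2.0) * v for n, v in zip(shape, vox)
    ]
    xx, yy, zz = np.meshgrid(*grids, indexing="ij")
    pts = np.stack([xx, yy, zz], axis=-1)  # mm
    vol = np.zeros(shape, dtype=float)
    for e in ph.ellipsoids:
        rel = (pts - np.asarray(e.center, float)) @ e.rotation.matrix()
        inside = np.sum((rel / np.asarray(e.semi_axes, float)) ** 2, axis=-1) <= 1.0
        vol[inside] += np.real(e.amplitude)
    affine = np.diag(list(vox) + [1.0])
    affine[:3, 3] = [-(n - 1) / 2.0 * v for n, v in zip(shape, vox)]
    return nib.Nifti1Image(vol.astype(np.float32), affine)
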