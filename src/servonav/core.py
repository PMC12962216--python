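"""Shared units, coordinate conventions and rigid-body pose algebra.

Conventions used throughout the package
---------------------------------------

* Device XYZ is the single internal coordinate frame (scanner device
  coordinates).  Gradient-logical PRS coordinates appear only at the
  :func:`prs_to_xyz` boundary.
* Rotations are extrinsic, about the fixed device axes, applied in the
  order X, then Y, then Z (overall matrix ``Rz @ Ry @ Rx``); angles are
  stored in degrees.  At the sub-2-degree scale relevant to navigator
  tracking the composition order is a second-order effect, but the
  convention is fixed and used consistently everywhere.
* Rotations are about the iso-center (the phantom / trajectory origin).
* Units: rotations deg, translations mm, phase rad, frequency Hz,
  gradient (shim) offsets uT/m, k-space rad/m, time ms unless a suffix
  says otherwise.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "GAMMA_BAR_HZ_PER_T",
    "PARAM_NAMES",
    "PARAM_UNITS",
    "Pose",
    "FieldState",
    "ParameterVector",
    "compose_pose",
    "inverse_pose",
    "pose_from_matrix",
    "prs_to_xyz",
    "quantize_shim",
]

#: Reduced gyromagnetic ratio of 1H in Hz/T.  Single authoritative value
#: used by every field-to-phase conversion in the package.
GAMMA_BAR_HZ_PER_T = 42.5774e6

#: Order of the 11 servo parameters and their units.
PARAM_NAMES = ("rx", "ry", "rz", "tx", "ty", "tz", "phi0", "f0", "gx", "gy", "gz")
PARAM_UNITS = ("deg", "deg", "deg", "mm", "mm", "mm", "rad", "Hz", "uT/m", "uT/m", "uT/m")

#: Index slices into a parameter vector.
ROT_SLICE = slice(0, 3)
TRANS_SLICE = slice(3, 6)
GRAD_SLICE = slice(8, 11)


@dataclass(frozen=True)
class Pose:
    """6-DoF rigid-body state: rotations (deg) and translations (mm).

    The identity pose has all six entries zero.  The transform maps a
    point ``r`` (mm, device frame) to ``R @ r + t`` with ``R`` the
    extrinsic X-Y-Z rotation matrix and ``t`` the translation.
    """

    rx: float = 0.0
    ry: float = 0.0
    rz: float = 0.0
    tx: float = 0.0
    ty: float = 0.0
    tz: float = 0.0

    @classmethod
    def identity(cls) -> "Pose":
        return cls()

    @property
    def angles(self) -> np.ndarray:
        """Rotation angles (deg) as a 3-vector."""
        return np.array([self.rx, self.ry, self.rz], dtype=float)

    @property
    def translation(self) -> np.ndarray:
        """Translation (mm) as a 3-vector."""
        return np.array([self.tx, self.ty, self.tz], dtype=float)

    def rotation(self) -> Rotation:
        return Rotation.from_euler("xyz", self.angles, degrees=True)

    def matrix(self) -> np.ndarray:
        """3x3 rotation matrix (extrinsic X-Y-Z)."""
        return self.rotation().as_matrix()

    def as_array(self) -> np.ndarray:
        return np.array([self.rx, self.ry, self.rz, self.tx, self.ty, self.tz], float)

    def rotation_magnitude(self) -> float:
        """Total rotation angle (deg) of the pose's rotation part."""
        return float(np.degrees(self.rotation().magnitude()))

    def translation_magnitude(self) -> float:
        """Euclidean norm (mm) of the translation part."""
        return float(np.linalg.norm(self.translation))


@dataclass(frozen=True)
class FieldState:
    """Zeroth- and first-order field state.

    phi0 : phase offset (rad); f0 : frequency offset (Hz);
    gx, gy, gz : gradient/shim offsets (uT/m) in device XYZ.
    The zero state modifies the navigator signal not at all.
    """

    phi0: float = 0.0
    f0: float = 0.0
    gx: float = 0.0
    gy: float = 0.0
    gz: float = 0.0

    @property
    def g(self) -> np.ndarray:
        """Gradient offsets (uT/m) as a 3-vector."""
        return np.array([self.gx, self.gy, self.gz], dtype=float)

    def as_array(self) -> np.ndarray:
        return np.array([self.phi0, self.f0, self.gx, self.gy, self.gz], float)


@dataclass(frozen=True)
class ParameterVector:
    """Ordered 11-tuple of servo parameters.

    Layout: ``[rx, ry, rz, tx, ty, tz, phi0, f0, gx, gy, gz]`` with units
    ``(deg, mm, rad, Hz, uT/m)``.  Splits losslessly into a :class:`Pose`
    and a :class:`FieldState`.
    """

    values: tuple

    def __post_init__(self):
        vals = tuple(float(v) for v in np.asarray(self.values, dtype=float).ravel())
        if len(vals) != 11:
            raise ValueError(f"ParameterVector needs exactly 11 entries, got {len(vals)}")
        object.__setattr__(self, "values", vals)

    @classmethod
    def zeros(cls) -> "ParameterVector":
        return cls((0.0,) * 11)

    @classmethod
    def from_parts(cls, pose: Pose, field: FieldState) -> "ParameterVector":
        return cls(tuple(pose.as_array()) + tuple(field.as_array()))

    @classmethod
    def from_array(cls, a) -> "ParameterVector":
        return cls(tuple(np.asarray(a, dtype=float)))

    def as_array(self) -> np.ndarray:
        return np.array(self.values, dtype=float)

    @property
    def pose(self) -> Pose:
        return Pose(*self.values[0:6])

    @property
    def field(self) -> FieldState:
        return FieldState(*self.values[6:11])

    def __getitem__(self, i):
        return self.values[i]

    def __len__(self) -> int:
        return 11


def compose_pose(a: Pose, b: Pose) -> Pose:
    """Pose equivalent to applying ``b`` first, then ``a``.

    Affine composition ``M(a) @ M(b)``: rotation matrices multiply and the
    result is converted back to extrinsic X-Y-Z angles; translations compose
    as ``R_a @ t_b + t_a``.
    """
    ra, rb = a.matrix(), b.matrix()
    r = ra @ rb
    t = ra @ b.translation + a.translation
    return pose_from_matrix(r, t)


def inverse_pose(p: Pose) -> Pose:
    """Pose ``q`` with ``compose_pose(p, q) == identity``."""
    r = p.matrix().T
    return pose_from_matrix(r, -r @ p.translation)


def pose_from_matrix(r: np.ndarray, t=(0.0, 0.0, 0.0)) -> Pose:
    """Build a Pose from a 3x3 rotation matrix and translation (mm)."""
    ang = Rotation.from_matrix(np.asarray(r, float)).as_euler("xyz", degrees=True)
    t = np.asarray(t, dtype=float)
    return Pose(ang[0], ang[1], ang[2], t[0], t[1], t[2])


def _check_orthonormal(m: np.ndarray, tol: float = 1e-6) -> None:
    m = np.asarray(m, dtype=float)
    if m.shape != (3, 3):
        raise ValueError(f"orientation must be 3x3, got shape {m.shape}")
    dev = np.max(np.abs(m.T @ m - np.eye(3)))
    if dev > tol:
        raise ValueError(
            f"orientation matrix is not orthonormal: max |M^T M - I| = {dev:.3e} > {tol:.0e}"
        )


def prs_to_xyz(v: ParameterVector, orientation: np.ndarray) -> ParameterVector:
    """Transform a parameter vector from gradient PRS to device XYZ coordinates.

    The rotation-angle, translation and gradient-offset 3-vectors are each
    mapped through the direction-cosine matrix ``orientation`` (small-angle
    treatment of the rotation triple, valid in the navigator's linear
    range); phi0 and f0 are frame-invariant and pass through unchanged.
    """
    _check_orthonormal(orientation)
    o = np.asarray(orientation, dtype=float)
    a = v.as_array()
    out = a.copy()
    out[ROT_SLICE] = o @ a[ROT_SLICE]
    out[TRANS_SLICE] = o @ a[TRANS_SLICE]
    out[GRAD_SLICE] = o @ a[GRAD_SLICE]
    return ParameterVector.from_array(out)


def quantize_shim(g, increment: float) -> np.ndarray:
    """Snap each gradient-offset component to the shim hardware lattice.

    Each component is replaced by the nearest integer multiple of
    ``increment`` (uT/m); half-increment ties round away from zero, which
    is symmetric under sign flip.  The scanner hardware motivating this
    applies linear shim updates only in discrete steps of ~0.14 uT/m.
    """
    if not increment > 0:
        raise ValueError(f"shim increment must be positive, got {increment}")
    g = np.asarray(g, dtype=float)
    return np.sign(g) * np.floor(np.abs(g) / increment + 0.5) * increment
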