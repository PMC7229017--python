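"""Pose difference between a reference and a test coordinate system.

Translation errors are the components of the test origin in the reference
frame; rotation errors are intrinsic y-x-z Euler angles of the relative
rotation, in degrees. Totals are the quadratic sums of the components (the
rotation total is NOT the geodesic angle and may exceed 180 degrees).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .mesh_core import CoordinateSystem, RigidTransform

__all__ = [
    "PoseError",
    "SummaryStats",
    "cs_to_cs",
    "euler_yxz",
    "pose_error",
    "summarize",
]


@dataclass(frozen=True)
class PoseError:
    dx: float
    dy: float
    dz: float
    phix: float
    phiy: float
    phiz: float
    d_err: float
    phi_err: float

    def __post_init__(self):
        vals = [self.dx, self.dy, self.dz, self.phix, self.phiy, self.phiz,
                self.d_err, self.phi_err]
        if not all(math.isfinite(v) for v in vals):
            raise ValidationError("pose-error components must be finite")
        if abs(self.d_err - math.hypot(self.dx, self.dy, self.dz)) > 1e-9:
            raise ValidationError("d_err does not match its components")
        if abs(self.phi_err - math.hypot(self.phix, self.phiy, self.phiz)) > 1e-9:
            raise ValidationError("phi_err does not match its components")
        if not -90.0 - 1e-9 <= self.phix <= 90.0 + 1e-9:
            raise ValidationError("phix must lie in [-90, 90]")

    @classmethod
    def from_components(cls, dx, dy, dz, phix, phiy, phiz) -> "PoseError":
        return cls(
            dx=float(dx), dy=float(dy), dz=float(dz),
            phix=float(phix), phiy=float(phiy), phiz=float(phiz),
            d_err=math.hypot(dx, dy, dz),
            phi_err=math.hypot(phix, phiy, phiz),
        )

    def as_dict(self) -> dict:
        return {
            "dx": self.dx, "dy": self.dy, "dz": self.dz,
            "phix": self.phix, "phiy": self.phiy, "phiz": self.phiz,
            "d_err": self.d_err, "phi_err": self.phi_err,
        }


@dataclass(frozen=True)
class SummaryStats:
    median: float
    iqr: tuple[float, float]
    min: float
    max: float


def cs_to_cs(reference: CoordinateSystem, test: CoordinateSystem) -> RigidTransform:
    """Rigid transform mapping the reference frame onto the test frame,
    expressed in reference-frame coordinates."""
    r_ref = reference.rotation
    r_test = test.rotation
    if np.array_equal(r_ref, r_test) and np.array_equal(reference.origin, test.origin):
        # identical frames -> exact identity (avoids ~1e-15 round-off angles)
        return RigidTransform.identity()
    return RigidTransform(
        r_ref.T @ r_test,
        r_ref.T @ (test.origin - reference.origin),
    )


def euler_yxz(rotation: np.ndarray) -> tuple[float, float, float]:
    """Decompose a rotation as R = Ry(phiy) Rx(phix) Rz(phiz), intrinsic
    y-x-z; returns (phiy, phix, phiz) in degrees, phix in [-90, 90].

    Gimbal lock (|cos phix| ~ 0): phiz is set to 0 and the remaining
    rotation absorbed into phiy.
    """
    m = np.asarray(rotation, dtype=float).reshape(3, 3)
    if np.abs(m.T @ m - np.eye(3)).max() > 1e-8 or abs(np.linalg.det(m) - 1.0) > 1e-9:
        raise ValidationError("input is not a proper rotation matrix")
    sx = -m[1, 2]
    sx = min(1.0, max(-1.0, sx))
    phix = math.asin(sx)
    if abs(math.cos(phix)) < 1e-9:
        phiz = 0.0
        # with phiz = 0: m[0,0] = cos(phiy), m[0,1] = sin(phiy)*sin(phix)
        phiy = math.atan2(sx * m[0, 1], m[0, 0])
    else:
        phiy = math.atan2(m[0, 2], m[2, 2])
        phiz = math.atan2(m[1, 0], m[1, 1])
    return math.degrees(phiy), math.degrees(phix), math.degrees(phiz)


def compose_yxz(phiy: float, phix: float, phiz: float) -> np.ndarray:
    """Inverse of :func:`euler_yxz`: build Ry(phiy) Rx(phix) Rz(phiz), degrees."""
    ay, ax, az = (math.radians(a) for a in (phiy, phix, phiz))
    cy, sy = math.cos(ay), math.sin(ay)
    cx, sx = math.cos(ax), math.sin(ax)
    cz, sz = math.cos(az), math.sin(az)
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return ry @ rx @ rz


def pose_error(reference: CoordinateSystem, test: CoordinateSystem) -> PoseError:
    """Full pose error of ``test`` relative to ``reference`` (CS100 -> CSx)."""
    t = cs_to_cs(reference, test)
    phiy, phix, phiz = euler_yxz(t.rotation)
    dx, dy, dz = t.translation
    return PoseError.from_components(dx, dy, dz, phix, phiy, phiz)


def summarize(values) -> SummaryStats:
    """Median, quartiles (linear-interpolation rule), min and max."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValidationError("cannot summarize an empty list")
    q1, med, q3 = np.quantile(arr, [0.25, 0.5, 0.75])
    return SummaryStats(
        median=float(med), iqr=(float(q1), float(q3)),
        min=float(arr.min()), max=float(arr.max()),
    )
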