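"""Automatic anatomical coordinate-system placement on (partial) radius meshes.

The algorithm derives a longitudinal axis from the inertia tensor of the mesh
vertices, orients it distally using a scan-direction hint, moves the axis to
the centroid of the distal portion of the bone, drops the origin onto the
distal articular surface, and points the x-axis at the styloid process.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    AmbiguousAxisError,
    DegenerateGeometryError,
    OrientationAmbiguousError,
    PlacementError,
    ValidationError,
)
from .mesh_core import CoordinateSystem, TriMesh, _as_unit, extent_along

__all__ = [
    "InertiaResult",
    "PlacementTrace",
    "inertia_tensor",
    "long_axis",
    "orient_z",
    "distal_window",
    "styloid_point",
    "place_rcs",
    "DEFAULT_DISTAL_FRAC",
    "DEFAULT_DISTAL_MIN_LEN_MM",
]

DEFAULT_DISTAL_FRAC = 0.15
DEFAULT_DISTAL_MIN_LEN_MM = 20.0
_EIG_GAP_TOL = 1e-6


@dataclass(frozen=True)
class InertiaResult:
    """Inertia tensor of a unit-mass point cloud about its centroid."""

    tensor: np.ndarray  # 3x3 symmetric, mm^2 * point-mass
    eigenvalues: np.ndarray  # ascending
    eigenvectors: np.ndarray  # columns matched to eigenvalues, orthonormal
    centroid: np.ndarray


@dataclass(frozen=True)
class PlacementTrace:
    """Intermediate state of :func:`place_rcs`, for diagnostics."""

    temp_axes: CoordinateSystem
    distal_window: tuple[float, float]
    distal_centroid: np.ndarray
    styloid_point: np.ndarray
    styloid_index: int
    origin_mode: str  # "ray" or "vertex"
    final: CoordinateSystem


def inertia_tensor(points) -> InertiaResult:
    """Inertia tensor sum_i (|r_i|^2 I - r_i r_i^T), r_i about the centroid,
    with unit mass per point; eigen-decomposition sorted ascending."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValidationError("points must be an (n, 3) array")
    if len(pts) < 4:
        raise ValidationError("need at least 4 points")
    centroid = pts.mean(axis=0)
    r = pts - centroid
    scatter = r.T @ r
    sw = np.linalg.eigvalsh(scatter)
    if sw[1] <= 1e-12 * max(sw[2], 1.0):
        raise DegenerateGeometryError("points are coincident or collinear")
    tensor = np.trace(scatter) * np.eye(3) - scatter
    w, v = np.linalg.eigh(tensor)
    return InertiaResult(tensor=tensor, eigenvalues=w, eigenvectors=v, centroid=centroid)


def long_axis(inertia: InertiaResult) -> np.ndarray:
    """Eigenvector of the smallest inertia eigenvalue = the elongation axis.

    Sign is unresolved at this stage; see :func:`orient_z`.
    """
    w = inertia.eigenvalues
    scale = max(float(w[2]), 1e-300)
    if (w[1] - w[0]) / scale <= _EIG_GAP_TOL:
        raise AmbiguousAxisError(
            "two smallest inertia eigenvalues are nearly equal; "
            "object is not elongated enough for a unique long axis"
        )
    return inertia.eigenvectors[:, 0].copy()


def orient_z(axis, global_up) -> np.ndarray:
    """Resolve the +/- sign of the long axis toward the global 'distal' hint."""
    axis = _as_unit(axis, "axis")
    global_up = _as_unit(global_up, "global_up")
    d = float(axis @ global_up)
    if abs(d) < 1e-12:
        raise OrientationAmbiguousError("axis is exactly perpendicular to global_up")
    return axis if d > 0 else -axis


def distal_window(
    mesh: TriMesh,
    z_axis,
    frac: float = DEFAULT_DISTAL_FRAC,
    min_len_mm: float = DEFAULT_DISTAL_MIN_LEN_MM,
) -> tuple[float, float]:
    """Projection bounds of the distal window: ``frac`` of the available
    length but at least ``min_len_mm``, clamped to what is available."""
    z_axis = _as_unit(z_axis, "z_axis")
    _, hi, length = extent_along(mesh, z_axis)
    w = min(max(frac * length, min_len_mm), length)
    return hi - w, hi


def styloid_point(mesh: TriMesh, z_axis) -> np.ndarray:
    """Mesh vertex with the largest projection onto ``z_axis`` (ties -> lowest index)."""
    z_axis = _as_unit(z_axis, "z_axis")
    idx = int(np.argmax(mesh.vertices @ z_axis))
    return mesh.vertices[idx].copy()


def _ray_surface_hit(mesh: TriMesh, origin: np.ndarray, direction: np.ndarray):
    """Most distal intersection of ray origin + t*direction (t >= 0) with the
    mesh triangles (vectorised Moeller-Trumbore). Returns point or None."""
    v0, v1, v2 = mesh.triangle_corners()
    e1 = v1 - v0
    e2 = v2 - v0
    h = np.cross(direction, e2)
    a = np.einsum("ij,ij->i", e1, h)
    ok = np.abs(a) > 1e-12
    inv = np.where(ok, 1.0 / np.where(ok, a, 1.0), 0.0)
    sv = origin - v0
    u = inv * np.einsum("ij,ij->i", sv, h)
    q = np.cross(sv, e1)
    vv = inv * (q @ direction)
    t = inv * np.einsum("ij,ij->i", e2, q)
    eps = 1e-9
    hit = ok & (u >= -eps) & (vv >= -eps) & (u + vv <= 1 + eps) & (t >= -eps)
    if not hit.any():
        return None
    tmax = float(t[hit].max())
    return origin + tmax * direction


def place_rcs(
    mesh: TriMesh,
    global_up=(0.0, 0.0, 1.0),
    distal_frac: float = DEFAULT_DISTAL_FRAC,
    distal_min_len_mm: float = DEFAULT_DISTAL_MIN_LEN_MM,
) -> tuple[CoordinateSystem, PlacementTrace]:
    """Place the anatomical coordinate system on a (partial) radius mesh.

    Steps: inertia tensor of the vertices; z = distally oriented smallest-
    eigenvalue axis; distal window along z; translate the z line to the
    window centroid; origin = most distal surface intersection of that line
    (fallback: most distal vertex within 2 mm of the line); x = unit
    rejection of (styloid - origin) off z; y = z cross x.

    The computation is frame-independent, so the result commutes with rigid
    motions that keep the bone axis within 90 degrees of ``global_up``.
    """
    global_up = _as_unit(global_up, "global_up")
    inertia = inertia_tensor(mesh.vertices)
    z = orient_z(long_axis(inertia), global_up)

    # temporary inertial frame (diagnostic only): remaining eigenvectors
    x_t = inertia.eigenvectors[:, 2]
    x_t = x_t - (x_t @ z) * z
    x_t = x_t / np.linalg.norm(x_t)
    temp = CoordinateSystem(inertia.centroid, x_t, np.cross(z, x_t), z)

    lo, hi = distal_window(mesh, z, distal_frac, distal_min_len_mm)
    s = mesh.vertices @ z
    in_window = s >= lo
    if not in_window.any():
        raise PlacementError("distal-window", "no vertices in the distal window")
    c = mesh.vertices[in_window].mean(axis=0)

    origin = _ray_surface_hit(mesh, c, z)
    origin_mode = "ray"
    if origin is None:
        perp = (mesh.vertices - c) - np.outer(s - c @ z, z)
        near = np.linalg.norm(perp, axis=1) <= 2.0
        if not near.any():
            raise PlacementError(
                "origin", "z line misses the surface and no vertex lies within 2 mm"
            )
        cand = np.where(near)[0]
        origin = mesh.vertices[cand[np.argmax(s[cand])]].copy()
        origin_mode = "vertex"

    sty_idx = int(np.argmax(s))
    styloid = mesh.vertices[sty_idx]
    xr = (styloid - origin) - ((styloid - origin) @ z) * z
    n = np.linalg.norm(xr)
    if n < 1e-9:
        raise PlacementError("styloid", "styloid lies on the z-axis; x direction undefined")
    x = xr / n
    cs = CoordinateSystem(origin, x, np.cross(z, x), z)
    trace = PlacementTrace(
        temp_axes=temp,
        distal_window=(lo, hi),
        distal_centroid=c,
        styloid_point=styloid.copy(),
        styloid_index=sty_idx,
        origin_mode=origin_mode,
        final=cs,
    )
    return cs, trace
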