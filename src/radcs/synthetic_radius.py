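"""Synthetic radius-like meshes with known ground-truth coordinate systems.

Stands in for clinical CT segmentations: a curved, tapered shaft with a
distal metaphyseal flare and a styloid process offset in a configurable
direction. Also provides segmentation-noise emulation (vertex jitter along
normals) and a stochastic simulator of manual (observer) placement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import GenerationError, ValidationError
from .mesh_core import CoordinateSystem, RigidTransform, TriMesh, apply_rigid

__all__ = [
    "RadiusShapeParams",
    "GroundTruth",
    "ManualNoiseModel",
    "CohortBone",
    "generate_radius",
    "generate_cohort",
    "segmentation_jitter",
    "simulate_manual_placement",
    "DEFAULT_VARIATION",
    "DEFAULT_MANUAL_NOISE",
]

_TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class RadiusShapeParams:
    """Parametric description of one synthetic radius (canonical frame:
    shaft chord along +z, proximal end at the origin)."""

    total_length: float = 230.0  # mm, arc length of the shaft midline
    shaft_radius_proximal: float = 8.0  # mm
    shaft_radius_distal: float = 10.0  # mm (before flare)
    bow_angle: float = 6.0  # degrees subtended by the midline arc (bulge +x)
    flare_scale: float = 1.45  # distal metaphysis widening factor
    styloid_height: float = 11.0  # mm
    styloid_offset_dir: tuple[float, float] = (1.0, 0.0)  # unit 2-vector, x-y plane
    vertex_spacing: float = 2.2  # mm, target uniform surface sampling
    seed: int = 0

    def validate(self) -> None:
        if self.total_length <= 0:
            raise ValidationError("total_length must be > 0")
        if self.shaft_radius_proximal <= 0 or self.shaft_radius_distal <= 0:
            raise ValidationError("shaft radii must be > 0")
        if self.styloid_height < 0:
            raise ValidationError("styloid_height must be >= 0")
        if self.vertex_spacing <= 0:
            raise ValidationError("vertex_spacing must be > 0")
        if np.hypot(*self.styloid_offset_dir) < 1e-9:
            raise ValidationError("styloid_offset_dir must be non-zero")
        # crude self-intersection guards
        if not 0 <= self.bow_angle < 60:
            raise GenerationError("bow_angle outside the supported [0, 60) range")
        if self.flare_scale <= 0.3:
            raise GenerationError("flare_scale too small; surface would collapse")
        max_r = max(self.shaft_radius_proximal, self.shaft_radius_distal) * max(
            1.0, self.flare_scale
        )
        if self.total_length < 6 * max_r:
            raise GenerationError("shaft too short relative to its radius")
        if self.vertex_spacing > min(self.shaft_radius_proximal, self.shaft_radius_distal):
            raise GenerationError("vertex_spacing exceeds the shaft radius")


@dataclass(frozen=True)
class GroundTruth:
    cs: CoordinateSystem
    styloid_vertex: int


@dataclass(frozen=True)
class ManualNoiseModel:
    trans_sd: float = 1.5  # mm, isotropic per-axis translation noise
    rot_sd_full: float = 6.6  # degrees at 100% length
    rot_sd_slope: float = 0.42  # degrees per 10% shortening step

    def __post_init__(self):
        if self.trans_sd < 0 or self.rot_sd_full < 0 or self.rot_sd_slope < 0:
            raise ValidationError("noise standard deviations must be >= 0")

    def rot_sd(self, length_pct: int) -> float:
        return self.rot_sd_full + self.rot_sd_slope * (100 - length_pct) / 10.0


DEFAULT_MANUAL_NOISE = ManualNoiseModel()


@dataclass(frozen=True)
class CohortBone:
    mesh: TriMesh
    truth: GroundTruth
    covariates: dict
    params: RadiusShapeParams

    def __iter__(self):  # allows tuple-style unpacking (mesh, truth, covariates)
        return iter((self.mesh, self.truth, self.covariates))


def _smoothstep(t: np.ndarray) -> np.ndarray:
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def _zipper(ia: np.ndarray, ang_a: np.ndarray, ib: np.ndarray, ang_b: np.ndarray,
            flip: bool = False) -> list[tuple[int, int, int]]:
    """Triangulate the band between two vertex loops (ascending angles),
    advancing whichever loop has the smaller next angle. Produces
    len(a) + len(b) triangles; every loop edge is used exactly once."""
    n, m = len(ia), len(ib)
    faces: list[tuple[int, int, int]] = []
    if m == 1:
        for i in range(n):
            faces.append((int(ia[i]), int(ia[(i + 1) % n]), int(ib[0])))
    elif n == 1:
        for j in range(m):
            faces.append((int(ia[0]), int(ib[(j + 1) % m]), int(ib[j])))
    else:
        # rotate loop b so it starts at the angle closest to a's start
        rel = np.mod(ang_b - ang_a[0] + math.pi, _TWO_PI) - math.pi
        k = int(np.argmin(np.abs(rel)))
        ib = np.roll(ib, -k)
        start_b = rel[k]
        a_rel = np.mod(ang_a - ang_a[0], _TWO_PI)
        b_rel = np.mod(ang_b - ang_b[k], _TWO_PI) + start_b
        a_ext = np.append(a_rel, a_rel[0] + _TWO_PI)
        b_ext = np.append(b_rel, b_rel[0] + _TWO_PI)
        i = j = 0
        while i < n or j < m:
            if i < n and (j >= m or a_ext[i + 1] <= b_ext[j + 1]):
                faces.append((int(ia[i]), int(ia[(i + 1) % n]), int(ib[j % m])))
                i += 1
            else:
                faces.append((int(ia[i % n]), int(ib[(j + 1) % m]), int(ib[j])))
                j += 1
    if flip:
        faces = [(a, c, b) for a, b, c in faces]
    return faces


def generate_radius(params: RadiusShapeParams) -> tuple[TriMesh, GroundTruth]:
    """Build one closed, manifold synthetic radius; deterministic in the seed.

    The midline is a circular arc of length ``total_length`` subtending
    ``bow_angle`` in the x-z plane, chord along +z. Ground truth: z along the
    chord (distal), x toward the styloid direction, origin at the centre of
    the distal articular dome.
    """
    params.validate()
    rng = np.random.default_rng(np.random.SeedSequence([0x52AD, params.seed & 0x7FFFFFFF]))
    L = params.total_length
    spacing = params.vertex_spacing
    theta = math.radians(params.bow_angle)
    if theta > 1e-9:
        r_arc = L / theta
        chord = 2.0 * r_arc * math.sin(theta / 2.0)
    else:
        r_arc = math.inf
        chord = L
    alpha = math.atan2(params.styloid_offset_dir[1], params.styloid_offset_dir[0])

    def midline(u: float) -> np.ndarray:
        if theta <= 1e-9:
            return np.array([0.0, 0.0, u * chord])
        phi = (u - 0.5) * theta
        x = r_arc * (math.cos(phi) - math.cos(theta / 2.0))
        z = chord / 2.0 + r_arc * math.sin(phi)
        return np.array([x, 0.0, z])

    def base_radius(u: float) -> float:
        r = params.shaft_radius_proximal + u * (
            params.shaft_radius_distal - params.shaft_radius_proximal
        )
        flare = 1.0 + (params.flare_scale - 1.0) * float(_smoothstep(np.array([(u - 0.85) / 0.15]))[0])
        return r * flare

    # smooth low-order random surface modulation (<= ~3% of the radius)
    amps = rng.uniform(0.0, 0.012, size=3)
    phases = rng.uniform(0.0, _TWO_PI, size=3)
    ax_phases = rng.uniform(0.0, _TWO_PI, size=3)

    def modulation(u: float, ang: np.ndarray) -> np.ndarray:
        out = np.zeros_like(ang)
        for p in range(3):
            out += amps[p] * np.sin((p + 2) * ang + phases[p]) * math.sin(
                (p + 1) * math.pi * u + ax_phases[p]
            )
        return out

    verts: list[np.ndarray] = []
    ring_idx: list[np.ndarray] = []
    ring_ang: list[np.ndarray] = []

    def add_ring(center: np.ndarray, rho: float, u: float, offset: float) -> None:
        nj = max(8, int(round(_TWO_PI * rho / spacing)))
        ang = np.sort(np.mod(np.arange(nj) * _TWO_PI / nj + offset, _TWO_PI))
        rr = rho * (1.0 + modulation(u, ang))
        pts = np.column_stack([
            center[0] + rr * np.cos(ang),
            center[1] + rr * np.sin(ang),
            np.full(nj, center[2]),
        ])
        base = sum(len(v) for v in verts)
        verts.append(pts)
        ring_idx.append(base + np.arange(nj))
        ring_ang.append(ang)

    n_rings = max(10, int(round(chord / spacing)) + 1)
    for k in range(n_rings):
        u = k / (n_rings - 1)
        off = alpha + (0.5 * _TWO_PI / 64) * (k % 2)
        add_ring(midline(u), base_radius(u), u, off)

    faces: list[tuple[int, int, int]] = []
    for k in range(n_rings - 1):
        faces += _zipper(ring_idx[k], ring_ang[k], ring_idx[k + 1], ring_ang[k + 1])

    def build_cap(ring0: int, center: np.ndarray, r0: float, dome_h: float,
                  sign: float, u_cap: float) -> None:
        """Concentric shrinking rings + centre fan; dome bulges sign * z."""
        prev_i, prev_a = ring_idx[ring0], ring_ang[ring0]
        rho = r0 - spacing
        step = 0
        while rho > 0.9 * spacing:
            zc = sign * dome_h * (1.0 - (rho / r0) ** 2)
            nj = max(8, int(round(_TWO_PI * rho / spacing)))
            ang = np.sort(np.mod(np.arange(nj) * _TWO_PI / nj + alpha
                                 + 0.5 * (_TWO_PI / nj) * (step % 2), _TWO_PI))
            rr = rho * (1.0 + modulation(u_cap, ang))
            pts = np.column_stack([
                center[0] + rr * np.cos(ang),
                center[1] + rr * np.sin(ang),
                np.full(nj, center[2] + zc),
            ])
            base = sum(len(v) for v in verts)
            verts.append(pts)
            idx = base + np.arange(nj)
            faces.extend(_zipper(prev_i, prev_a, idx, ang, flip=(sign < 0)))
            prev_i, prev_a = idx, ang
            rho -= spacing
            step += 1
        base = sum(len(v) for v in verts)
        verts.append(np.array([[center[0], center[1], center[2] + sign * dome_h]]))
        faces.extend(_zipper(prev_i, prev_a, np.array([base]), np.array([0.0]),
                             flip=(sign < 0)))

    r_dist = base_radius(1.0)
    r_prox = base_radius(0.0)
    end_c = midline(1.0)
    build_cap(n_rings - 1, end_c, r_dist, 0.25 * r_dist, +1.0, 1.0)
    build_cap(0, midline(0.0), r_prox, 0.2 * r_prox, -1.0, 0.0)

    v = np.vstack(verts)

    # styloid: smooth distal bump toward +z, centred at ring angle alpha
    h = params.styloid_height
    if h > 0:
        rel = v[:, :2] - end_c[:2]
        rho = np.hypot(rel[:, 0], rel[:, 1])
        ang = np.arctan2(rel[:, 1], rel[:, 0])
        dphi = np.mod(ang - alpha + math.pi, _TWO_PI) - math.pi
        sig_phi = min(1.2, max(0.6, 1.5 * h / r_dist))
        sig_z = 2.0 * h
        w_phi = np.exp(-((dphi / sig_phi) ** 2))
        w_z = np.exp(-((np.maximum(end_c[2] - v[:, 2], 0.0) / sig_z) ** 2))
        w_rho = _smoothstep((rho / r_dist - 0.45) / 0.30)
        v = v.copy()
        v[:, 2] = v[:, 2] + h * w_phi * w_z * w_rho

    mesh = TriMesh(v, np.asarray(faces, dtype=np.int64))
    if not mesh.is_watertight():
        raise GenerationError("generated surface is not watertight")
    if mesh.signed_volume() <= 0:
        raise GenerationError("generated surface is inverted or self-intersecting")

    styloid_vertex = int(np.argmax(v[:, 2]))
    origin = end_c + np.array([0.0, 0.0, 0.25 * r_dist])  # distal dome apex
    x_axis = np.array([math.cos(alpha), math.sin(alpha), 0.0])
    z_axis = np.array([0.0, 0.0, 1.0])
    cs = CoordinateSystem(origin, x_axis, np.cross(z_axis, x_axis), z_axis)
    return mesh, GroundTruth(cs=cs, styloid_vertex=styloid_vertex)


DEFAULT_VARIATION: dict[str, tuple[float, float]] = {
    "total_length": (200.0, 260.0),
    "shaft_radius_proximal": (7.0, 9.5),
    "distal_radius_ratio": (1.1, 1.35),
    "bow_angle": (2.0, 10.0),
    "flare_scale": (1.25, 1.6),
    "styloid_height": (8.0, 15.0),
    "styloid_angle": (-0.5, 0.5),  # radians about +x
    "vertex_spacing": (2.2, 2.2),
    "tilt_deg": (0.0, 8.0),  # random scanner-pose tilt of the whole bone
    "shift_mm": (-30.0, 30.0),
}


def generate_cohort(n: int, seed: int, variation: dict | None = None) -> list[CohortBone]:
    """Draw ``n`` independent synthetic radii with per-bone shape variation.

    Per-bone randomness is derived from (seed, bone index), so any single
    bone is reproducible without generating the ones before it. Covariates
    (gender label, age, growth-plate flag) are synthetic hooks for the
    statistics layer, not anatomical claims.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    ranges = dict(DEFAULT_VARIATION)
    if variation:
        ranges.update(variation)
    for key, (lo, hi) in ranges.items():
        if lo > hi:
            raise ValidationError(f"invalid range for {key!r}: ({lo}, {hi})")

    def u(rng, key):
        lo, hi = ranges[key]
        return float(rng.uniform(lo, hi))

    bones: list[CohortBone] = []
    for i in range(n):
        ss = np.random.SeedSequence([seed & 0x7FFFFFFF, i])
        rng = np.random.default_rng(ss)
        bone_seed = int(ss.generate_state(1)[0])
        r_prox = u(rng, "shaft_radius_proximal")
        ang = u(rng, "styloid_angle")
        params = RadiusShapeParams(
            total_length=u(rng, "total_length"),
            shaft_radius_proximal=r_prox,
            shaft_radius_distal=r_prox * u(rng, "distal_radius_ratio"),
            bow_angle=u(rng, "bow_angle"),
            flare_scale=u(rng, "flare_scale"),
            styloid_height=u(rng, "styloid_height"),
            styloid_offset_dir=(math.cos(ang), math.sin(ang)),
            vertex_spacing=u(rng, "vertex_spacing"),
            seed=bone_seed,
        )
        mesh, truth = generate_radius(params)
        # random scanner pose: small tilt + shift, applied to mesh and truth
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        tilt = math.radians(u(rng, "tilt_deg"))
        rot = Rotation.from_rotvec(axis * tilt).as_matrix()
        shift = rng.uniform(*ranges["shift_mm"], size=3)
        t = RigidTransform(rot, shift)
        mesh = apply_rigid(mesh, t)
        truth = GroundTruth(cs=truth.cs.transformed(t), styloid_vertex=truth.styloid_vertex)
        covariates = {
            "gender_label": "M" if rng.random() < 0.5 else "F",
            "age_years": int(np.clip(round(rng.normal(27.0, 15.0)), 7, 72)),
            "growth_plate_flag": bool(rng.random() < 33.0 / 85.0),
        }
        bones.append(CohortBone(mesh=mesh, truth=truth, covariates=covariates, params=params))
    return bones


def segmentation_jitter(mesh: TriMesh, sd_mm: float, seed: int) -> TriMesh:
    """Displace each vertex along its outward normal by Gaussian(0, sd_mm) mm,
    emulating repeated-segmentation variability."""
    if sd_mm < 0:
        raise ValidationError("sd_mm must be >= 0")
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, sd_mm, size=mesh.n_vertices) if sd_mm > 0 else np.zeros(mesh.n_vertices)
    return TriMesh(mesh.vertices + noise[:, None] * mesh.vertex_normals(), mesh.faces)


def simulate_manual_placement(
    truth: GroundTruth,
    length_pct: int,
    noise: ManualNoiseModel,
    seed: int,
) -> CoordinateSystem:
    """Perturb the ground-truth frame like a human observer would.

    Translation: isotropic Gaussian per axis, independent of length.
    Rotation: about a uniformly random axis, angle |Gaussian(0, sd)| where
    sd grows with shortening (rot_sd_full + rot_sd_slope per 10% step).
    """
    if length_pct not in range(10, 101, 10):
        raise ValidationError("length_pct must be one of 10, 20, ..., 100")
    rng = np.random.default_rng(seed)
    dt = rng.normal(0.0, noise.trans_sd, size=3) if noise.trans_sd > 0 else np.zeros(3)
    axis = rng.normal(size=3)
    while np.linalg.norm(axis) < 1e-12:  # pragma: no cover - essentially impossible
        axis = rng.normal(size=3)
    axis = axis / np.linalg.norm(axis)
    sd = noise.rot_sd(length_pct)
    angle = abs(float(rng.normal(0.0, sd))) if sd > 0 else 0.0
    rot = Rotation.from_rotvec(axis * math.radians(angle)).as_matrix()
    cs = truth.cs
    return CoordinateSystem(
        cs.origin + dt,
        rot @ cs.x_axis,
        rot @ cs.y_axis,
        rot @ cs.z_axis,
    )
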