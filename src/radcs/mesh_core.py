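"""Triangle-mesh data model, STL/PLY I/O, rigid transforms, mirroring and clipping.

All coordinates are in millimetres, in a right-handed global frame. By
convention +z is the scanner axis pointing distal (configurable downstream).
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import MeshFormatError, ValidationError

__all__ = [
    "TriMesh",
    "RigidTransform",
    "CoordinateSystem",
    "load_mesh",
    "save_mesh",
    "apply_rigid",
    "mirror_mesh",
    "extent_along",
    "clip_fraction",
]

_ORTHO_TOL = 1e-9


def _as_unit(axis, name: str = "axis") -> np.ndarray:
    axis = np.asarray(axis, dtype=float).reshape(3)
    n = float(np.linalg.norm(axis))
    if n < 1e-12:
        raise ValidationError(f"{name} must be non-zero")
    if abs(n - 1.0) > 1e-8:
        raise ValidationError(f"{name} must be unit length (|{name}| = {n:.6g})")
    return axis


@dataclass(frozen=True)
class TriMesh:
    """Triangulated surface: ``vertices`` (n, 3) float mm, ``faces`` (m, 3) int."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self):
        v = np.ascontiguousarray(np.asarray(self.vertices, dtype=float))
        f = np.ascontiguousarray(np.asarray(self.faces, dtype=np.int64))
        if v.ndim != 2 or v.shape[1] != 3:
            raise ValidationError("vertices must be an (n, 3) array")
        if f.ndim != 2 or f.shape[1] != 3:
            raise ValidationError("faces must be an (m, 3) array")
        if not np.isfinite(v).all():
            raise ValidationError("vertex coordinates must be finite")
        if len(f) == 0:
            raise ValidationError("mesh has no faces")
        if f.min() < 0 or f.max() >= len(v):
            raise ValidationError("face indices out of range")
        if len(v) < 4:
            raise ValidationError("mesh needs at least 4 vertices")
        # reject (near-)coplanar degenerate meshes: vertex scatter must be rank 3
        c = v - v.mean(axis=0)
        s = np.linalg.svd(c, compute_uv=False)
        if s[2] <= 1e-9 * max(s[0], 1.0):
            raise ValidationError("degenerate mesh: vertices are coplanar")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def triangle_corners(self):
        """Per-face corner coordinate arrays (v0, v1, v2), each (m, 3)."""
        f = self.faces
        return self.vertices[f[:, 0]], self.vertices[f[:, 1]], self.vertices[f[:, 2]]

    def face_normals(self, normalize: bool = True) -> np.ndarray:
        v0, v1, v2 = self.triangle_corners()
        n = np.cross(v1 - v0, v2 - v0)
        if normalize:
            ln = np.linalg.norm(n, axis=1)
            ln[ln == 0] = 1.0
            n = n / ln[:, None]
        return n

    def vertex_normals(self) -> np.ndarray:
        """Area-weighted outward vertex normals (unit length where defined)."""
        raw = self.face_normals(normalize=False)  # magnitude = 2 * area
        vn = np.zeros_like(self.vertices)
        for k in range(3):
            np.add.at(vn, self.faces[:, k], raw)
        ln = np.linalg.norm(vn, axis=1)
        ln[ln == 0] = 1.0
        return vn / ln[:, None]

    def area(self) -> float:
        return float(0.5 * np.linalg.norm(self.face_normals(normalize=False), axis=1).sum())

    def signed_volume(self) -> float:
        """Signed enclosed volume (divergence theorem); meaningful if watertight."""
        v0, v1, v2 = self.triangle_corners()
        return float(np.einsum("ij,ij->i", v0, np.cross(v1, v2)).sum() / 6.0)

    def is_watertight(self) -> bool:
        """True iff every undirected edge is used by exactly two faces."""
        f = self.faces
        edges = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
        edges = np.sort(edges, axis=1)
        _, counts = np.unique(edges, axis=0, return_counts=True)
        return bool((counts == 2).all())


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion ``p -> rotation @ p + translation``."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        r = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.isfinite(r).all() or not np.isfinite(t).all():
            raise ValidationError("transform entries must be finite")
        if np.abs(r.T @ r - np.eye(3)).max() > 1e-8:
            raise ValidationError("rotation matrix is not orthonormal")
        if abs(np.linalg.det(r) - 1.0) > 1e-8:
            raise ValidationError("rotation matrix must have determinant +1")
        object.__setattr__(self, "rotation", r)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return points @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: (self ∘ other)(p) = self(other(p))."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)


@dataclass(frozen=True)
class CoordinateSystem:
    """Origin plus a right-handed orthonormal axis triad (x, y, z)."""

    origin: np.ndarray
    x_axis: np.ndarray
    y_axis: np.ndarray
    z_axis: np.ndarray

    def __post_init__(self):
        o = np.asarray(self.origin, dtype=float).reshape(3)
        x = np.asarray(self.x_axis, dtype=float).reshape(3)
        y = np.asarray(self.y_axis, dtype=float).reshape(3)
        z = np.asarray(self.z_axis, dtype=float).reshape(3)
        for name, a in (("x_axis", x), ("y_axis", y), ("z_axis", z)):
            if abs(np.linalg.norm(a) - 1.0) > 1e-8:
                raise ValidationError(f"{name} must be unit length")
        if max(abs(x @ y), abs(y @ z), abs(x @ z)) > 1e-8:
            raise ValidationError("axes must be pairwise orthogonal")
        if np.linalg.norm(np.cross(x, y) - z) > 1e-8:
            raise ValidationError("axes must be right-handed (x cross y = z)")
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "x_axis", x)
        object.__setattr__(self, "y_axis", y)
        object.__setattr__(self, "z_axis", z)

    @property
    def rotation(self) -> np.ndarray:
        """3x3 matrix with the axes as columns (local -> global)."""
        return np.column_stack([self.x_axis, self.y_axis, self.z_axis])

    @classmethod
    def from_rotation(cls, origin, rotation: np.ndarray) -> "CoordinateSystem":
        rotation = np.asarray(rotation, dtype=float)
        return cls(origin, rotation[:, 0], rotation[:, 1], rotation[:, 2])

    def transformed(self, t: RigidTransform) -> "CoordinateSystem":
        return CoordinateSystem.from_rotation(t.apply(self.origin), t.rotation @ self.rotation)

    def to_dict(self) -> dict:
        return {
            "origin": self.origin.tolist(),
            "x_axis": self.x_axis.tolist(),
            "y_axis": self.y_axis.tolist(),
            "z_axis": self.z_axis.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CoordinateSystem":
        return cls(d["origin"], d["x_axis"], d["y_axis"], d["z_axis"])


# ---------------------------------------------------------------------------
# File I/O: STL (ASCII + binary) and PLY (ASCII + binary little-endian).
# Implemented locally because no mesh-I/O library is available at run time.
# ---------------------------------------------------------------------------


def _merge_duplicate_vertices(tri_coords: np.ndarray) -> TriMesh:
    """Build an indexed mesh from per-triangle corner coordinates (m, 3, 3)."""
    flat = tri_coords.reshape(-1, 3)
    uniq, inverse = np.unique(flat, axis=0, return_inverse=True)
    faces = inverse.reshape(-1, 3)
    return TriMesh(uniq, faces)


def _read_stl_ascii(text: str) -> TriMesh:
    coords = []
    for line in text.splitlines():
        parts = line.split()
        if len(parts) == 4 and parts[0] == "vertex":
            try:
                coords.append([float(parts[1]), float(parts[2]), float(parts[3])])
            except ValueError as exc:
                raise MeshFormatError(f"bad STL vertex line: {line!r}") from exc
    if not coords or len(coords) % 3 != 0:
        raise MeshFormatError("ASCII STL: vertex count not a multiple of 3")
    tri = np.asarray(coords, dtype=float).reshape(-1, 3, 3)
    return _merge_duplicate_vertices(tri)


def _read_stl_binary(data: bytes) -> TriMesh:
    if len(data) < 84:
        raise MeshFormatError("binary STL truncated (no header)")
    (n_tri,) = struct.unpack_from("<I", data, 80)
    if n_tri == 0:
        raise MeshFormatError("binary STL contains no triangles")
    expected = 84 + 50 * n_tri
    if len(data) < expected:
        raise MeshFormatError(
            f"binary STL truncated: {len(data)} bytes, expected {expected}"
        )
    rec = np.frombuffer(data, dtype=np.uint8, count=50 * n_tri, offset=84)
    rec = rec.reshape(n_tri, 50)
    tri = rec[:, 12:48].copy().view("<f4").reshape(n_tri, 3, 3).astype(float)
    return _merge_duplicate_vertices(tri)


def _write_stl_ascii(mesh: TriMesh, path: Path) -> None:
    v0, v1, v2 = mesh.triangle_corners()
    normals = mesh.face_normals()
    with open(path, "w") as fh:
        fh.write("solid radcs\n")
        for n, a, b, c in zip(normals, v0, v1, v2):
            fh.write(f"  facet normal {n[0]:.17g} {n[1]:.17g} {n[2]:.17g}\n")
            fh.write("    outer loop\n")
            for p in (a, b, c):
                fh.write(f"      vertex {p[0]:.17g} {p[1]:.17g} {p[2]:.17g}\n")
            fh.write("    endloop\n  endfacet\n")
        fh.write("endsolid radcs\n")


def _write_stl_binary(mesh: TriMesh, path: Path) -> None:
    v0, v1, v2 = mesh.triangle_corners()
    normals = mesh.face_normals().astype("<f4")
    m = mesh.n_faces
    rec = np.zeros(m, dtype=np.dtype([("n", "<f4", 3), ("v", "<f4", (3, 3)), ("attr", "<u2")]))
    rec["n"] = normals
    rec["v"][:, 0] = v0
    rec["v"][:, 1] = v1
    rec["v"][:, 2] = v2
    with open(path, "wb") as fh:
        fh.write(b"radcs binary stl".ljust(80, b"\x00"))
        fh.write(struct.pack("<I", m))
        fh.write(rec.tobytes())


_PLY_TYPES = {
    "char": "i1", "int8": "i1",
    "uchar": "u1", "uint8": "u1",
    "short": "i2", "int16": "i2",
    "ushort": "u2", "uint16": "u2",
    "int": "i4", "int32": "i4",
    "uint": "u4", "uint32": "u4",
    "float": "f4", "float32": "f4",
    "double": "f8", "float64": "f8",
}


def _read_ply(data: bytes) -> TriMesh:
    # --- header ---
    end = data.find(b"end_header\n")
    if not data.startswith(b"ply") or end < 0:
        raise MeshFormatError("not a PLY file (missing header)")
    header = data[: end + 11].decode("ascii", errors="replace")
    body = data[end + 11:]
    fmt = None
    elements: list[tuple[str, int, list]] = []  # (name, count, [props])
    for line in header.splitlines():
        tok = line.split()
        if not tok:
            continue
        if tok[0] == "format":
            fmt = tok[1]
        elif tok[0] == "element":
            elements.append((tok[1], int(tok[2]), []))
        elif tok[0] == "property":
            if not elements:
                raise MeshFormatError("PLY property before any element")
            if tok[1] == "list":
                elements[-1][2].append(("list", tok[2], tok[3], tok[4]))
            else:
                elements[-1][2].append(("scalar", tok[1], tok[2]))
    if fmt == "binary_big_endian":
        raise MeshFormatError("big-endian PLY is not supported")
    if fmt not in ("ascii", "binary_little_endian"):
        raise MeshFormatError(f"unknown PLY format {fmt!r}")

    vertices = None
    faces = None
    if fmt == "ascii":
        lines = body.decode("ascii", errors="replace").split("\n")
        pos = 0
        for name, count, props in elements:
            rows = lines[pos: pos + count]
            if len(rows) < count:
                raise MeshFormatError(f"PLY truncated in element {name!r}")
            pos += count
            if name == "vertex":
                names = [p[1] if p[0] == "list" else p[2] for p in props]
                try:
                    arr = np.array([[float(x) for x in r.split()] for r in rows])
                except ValueError as exc:
                    raise MeshFormatError("bad ASCII PLY vertex row") from exc
                if arr.shape != (count, len(props)):
                    raise MeshFormatError("ASCII PLY vertex row width mismatch")
                idx = [names.index(k) for k in ("x", "y", "z")]
                vertices = arr[:, idx]
            elif name == "face":
                fl = []
                for r in rows:
                    t = r.split()
                    n = int(t[0])
                    if n != 3:
                        raise MeshFormatError("only triangular PLY faces supported")
                    fl.append([int(t[1]), int(t[2]), int(t[3])])
                faces = np.asarray(fl, dtype=np.int64)
    else:
        offset = 0
        for name, count, props in elements:
            if name == "vertex":
                if any(p[0] == "list" for p in props):
                    raise MeshFormatError("list property in PLY vertex element")
                dt = np.dtype([(p[2], "<" + _PLY_TYPES[p[1]]) for p in props])
                need = dt.itemsize * count
                if len(body) - offset < need:
                    raise MeshFormatError("PLY truncated in vertex element")
                arr = np.frombuffer(body, dtype=dt, count=count, offset=offset)
                offset += need
                vertices = np.column_stack(
                    [arr["x"].astype(float), arr["y"].astype(float), arr["z"].astype(float)]
                )
            elif name == "face":
                if len(props) != 1 or props[0][0] != "list":
                    raise MeshFormatError("unsupported PLY face properties")
                cdt = np.dtype("<" + _PLY_TYPES[props[0][1]])
                idt = np.dtype("<" + _PLY_TYPES[props[0][2]])
                fl = np.empty((count, 3), dtype=np.int64)
                for i in range(count):
                    if len(body) - offset < cdt.itemsize:
                        raise MeshFormatError("PLY truncated in face element")
                    n = int(np.frombuffer(body, dtype=cdt, count=1, offset=offset)[0])
                    offset += cdt.itemsize
                    if n != 3:
                        raise MeshFormatError("only triangular PLY faces supported")
                    need = 3 * idt.itemsize
                    if len(body) - offset < need:
                        raise MeshFormatError("PLY truncated in face element")
                    fl[i] = np.frombuffer(body, dtype=idt, count=3, offset=offset)
                    offset += need
                faces = fl
            else:  # skip unknown fixed-size elements
                if any(p[0] == "list" for p in props):
                    raise MeshFormatError(f"cannot skip PLY list element {name!r}")
                dt = np.dtype([(p[2], "<" + _PLY_TYPES[p[1]]) for p in props])
                offset += dt.itemsize * count
    if vertices is None or faces is None:
        raise MeshFormatError("PLY is missing vertex or face element")
    return TriMesh(vertices, faces)


def _write_ply(mesh: TriMesh, path: Path, binary: bool) -> None:
    v, f = mesh.vertices, mesh.faces
    fmt = "binary_little_endian" if binary else "ascii"
    header = (
        "ply\n"
        f"format {fmt} 1.0\n"
        "comment radcs\n"
        f"element vertex {len(v)}\n"
        "property double x\nproperty double y\nproperty double z\n"
        f"element face {len(f)}\n"
        "property list uchar int vertex_indices\n"
        "end_header\n"
    )
    if binary:
        with open(path, "wb") as fh:
            fh.write(header.encode("ascii"))
            fh.write(np.ascontiguousarray(v, dtype="<f8").tobytes())
            rec = np.zeros(len(f), dtype=np.dtype([("n", "u1"), ("idx", "<i4", 3)]))
            rec["n"] = 3
            rec["idx"] = f
            fh.write(rec.tobytes())
    else:
        with open(path, "w") as fh:
            fh.write(header)
            for p in v:
                fh.write(f"{p[0]:.17g} {p[1]:.17g} {p[2]:.17g}\n")
            for a, b, c in f:
                fh.write(f"3 {a} {b} {c}\n")


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        format = format.lower()
        if format not in ("stl", "ply"):
            raise ValidationError(f"unsupported mesh format {format!r}")
        return format
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("stl", "ply"):
        return suffix
    raise ValidationError(f"cannot infer mesh format from {path.name!r}")


def load_mesh(path, format: str | None = None) -> TriMesh:
    """Load an STL or PLY surface mesh (units taken as millimetres verbatim)."""
    path = Path(path)
    fmt = _infer_format(path, format)
    data = path.read_bytes()
    if fmt == "ply":
        mesh = _read_ply(data)
    else:
        # ASCII STL starts with 'solid' AND contains 'facet'; some binary
        # exporters also start with 'solid', hence the second check.
        head = data[:512].lstrip()
        if head.startswith(b"solid") and b"facet" in data[:1024]:
            mesh = _read_stl_ascii(data.decode("ascii", errors="replace"))
        else:
            mesh = _read_stl_binary(data)
    return mesh


def save_mesh(mesh: TriMesh, path, format: str | None = None, binary: bool = True) -> None:
    """Write ``mesh`` as STL or PLY (format inferred from extension by default)."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "stl":
        (_write_stl_binary if binary else _write_stl_ascii)(mesh, path)
    else:
        _write_ply(mesh, path, binary)


# ---------------------------------------------------------------------------
# Geometric operations
# ---------------------------------------------------------------------------


def apply_rigid(mesh: TriMesh, t: RigidTransform) -> TriMesh:
    """Rigidly move a mesh: each vertex v -> R v + translation; faces unchanged."""
    return TriMesh(t.apply(mesh.vertices), mesh.faces)


def mirror_mesh(mesh: TriMesh) -> TriMesh:
    """Reflect across the x = 0 plane, reversing face winding to keep
    outward orientation. Used to map left bones onto right-bone geometry."""
    v = mesh.vertices.copy()
    v[:, 0] = -v[:, 0]
    return TriMesh(v, mesh.faces[:, [0, 2, 1]])


def extent_along(mesh: TriMesh, axis) -> tuple[float, float, float]:
    """(min, max, length) of vertex projections onto a unit axis."""
    axis = _as_unit(axis)
    s = mesh.vertices @ axis
    lo, hi = float(s.min()), float(s.max())
    return lo, hi, hi - lo


def clip_fraction(mesh: TriMesh, axis, keep_fraction: float) -> TriMesh:
    """Keep the distal ``keep_fraction`` of the mesh along ``axis``.

    The cut plane sits at ``max_s - keep_fraction * length``; triangles
    crossing the plane are split at it (new vertices on cut edges), so the
    retained extent is exact. The mesh is left open at the cut.
    """
    axis = _as_unit(axis)
    if not (0.0 < keep_fraction <= 1.0):
        raise ValidationError(f"keep_fraction must be in (0, 1], got {keep_fraction}")
    if keep_fraction == 1.0:
        return TriMesh(mesh.vertices, mesh.faces)

    s = mesh.vertices @ axis
    hi = s.max()
    cut = hi - keep_fraction * (hi - s.min())
    keep = s >= cut

    verts = [mesh.vertices]
    n_orig = mesh.n_vertices
    new_index: dict[tuple[int, int], int] = {}
    extra: list[np.ndarray] = []

    def cut_point(i: int, j: int) -> int:
        key = (i, j) if i < j else (j, i)
        idx = new_index.get(key)
        if idx is None:
            t = (cut - s[key[0]]) / (s[key[1]] - s[key[0]])
            p = mesh.vertices[key[0]] + t * (mesh.vertices[key[1]] - mesh.vertices[key[0]])
            idx = n_orig + len(extra)
            extra.append(p)
            new_index[key] = idx
        return idx

    faces_out: list[tuple[int, int, int]] = []
    for tri in mesh.faces:
        k = keep[tri]
        nk = int(k.sum())
        if nk == 3:
            faces_out.append(tuple(tri))
        elif nk == 0:
            continue
        else:
            # rotate so kept vertices come first, preserving winding
            order = [0, 1, 2]
            while not (k[order[0]] and (nk == 1 or k[order[1]])):
                order = order[1:] + order[:1]
            a, b, c = (int(tri[o]) for o in order)
            if nk == 1:
                pab = cut_point(a, b)
                pca = cut_point(c, a)
                faces_out.append((a, pab, pca))
            else:
                pbc = cut_point(b, c)
                pca = cut_point(c, a)
                faces_out.append((a, b, pbc))
                faces_out.append((a, pbc, pca))
    if not faces_out:
        raise ValidationError("clip produced an empty mesh")

    all_verts = np.vstack([mesh.vertices] + [np.asarray(extra)]) if extra else mesh.vertices
    faces_arr = np.asarray(faces_out, dtype=np.int64)
    used = np.unique(faces_arr)
    remap = np.full(len(all_verts), -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    return TriMesh(all_verts[used], remap[faces_arr])
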