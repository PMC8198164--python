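"""Socket geometry: STL I/O, cylindrical parameterization, synthetic sockets.

The socket wall is treated as a single triangle-mesh shell, open at the
proximal brim and capped at the distal end.  Positions on the wall are
addressed in a cylindrical frame anchored at the highest point of the
proximal *lateral* brim:

* ``h``      -- depth in mm below the brim reference point (>= 0, grows
                distally),
* ``theta``  -- angle in degrees, **clockwise when viewed from the proximal
                (open) end looking distally**, 0 deg at the brim reference
                point, normalized to [0, 360),
* ``r``      -- radial distance from the socket axis in mm.

Region definition files (``z_min, z_max, theta_min, theta_max``) use exactly
this convention.  All lengths are mm; STL files carry no unit so the mm
convention is declared here once and assumed everywhere.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
import trimesh


class SocketFormatError(ValueError):
    """Raised for unreadable or malformed mesh files."""


class FrameError(ValueError):
    """Raised when a cylindrical frame is required but not configured."""


@dataclass(frozen=True)
class CylindricalFrame:
    """Axis and angular reference of a socket.

    ``origin`` is the point on the axis at brim height, ``axis`` the unit
    vector pointing from the brim toward the distal end, and ``ref_dir`` the
    unit vector (perpendicular to ``axis``) toward the theta = 0 brim
    reference point.
    """

    origin: np.ndarray
    axis: np.ndarray
    ref_dir: np.ndarray

    def __post_init__(self):
        o = np.asarray(self.origin, dtype=float).reshape(3)
        d = np.asarray(self.axis, dtype=float).reshape(3)
        e1 = np.asarray(self.ref_dir, dtype=float).reshape(3)
        if not np.linalg.norm(d) > 0:
            raise FrameError("axis direction must be nonzero")
        d = d / np.linalg.norm(d)
        # orthogonalize ref_dir against the axis
        e1 = e1 - np.dot(e1, d) * d
        n = np.linalg.norm(e1)
        if not n > 1e-12:
            raise FrameError("ref_dir must not be parallel to the axis")
        e1 = e1 / n
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "axis", d)
        object.__setattr__(self, "ref_dir", e1)

    @property
    def binormal(self) -> np.ndarray:
        # axis x ref_dir: a right-hand rotation about `axis` appears
        # clockwise to a viewer looking *along* the axis (proximal->distal),
        # which is exactly the region-file convention.
        return np.cross(self.axis, self.ref_dir)

    def to_cylindrical(self, points: np.ndarray) -> np.ndarray:
        """Map (n, 3) cartesian points to (n, 3) columns (h, theta, r)."""
        p = np.atleast_2d(np.asarray(points, dtype=float)) - self.origin
        h = p @ self.axis
        u = p - np.outer(h, self.axis)
        x = u @ self.ref_dir
        y = u @ self.binormal
        theta = np.degrees(np.arctan2(y, x)) % 360.0
        r = np.hypot(x, y)
        out = np.column_stack([h, theta, r])
        return out if np.asarray(points).ndim > 1 else out[0]

    def from_cylindrical(self, coords: np.ndarray) -> np.ndarray:
        """Inverse of :meth:`to_cylindrical`."""
        c = np.atleast_2d(np.asarray(coords, dtype=float))
        h, theta, r = c[:, 0], np.radians(c[:, 1]), c[:, 2]
        pts = (
            self.origin
            + np.outer(h, self.axis)
            + np.outer(r * np.cos(theta), self.ref_dir)
            + np.outer(r * np.sin(theta), self.binormal)
        )
        return pts if np.asarray(coords).ndim > 1 else pts[0]


@dataclass
class SocketMesh:
    """Triangle mesh of the socket wall plus its cylindrical frame.

    ``frame`` is known for synthetic sockets; for imported STL files it must
    be supplied (config) before any cylindrical-coordinate operation.
    """

    vertices: np.ndarray
    faces: np.ndarray
    frame: CylindricalFrame | None = None
    _tm: trimesh.Trimesh | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise SocketFormatError("face indices out of range")

    @property
    def trimesh(self) -> trimesh.Trimesh:
        if self._tm is None:
            self._tm = trimesh.Trimesh(
                vertices=self.vertices, faces=self.faces, process=False
            )
        return self._tm

    @property
    def vertex_normals(self) -> np.ndarray:
        """Outward unit vertex normals (area-weighted face-normal average)."""
        n = np.array(self.trimesh.vertex_normals, dtype=float)
        norm = np.linalg.norm(n, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        return n / norm

    def with_vertices(self, vertices: np.ndarray) -> "SocketMesh":
        """Same topology and frame, new vertex positions."""
        return SocketMesh(vertices=np.asarray(vertices, float), faces=self.faces.copy(),
                          frame=self.frame)

    def require_frame(self) -> CylindricalFrame:
        if self.frame is None:
            raise FrameError(
                "socket axis is not configured; supply a CylindricalFrame "
                "(origin, axis, ref_dir) for imported meshes"
            )
        return self.frame

    def cylindrical(self) -> np.ndarray:
        """(n, 3) array of (h, theta, r) for every vertex."""
        return self.require_frame().to_cylindrical(self.vertices)


@dataclass(frozen=True)
class SyntheticSocketParams:
    """Parameters of the synthetic tapered elliptical socket shell.

    Default dimensions approximate an adult transfemoral quadrilateral
    check-socket: brim semi-axes 70 x 55 mm tapering to a 25 x 22 mm distal
    end over 300 mm.  ``taper`` is the exponent of the taper profile
    (1 = conical, >1 = fuller proximally).
    """

    brim_a: float = 70.0
    brim_b: float = 55.0
    distal_a: float = 25.0
    distal_b: float = 22.0
    length: float = 300.0
    n_theta: int = 96
    n_rings: int = 60
    taper: float = 1.5

    def __post_init__(self):
        for name in ("brim_a", "brim_b", "distal_a", "distal_b", "length", "taper"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.n_theta < 8 or self.n_rings < 8:
            raise ValueError("angular/vertical resolution must be >= 8")


def generate_socket(params: SyntheticSocketParams | None = None) -> SocketMesh:
    """Generate the synthetic socket shell: elliptical cross-sections tapering
    from brim to distal semi-axes, open at the brim, fan-capped distally.

    The generation frame places the brim at world z = 0 with the axis along
    -z (distal is down) and the theta = 0 reference at (+x) on the brim.
    """
    p = params or SyntheticSocketParams()
    frame = CylindricalFrame(
        origin=np.zeros(3), axis=np.array([0.0, 0.0, -1.0]), ref_dir=np.array([1.0, 0.0, 0.0])
    )
    hs = np.linspace(0.0, p.length, p.n_rings)
    t = (hs / p.length) ** p.taper
    a = p.brim_a + (p.distal_a - p.brim_a) * t
    b = p.brim_b + (p.distal_b - p.brim_b) * t
    theta = np.radians(np.arange(p.n_theta) * 360.0 / p.n_theta)

    verts = []
    for j in range(p.n_rings):
        # parametric ellipse in the clockwise-theta frame
        x = a[j] * np.cos(theta)
        y = b[j] * np.sin(theta)
        ring = frame.origin + np.outer(
            np.full(p.n_theta, hs[j]), frame.axis
        ) + np.outer(x, frame.ref_dir) + np.outer(y, frame.binormal)
        verts.append(ring)
    verts = np.concatenate(verts)

    faces = []
    n = p.n_theta
    for j in range(p.n_rings - 1):
        for i in range(n):
            i2 = (i + 1) % n
            v00, v01 = j * n + i, j * n + i2
            v10, v11 = (j + 1) * n + i, (j + 1) * n + i2
            faces.append([v00, v10, v01])
            faces.append([v01, v10, v11])
    # distal fan cap
    apex = len(verts)
    centre = frame.origin + p.length * frame.axis
    verts = np.vstack([verts, centre])
    last = (p.n_rings - 1) * n
    for i in range(n):
        faces.append([last + i, apex, last + (i + 1) % n])

    mesh = SocketMesh(vertices=verts, faces=np.array(faces), frame=frame)
    # enforce outward winding (positive enclosed volume)
    if enclosed_volume(mesh, signed=True) < 0:
        mesh = SocketMesh(vertices=mesh.vertices, faces=mesh.faces[:, ::-1], frame=frame)
    return mesh


def load_socket(path, frame: CylindricalFrame | None = None) -> SocketMesh:
    """Load an STL socket (binary or ASCII).

    Duplicate per-facet vertices are welded so downstream operations see a
    connected shell; the facet count of the file is preserved exactly.
    """
    try:
        tm = trimesh.load_mesh(str(path), file_type="stl", process=False)
    except Exception as exc:  # noqa: BLE001 - wrap any parser failure
        raise SocketFormatError(f"cannot read STL file {path!s}: {exc}") from exc
    if not isinstance(tm, trimesh.Trimesh) or len(tm.faces) == 0:
        raise SocketFormatError(f"{path!s} contains no triangle data")
    tm.merge_vertices()
    return SocketMesh(vertices=np.array(tm.vertices), faces=np.array(tm.faces), frame=frame)


def save_socket(mesh: SocketMesh, path, dialect: str = "binary") -> None:
    """Write the socket as STL (``binary`` or ``ascii``)."""
    if dialect not in ("binary", "ascii"):
        raise ValueError("dialect must be 'binary' or 'ascii'")
    tm = mesh.trimesh
    try:
        if dialect == "ascii":
            data = trimesh.exchange.stl.export_stl_ascii(tm)
            with open(path, "w") as fh:
                fh.write(data)
        else:
            data = trimesh.exchange.stl.export_stl(tm)
            with open(path, "wb") as fh:
                fh.write(data)
    except OSError as exc:
        raise OSError(f"cannot write STL to {path!s}: {exc}") from exc


def to_cylindrical(mesh: SocketMesh, point) -> np.ndarray:
    """(h, theta, r) of a cartesian point in the mesh's frame."""
    return mesh.require_frame().to_cylindrical(np.asarray(point, float))


def from_cylindrical(mesh: SocketMesh, coord) -> np.ndarray:
    """Cartesian position of an (h, theta, r) coordinate."""
    return mesh.require_frame().from_cylindrical(np.asarray(coord, float))


def make_loose(mesh: SocketMesh, area_increase: float) -> SocketMesh:
    """Enlarge every cross-section's area by ``area_increase`` (fraction).

    Implemented as radial scaling about the socket axis by
    sqrt(1 + area_increase), which scales each planar section area exactly by
    (1 + area_increase) and cannot self-intersect.  Topology is unchanged.
    """
    if area_increase < 0 or area_increase >= 1:
        raise ValueError("area_increase must be in [0, 1)")
    frame = mesh.require_frame()
    if area_increase == 0:
        return mesh.with_vertices(mesh.vertices.copy())
    s = float(np.sqrt(1.0 + area_increase))
    c = frame.to_cylindrical(mesh.vertices)
    c[:, 2] *= s
    return mesh.with_vertices(frame.from_cylindrical(c))


def cross_section_area(mesh: SocketMesh, h: float) -> float:
    """Area (mm^2) of the planar cross-section at depth ``h`` below the brim."""
    frame = mesh.require_frame()
    hs = frame.to_cylindrical(mesh.vertices)[:, 0]
    if not (hs.min() - 1e-9 <= h <= hs.max() + 1e-9):
        raise ValueError(f"h={h} outside the socket height range [{hs.min()}, {hs.max()}]")
    origin = frame.origin + h * frame.axis
    section = mesh.trimesh.section(plane_origin=origin, plane_normal=frame.axis)
    if section is None:
        raise ValueError(f"no cross-section found at h={h}")
    planar, _ = section.to_2D()
    return float(abs(planar.area))


def _boundary_loops(tm: trimesh.Trimesh) -> list[np.ndarray]:
    """Directed boundary edges grouped into closed vertex loops."""
    edges = tm.edges  # directed, one per face side
    edges_sorted = np.sort(edges, axis=1)
    from trimesh import grouping

    idx = grouping.group_rows(edges_sorted, require_count=1)
    boundary = edges[idx]
    nxt = {int(a): int(b) for a, b in boundary}
    loops = []
    seen: set[int] = set()
    for start in list(nxt):
        if start in seen:
            continue
        loop = [start]
        seen.add(start)
        cur = nxt[start]
        while cur != start and cur not in seen:
            loop.append(cur)
            seen.add(cur)
            if cur not in nxt:
                break
            cur = nxt[cur]
        loops.append(np.array(loop, dtype=np.int64))
    return loops


def enclosed_volume(mesh: SocketMesh, signed: bool = False) -> float:
    """Interior volume (mm^3) of the socket with its open brim fan-capped.

    Uses the divergence theorem on the capped shell; boundary loops are
    closed with a fan to their centroid, oriented consistently with the
    adjacent wall faces so the signed volume reflects the winding.
    """
    tm = mesh.trimesh
    verts = np.array(tm.vertices)
    faces = [np.array(tm.faces)]
    for loop in _boundary_loops(tm):
        if len(loop) < 3:
            continue
        centroid = verts[loop].mean(axis=0)
        ci = len(verts)
        verts = np.vstack([verts, centroid])
        # the directed boundary edge (a, b) belongs to a wall face; the cap
        # triangle (b, a, centroid) continues the same orientation
        a = loop
        b = np.roll(loop, -1)
        fan = np.column_stack([b, a, np.full(len(loop), ci)])
        faces.append(fan)
    capped = trimesh.Trimesh(vertices=verts, faces=np.vstack(faces), process=False)
    vol = float(capped.volume)
    return vol if signed else abs(vol)


def check_mesh(mesh: SocketMesh, atol: float = 1e-12) -> None:
    """Sanity checks: valid indices, no zero-area faces, unit normals."""
    areas = mesh.trimesh.area_faces
    if np.any(areas <= atol):
        raise SocketFormatError(f"{int(np.sum(areas <= atol))} degenerate (zero-area) faces")
    norms = np.linalg.norm(np.asarray(mesh.trimesh.vertex_normals, float), axis=1)
    if not np.allclose(norms, 1.0, atol=1e-6):
        warnings.warn("vertex normals deviate from unit length", RuntimeWarning)


def replace(obj, **changes):
    """dataclasses.replace re-export (convenience for params objects)."""
    return dataclasses.replace(obj, **changes)
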