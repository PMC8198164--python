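"""Surface-based socket rectification along vertex normals.

The wall is split into a control region H (vertices between a start and an
end angle, inside a height band) and a fixed region F (everything else);
there is no unconstrained region, so no PDE or linear system is solved.
Each H vertex moves *inward* along its outward unit normal — rectification
is inner-volume reduction (thickening of the inner wall).

Two displacement laws are provided: a constant normal displacement, and the
antero-lateral blend, a piecewise profile in the clockwise angle offset u
from the start angle theta_AS over the control extent Dtheta = clockwise
extent from theta_AS to theta_LE:

* logistic rise 0 -> m_A over the first 10% of Dtheta,
* plateau m_A up to theta_AL - Dtheta/2,
* logistic transition m_A -> m_L over the interval theta_AL +/- Dtheta/2,
* plateau m_L up to theta_LE - 10% of Dtheta,
* logistic fall m_L -> 0 over the last 10%,

finally scaled by h / h_max so the displacement grows linearly with depth
in H.  Logistic steepness defaults to k = 2 ln(99) / width (the sigmoid
covers 98% of its range inside its interval) and midpoints sit at interval
centres.  The middle transition's nominal interval necessarily reaches into
the 10% edge zones; it is clamped between them, and its steepness and
midpoint follow the clamped interval so the profile stays continuous to
within the 1% logistic residual at every join.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .fuzzy import DssOutput
from .geometry import SocketMesh

LOG99 = float(2.0 * np.log(99.0))


class DeformationError(ValueError):
    """Raised for degenerate deformation specifications."""


@dataclass(frozen=True)
class LogisticParams:
    """Parameters of one logistic transition f(x) = L / (1 + exp(n k (x - x0)))."""

    L: float
    k: float
    n: int
    x0: float

    def __post_init__(self):
        if self.k <= 0:
            raise DeformationError("logistic steepness k must be > 0")
        if self.n not in (1, -1):
            raise DeformationError("logistic direction n must be +1 or -1")


def logistic_blend(x, params: LogisticParams):
    """Evaluate the logistic transition; vectorized over x."""
    z = params.n * params.k * (np.asarray(x, dtype=float) - params.x0)
    return params.L / (1.0 + np.exp(np.clip(z, -500.0, 500.0)))


@dataclass(frozen=True)
class DeformationSpec:
    """Control-region geometry and magnitudes of one rectification.

    Angles are clockwise degrees (theta_AS -> theta_AL -> theta_LE in
    clockwise order, wrap through 0 permitted); magnitudes in mm; the
    height band [h_min, h_max] bounds H vertically.
    """

    theta_AS: float
    theta_AL: float
    theta_LE: float
    m_A: float = 0.0
    m_L: float = 0.0
    h_min: float = 0.0
    h_max: float = 180.0
    edge_frac: float = 0.1
    smooth_edges: bool = True
    height_scale: bool = True
    k_edge: float | None = None
    k_mid: float | None = None

    def __post_init__(self):
        if self.m_A < 0 or self.m_L < 0:
            raise DeformationError("magnitudes must be >= 0")
        if not self.h_min < self.h_max:
            raise DeformationError("h_min must be < h_max")
        if self.delta_theta_max <= 0:
            raise DeformationError("control region must have positive angular width")
        if not 0 <= self.edge_frac < 0.5:
            raise DeformationError("edge_frac must be in [0, 0.5)")
        if not 0 < self.u_AL < self.delta_theta_max:
            raise DeformationError(
                "theta_AL must lie strictly between theta_AS and theta_LE clockwise"
            )

    @property
    def delta_theta_max(self) -> float:
        """Dtheta_max: the clockwise angular extent from theta_AS to theta_LE
        (a full 360 deg when the end angle wraps onto the start)."""
        span = (self.theta_LE - self.theta_AS) % 360.0
        if span == 0.0 and self.theta_LE != self.theta_AS:
            return 360.0
        return span

    @property
    def u_AL(self) -> float:
        return (self.theta_AL - self.theta_AS) % 360.0

    def breakpoints(self) -> np.ndarray:
        """Offsets [rise end, A-plateau end, L-plateau start, fall start].

        The edge transitions always occupy exactly the first and last
        ``edge_frac`` of the control extent; the middle (A -> L) transition,
        whose printed interval theta_AL +/- Dtheta_max/2 necessarily reaches
        into the edge zones, is clamped between them.  A warning is emitted
        only when the clamp collapses the middle transition entirely.
        """
        d = self.delta_theta_max
        b1 = self.edge_frac * d
        b4 = (1.0 - self.edge_frac) * d
        b2 = float(np.clip(self.u_AL - d / 2.0, b1, b4))
        b3 = float(np.clip(self.u_AL + d / 2.0, b1, b4))
        if b2 == b3 and self.m_A != self.m_L:
            warnings.warn(
                "middle transition collapsed after clamping to the edge "
                "zones; the A->L blend degenerates to a step",
                RuntimeWarning,
            )
        return np.array([b1, b2, b3, b4])


@dataclass(frozen=True)
class RegionPartition:
    """Index sets of the control (H) and fixed (F) vertices; H | F covers
    every vertex and the two sets are disjoint."""

    H: np.ndarray
    F: np.ndarray


def _angular_offset(theta, theta_start) -> np.ndarray:
    return (np.asarray(theta, dtype=float) - theta_start) % 360.0


def partition_vertices(mesh: SocketMesh, spec: DeformationSpec) -> RegionPartition:
    """H = vertices with clockwise offset from theta_AS within the control
    extent (closed at the start edge, open at the end unless full-circle)
    and h inside [h_min, h_max]."""
    cyl = mesh.cylindrical()
    h, theta = cyl[:, 0], cyl[:, 1]
    d = spec.delta_theta_max
    u = _angular_offset(theta, spec.theta_AS)
    in_theta = u <= d if d >= 360.0 - 1e-9 else u < d
    in_h = (h >= spec.h_min) & (h <= spec.h_max)
    mask = in_theta & in_h
    if not mask.any():
        raise DeformationError("degenerate spec: the control region H is empty")
    idx = np.arange(len(mesh.vertices))
    return RegionPartition(H=idx[mask], F=idx[~mask])


def blend_coefficient(theta, h, spec: DeformationSpec, h_max: float | None = None):
    """Displacement magnitude c_i(theta, h) of the antero-lateral blend (mm).

    Vectorized over (theta, h); points outside H return exactly 0, plateau
    points return exactly m_A / m_L (before height scaling).
    """
    scalar = np.ndim(theta) == 0 and np.ndim(h) == 0
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    h = np.broadcast_to(np.asarray(h, dtype=float), theta.shape).astype(float)
    d = spec.delta_theta_max
    u = _angular_offset(theta, spec.theta_AS)
    in_theta = u <= d if d >= 360.0 - 1e-9 else u < d
    in_H = in_theta & (h >= spec.h_min) & (h <= spec.h_max)

    c = np.zeros_like(u)
    if spec.smooth_edges:
        b1, b2, b3, b4 = spec.breakpoints()
        k_edge = spec.k_edge if spec.k_edge is not None else LOG99 / max(spec.edge_frac * d, 1e-12)
        # midpoint at the centre of the (possibly clamped) transition
        # interval, steepness covering 98% of the range inside it
        mid_width = max(b3 - b2, 1e-12)
        k_mid = spec.k_mid if spec.k_mid is not None else LOG99 / mid_width
        x0_mid = (b2 + b3) / 2.0
        rise = logistic_blend(u, LogisticParams(spec.m_A, k_edge, -1, b1 / 2.0))
        if spec.m_A >= spec.m_L:
            mid = spec.m_L + logistic_blend(
                u, LogisticParams(spec.m_A - spec.m_L, k_mid, 1, x0_mid))
        else:
            mid = spec.m_A + logistic_blend(
                u, LogisticParams(spec.m_L - spec.m_A, k_mid, -1, x0_mid))
        fall = logistic_blend(u, LogisticParams(spec.m_L, k_edge, 1, (b4 + d) / 2.0))
        c = np.select(
            [u < b1, u < b2, u < b3, u < b4],
            [rise, spec.m_A, mid, spec.m_L],
            default=fall,
        )
    else:
        c = np.where(u < spec.u_AL, spec.m_A, spec.m_L).astype(float)

    c = np.where(in_H, c, 0.0)
    if spec.height_scale:
        hm = spec.h_max if h_max is None else float(h_max)
        if hm <= 0:
            raise DeformationError("h_max must be positive for height scaling")
        c = c * np.where(in_H, h / hm, 0.0)
    return float(c[0]) if scalar else c


def _displace(mesh: SocketMesh, amounts: np.ndarray) -> SocketMesh:
    """Move every vertex inward along its outward normal by `amounts` (mm)."""
    if mesh.frame is not None:
        r_old = mesh.cylindrical()[:, 2]
        crossed = (amounts > 0) & (r_old > 1e-9) & (amounts >= r_old)
        if crossed.any():
            raise DeformationError(
                f"displacement of {int(crossed.sum())} vertices reaches or "
                "crosses the socket axis"
            )
    moved = mesh.vertices - amounts[:, None] * mesh.vertex_normals
    return mesh.with_vertices(moved)


def displace_constant(
    mesh: SocketMesh, C: float, theta_start: float, theta_end: float,
    h_min: float | None = None, h_max: float | None = None,
) -> SocketMesh:
    """Constant inward normal displacement of every H vertex by C mm; the
    fixed region F does not move and topology is unchanged."""
    if C < 0:
        raise DeformationError("displacement C must be >= 0")
    cyl = mesh.cylindrical()
    h = cyl[:, 0]
    lo = h.min() if h_min is None else h_min
    hi = h.max() if h_max is None else h_max
    spec = DeformationSpec(
        theta_AS=theta_start,
        theta_AL=(theta_start + ((theta_end - theta_start) % 360.0 or 360.0) / 2.0) % 360.0,
        theta_LE=theta_end,
        m_A=C, m_L=C, h_min=min(lo, hi - 1e-9), h_max=hi,
        smooth_edges=False, height_scale=False,
    )
    part = partition_vertices(mesh, spec)
    amounts = np.zeros(len(mesh.vertices))
    amounts[part.H] = C
    rectified = _displace(mesh, amounts)
    _warn_if_flipped(mesh, rectified)
    return rectified


def rectify_anterolateral(mesh: SocketMesh, spec: DeformationSpec) -> SocketMesh:
    """Apply the smoothed antero-lateral volume reduction to the mesh."""
    cyl = mesh.cylindrical()
    part = partition_vertices(mesh, spec)
    h_max_H = float(cyl[part.H, 0].max()) if spec.height_scale else None
    amounts = blend_coefficient(cyl[:, 1], cyl[:, 0], spec, h_max=h_max_H)
    amounts = np.asarray(amounts, dtype=float)
    amounts[part.F] = 0.0
    rectified = _displace(mesh, amounts)
    _warn_if_flipped(mesh, rectified)
    return rectified


def _warn_if_flipped(before: SocketMesh, after: SocketMesh) -> None:
    """Cheap self-intersection heuristic: faces whose normal reversed."""
    n0 = before.trimesh.face_normals
    n1 = after.trimesh.face_normals
    flipped = int(np.sum(np.einsum("ij,ij->i", n0, n1) < 0))
    if flipped:
        warnings.warn(
            f"{flipped} faces flipped orientation after displacement; the "
            "rectified wall may self-intersect",
            RuntimeWarning,
        )


#: Which blend magnitude each inference zone drives.
DEFAULT_ZONE_ROLES = {
    "anterior_scarpa": "anterior",
    "anterior_wall": "anterior",
    "lateral_wall": "lateral",
}


def apply_actions(
    mesh: SocketMesh,
    output: DssOutput,
    template: DeformationSpec,
    zone_roles: dict[str, str] | None = None,
) -> SocketMesh:
    """Fill the blend template's magnitudes from the inference actions and
    rectify once with the combined spec.

    Anterior-role zones drive m_A, lateral-role zones m_L (max over
    contributing actions).  An empty action list returns the mesh unchanged.
    """
    roles = DEFAULT_ZONE_ROLES if zone_roles is None else zone_roles
    m = {"anterior": 0.0, "lateral": 0.0}
    for action in output.actions:
        if action.zone not in roles:
            raise DeformationError(f"no deformation role configured for zone {action.zone!r}")
        role = roles[action.zone]
        m[role] = max(m[role], action.magnitude_mm)
    if m["anterior"] == 0.0 and m["lateral"] == 0.0:
        return mesh.with_vertices(mesh.vertices.copy())
    spec = replace(template, m_A=m["anterior"], m_L=m["lateral"])
    return rectify_anterolateral(mesh, spec)


def default_template() -> DeformationSpec:
    """Antero-lateral control region of the default socket: anterior wall at
    250 deg clockwise through the lateral wall at 60 deg (extent 170 deg),
    upper/mid socket heights."""
    return DeformationSpec(theta_AS=250.0, theta_AL=335.0, theta_LE=60.0,
                           h_min=0.0, h_max=180.0)
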