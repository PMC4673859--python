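"""Triangulated surfaces and in-plane motion across them.

A membrane is represented as a collection of named *surfaces*, each a set of
triangular *panels* embedded in 3-D. Every panel carries an orthonormal tangent
frame (origin at its first vertex, first axis along the first edge), so a
molecule's location is stored as ``(panel, local 2-D coordinates)`` and only
converted to 3-D for output and for inter-molecule distances.

In-plane displacements that leave a panel are continued by *geodesic
unfolding*: the residual displacement is rotated about the shared edge into the
neighbouring panel's plane, which preserves path length exactly. Displacements
that hit an unshared (boundary) edge are reflected specularly and continue in
the same panel. All coordinates are in micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "BOUNDARY",
    "MeshError",
    "PropagationError",
    "Panel",
    "SurfaceMesh",
    "SurfacePosition",
    "build_mesh",
    "to_world",
    "from_world",
    "propagate",
    "export_panels_tsv",
]

BOUNDARY = -1

_TIE_EPS = 1e-15


class MeshError(ValueError):
    """Raised for invalid mesh input (degenerate panel, over-shared edge, ...)."""


class PropagationError(RuntimeError):
    """Raised when a step undergoes more edge events than ``max_crossings``.

    This signals a pathological ratio of step size to panel size rather than a
    numerical failure, and should be fixed in the configuration.
    """


@dataclass(frozen=True)
class Panel:
    """One triangular facet with its tangent frame.

    The frame origin is the first listed vertex; the first tangent axis points
    along ``v2 - v1``; the normal is ``cross(v2-v1, v3-v1)`` normalised, so the
    orientation is fixed by the vertex winding.
    """

    id: int
    vertices: np.ndarray  # (3, 3), µm
    surface: str
    origin: np.ndarray = field(repr=False)  # (3,)
    e1: np.ndarray = field(repr=False)  # (3,) unit tangent
    e2: np.ndarray = field(repr=False)  # (3,) unit tangent, normal x e1
    normal: np.ndarray = field(repr=False)  # (3,) unit
    local: np.ndarray = field(repr=False)  # (3, 2) vertices in the frame

    @property
    def area(self) -> float:
        a, b, c = self.local
        return 0.5 * abs((b[0] - a[0]) * (c[1] - a[1]) - (c[0] - a[0]) * (b[1] - a[1]))


@dataclass(frozen=True)
class SurfacePosition:
    """A molecule's location: a panel index plus 2-D coordinates in its frame."""

    panel: int
    xy: tuple[float, float]


class SurfaceMesh:
    """Panels, per-surface bookkeeping and edge adjacency in flat arrays.

    Edge ``e`` of a panel runs from local vertex ``e`` to ``(e+1) % 3``.
    ``neighbor_panel[p, e]`` is the adjacent panel index or :data:`BOUNDARY`.
    The ``xfer_*`` arrays pre-compute the frame change used by unfolding: for a
    shared edge they hold, in the *neighbour's* frame, the image of the edge
    anchor point, the edge direction, and the inward in-plane edge normal.
    """

    def __init__(self, panels: list[Panel], tolerance: float):
        self.panels = panels
        self.tolerance = float(tolerance)
        n = len(panels)

        self.surface_names: list[str] = []
        for p in panels:
            if p.surface not in self.surface_names:
                self.surface_names.append(p.surface)
        self._surface_index = {s: i for i, s in enumerate(self.surface_names)}
        self.surface_of_panel = np.array(
            [self._surface_index[p.surface] for p in panels], dtype=np.int64
        )

        self.origin = np.array([p.origin for p in panels])
        self.e1 = np.array([p.e1 for p in panels])
        self.e2 = np.array([p.e2 for p in panels])
        self.normal = np.array([p.normal for p in panels])
        self.local = np.array([p.local for p in panels])  # (n, 3, 2)
        self.vertices3 = np.array([p.vertices for p in panels])  # (n, 3, 3)

        areas = np.array([p.area for p in panels])
        self.panel_area = areas
        self.surface_area = {
            s: float(areas[self.surface_of_panel == i].sum())
            for s, i in self._surface_index.items()
        }

        # Edge geometry in the owner frame.
        va = self.local  # (n,3,2)
        vb = self.local[:, [1, 2, 0], :]
        self.edge_anchor = va.copy()
        ev = vb - va
        self.edge_length = np.linalg.norm(ev, axis=2)
        self.edge_dir = ev / self.edge_length[:, :, None]
        # Outward in-plane normal: perpendicular pointing away from the centroid.
        perp = np.stack([self.edge_dir[:, :, 1], -self.edge_dir[:, :, 0]], axis=2)
        centroid = self.local.mean(axis=1)  # (n,2)
        out = np.einsum("pek,pk->pe", perp, centroid) - np.einsum(
            "pek,pek->pe", perp, self.edge_anchor
        )
        self.edge_normal = np.where((out < 0)[:, :, None], perp, -perp)

        self.neighbor_panel = np.full((n, 3), BOUNDARY, dtype=np.int64)
        self.neighbor_edge = np.full((n, 3), BOUNDARY, dtype=np.int64)
        self.xfer_anchor = np.zeros((n, 3, 2))
        self.xfer_dir = np.zeros((n, 3, 2))
        self.xfer_normal_in = np.zeros((n, 3, 2))
        self._build_adjacency()

    # -- construction helpers -------------------------------------------------

    def _build_adjacency(self) -> None:
        n = len(self.panels)
        verts = self.vertices3.reshape(-1, 3)
        # Merge vertices within tolerance into canonical ids.
        canon = np.arange(len(verts))
        if len(verts) > 1:
            tree = cKDTree(verts)
            for i, j in sorted(tree.query_pairs(self.tolerance)):
                root = min(canon[i], canon[j])
                canon[canon == canon[i]] = root
                canon[canon == canon[j]] = root
        edge_map: dict[tuple[int, int], list[tuple[int, int]]] = {}
        for p in range(n):
            for e in range(3):
                i0 = canon[3 * p + e]
                i1 = canon[3 * p + (e + 1) % 3]
                key = (min(i0, i1), max(i0, i1))
                edge_map.setdefault(key, []).append((p, e))
        for key, owners in edge_map.items():
            if len(owners) > 2:
                raise MeshError(
                    f"edge shared by {len(owners)} panels: "
                    + ", ".join(f"panel {p} edge {e}" for p, e in owners)
                )
            if len(owners) == 2:
                (p, e), (q, f) = owners
                self.neighbor_panel[p, e] = q
                self.neighbor_edge[p, e] = f
                self.neighbor_panel[q, f] = p
                self.neighbor_edge[q, f] = e
                self._set_transfer(p, e, q)
                self._set_transfer(q, f, p)

    def _set_transfer(self, p: int, e: int, q: int) -> None:
        """Pre-compute the unfolding map for edge ``e`` of panel ``p`` into ``q``."""
        v0 = self.vertices3[p, e]
        v1 = self.vertices3[p, (e + 1) % 3]
        a_q = self._to_local(q, v0)
        b_q = self._to_local(q, v1)
        u_q = b_q - a_q
        u_q = u_q / np.linalg.norm(u_q)
        n_q = np.array([-u_q[1], u_q[0]])
        centroid_q = self.local[q].mean(axis=0)
        if np.dot(n_q, centroid_q - a_q) < 0:
            n_q = -n_q
        self.xfer_anchor[p, e] = a_q
        self.xfer_dir[p, e] = u_q
        self.xfer_normal_in[p, e] = n_q

    def _to_local(self, panel: int, point: np.ndarray) -> np.ndarray:
        d = np.asarray(point, dtype=float) - self.origin[panel]
        return np.array([np.dot(d, self.e1[panel]), np.dot(d, self.e2[panel])])

    # -- queries --------------------------------------------------------------

    @property
    def n_panels(self) -> int:
        return len(self.panels)

    def surface_index(self, name: str) -> int:
        return self._surface_index[name]

    def surface_of(self, panel: int) -> str:
        return self.surface_names[self.surface_of_panel[panel]]

    def contains_local(self, panel: int, xy: np.ndarray, tol: float = 1e-9) -> bool:
        d = xy - self.edge_anchor[panel]
        s = np.einsum("ek,ek->e", d, self.edge_normal[panel])
        return bool(np.all(s <= tol))

    def sample_uniform(self, surface: str, rng: np.random.Generator) -> SurfacePosition:
        """Uniform random point on a named surface (area-weighted over panels)."""
        idx = np.flatnonzero(self.surface_of_panel == self._surface_index[surface])
        if idx.size == 0:
            raise MeshError(f"surface {surface!r} has no panels")
        w = self.panel_area[idx]
        panel = int(rng.choice(idx, p=w / w.sum()))
        r1, r2 = rng.random(2)
        if r1 + r2 > 1.0:  # fold to keep the point in the triangle
            r1, r2 = 1.0 - r1, 1.0 - r2
        a, b, c = self.local[panel]
        xy = a + r1 * (b - a) + r2 * (c - a)
        return SurfacePosition(panel, (float(xy[0]), float(xy[1])))


def _panel_from_vertices(pid: int, verts: np.ndarray, surface: str) -> Panel:
    verts = np.asarray(verts, dtype=float).reshape(3, 3)
    u = verts[1] - verts[0]
    w = verts[2] - verts[0]
    nvec = np.cross(u, w)
    area2 = np.linalg.norm(nvec)
    if area2 <= 1e-14 * max(1.0, float(np.abs(verts).max()) ** 2):
        raise MeshError(f"panel {pid}: degenerate (zero-area) triangle")
    normal = nvec / area2
    e1 = u / np.linalg.norm(u)
    e2 = np.cross(normal, e1)
    local = np.stack(
        [
            np.zeros(2),
            np.array([np.dot(u, e1), np.dot(u, e2)]),
            np.array([np.dot(w, e1), np.dot(w, e2)]),
        ]
    )
    return Panel(
        id=pid,
        vertices=verts,
        surface=surface,
        origin=verts[0].copy(),
        e1=e1,
        e2=e2,
        normal=normal,
        local=local,
    )


def build_mesh(
    triangles, surface_labels, tolerance: float = 1e-6
) -> SurfaceMesh:
    """Assemble a :class:`SurfaceMesh` from raw triangles.

    Parameters
    ----------
    triangles
        Sequence of vertex triples, shape ``(n, 3, 3)`` in µm.
    surface_labels
        Surface name per triangle (a single string assigns all to one surface).
    tolerance
        Edge endpoints closer than this are treated as coincident when
        computing adjacency. Unmatched edges become reflective boundaries.
    """
    triangles = np.asarray(triangles, dtype=float)
    if triangles.ndim != 3 or triangles.shape[1:] != (3, 3) or len(triangles) == 0:
        raise MeshError("triangles must have shape (n, 3, 3) with n >= 1")
    if tolerance <= 0:
        raise MeshError("tolerance must be positive")
    if isinstance(surface_labels, str):
        surface_labels = [surface_labels] * len(triangles)
    if len(surface_labels) != len(triangles):
        raise MeshError("one surface label required per triangle")
    panels = [
        _panel_from_vertices(i, t, s)
        for i, (t, s) in enumerate(zip(triangles, surface_labels))
    ]
    return SurfaceMesh(panels, tolerance)


def to_world(pos: SurfacePosition, mesh: SurfaceMesh) -> np.ndarray:
    """3-D point of a surface position: panel origin + local · frame."""
    p = pos.panel
    if not 0 <= p < mesh.n_panels:
        raise KeyError(f"unknown panel id {p}")
    x, y = pos.xy
    return mesh.origin[p] + x * mesh.e1[p] + y * mesh.e2[p]


def from_world(point, panel: int, mesh: SurfaceMesh) -> SurfacePosition:
    """Inverse of :func:`to_world` for points on (or near) the given panel."""
    if not 0 <= panel < mesh.n_panels:
        raise KeyError(f"unknown panel id {panel}")
    xy = mesh._to_local(panel, np.asarray(point, dtype=float))
    return SurfacePosition(panel, (float(xy[0]), float(xy[1])))


# -- the propagation kernel ---------------------------------------------------
#
# Written over flat arrays and scalars so it can be JIT-compiled verbatim.
# Status codes: 0 ok, 1 max_crossings exceeded.


def _propagate_kernel(
    panel, px, py, dx, dy,
    edge_anchor, edge_normal, edge_dir,
    neighbor_panel, xfer_anchor, xfer_dir, xfer_normal_in,
    allow_cross, max_crossings, rec,
):
    ncross = 0
    events = 0
    record = rec.shape[0] > 0
    while dx != 0.0 or dy != 0.0:
        best_t = 1e300
        best_e = -1
        for e in range(3):
            nx = edge_normal[panel, e, 0]
            ny = edge_normal[panel, e, 1]
            denom = dx * nx + dy * ny
            if denom > 0.0:
                t = (
                    (edge_anchor[panel, e, 0] - px) * nx
                    + (edge_anchor[panel, e, 1] - py) * ny
                ) / denom
                if t < 0.0:
                    t = 0.0
                if t < best_t - _TIE_EPS:
                    best_t = t
                    best_e = e
        if best_e < 0 or best_t >= 1.0:
            px += dx
            py += dy
            break
        events += 1
        if events > max_crossings:
            return panel, px, py, ncross, 1
        px += best_t * dx
        py += best_t * dy
        scale = 1.0 - best_t
        dx *= scale
        dy *= scale
        nx = edge_normal[panel, best_e, 0]
        ny = edge_normal[panel, best_e, 1]
        q = neighbor_panel[panel, best_e]
        if allow_cross and q >= 0:
            ux = edge_dir[panel, best_e, 0]
            uy = edge_dir[panel, best_e, 1]
            s = (px - edge_anchor[panel, best_e, 0]) * ux + (
                py - edge_anchor[panel, best_e, 1]
            ) * uy
            du = dx * ux + dy * uy
            dn = dx * nx + dy * ny
            ax = xfer_anchor[panel, best_e, 0]
            ay = xfer_anchor[panel, best_e, 1]
            vx = xfer_dir[panel, best_e, 0]
            vy = xfer_dir[panel, best_e, 1]
            wx = xfer_normal_in[panel, best_e, 0]
            wy = xfer_normal_in[panel, best_e, 1]
            px = ax + s * vx
            py = ay + s * vy
            dx = du * vx + dn * wx
            dy = du * vy + dn * wy
            panel = q
            if record and ncross < rec.shape[0]:
                rec[ncross] = q
            ncross += 1
        else:
            dn = dx * nx + dy * ny
            dx -= 2.0 * dn * nx
            dy -= 2.0 * dn * ny
    return panel, px, py, ncross, 0


_kernel = _propagate_kernel
try:  # optional JIT acceleration; semantics identical
    import numba

    _kernel = numba.njit(_propagate_kernel, cache=False, nogil=True)
except Exception:  # pragma: no cover - numba genuinely absent
    pass

_NO_REC = np.empty(0, dtype=np.int64)


def propagate(
    start: SurfacePosition,
    displacement,
    mesh: SurfaceMesh,
    max_crossings: int = 1000,
    allow_cross: bool = True,
):
    """Carry an in-plane displacement across the mesh.

    The step moves in a straight line within the current panel's plane. On
    exiting through a shared edge the residual displacement is rotated about
    that edge into the neighbour's plane (unfolding); on exiting through a
    boundary edge it is reflected specularly. With ``allow_cross=False`` every
    edge acts as a boundary, which confines the molecule to its panel's
    surface.

    Returns ``(position, crossings)`` where ``crossings`` is the ordered list
    of ``(panel_id, surface_name)`` entered.
    """
    if max_crossings < 1:
        raise ValueError("max_crossings must be >= 1")
    dx, dy = float(displacement[0]), float(displacement[1])
    rec = np.empty(max_crossings, dtype=np.int64)
    panel, px, py, ncross, status = _kernel(
        int(start.panel), float(start.xy[0]), float(start.xy[1]), dx, dy,
        mesh.edge_anchor, mesh.edge_normal, mesh.edge_dir,
        mesh.neighbor_panel, mesh.xfer_anchor, mesh.xfer_dir,
        mesh.xfer_normal_in, allow_cross, max_crossings, rec,
    )
    if status != 0:
        raise PropagationError(
            f"step exceeded {max_crossings} edge events; "
            "step size is too large for the panel size"
        )
    crossings = [(int(q), mesh.surface_of(int(q))) for q in rec[:ncross]]
    return SurfacePosition(int(panel), (px, py)), crossings


def export_panels_tsv(mesh: SurfaceMesh, path) -> None:
    """Write panels as TSV: panel_id, surface, then 9 vertex coordinates."""
    with open(path, "w") as fh:
        fh.write("panel\tsurface\t" + "\t".join(
            f"{a}{i}" for i in (1, 2, 3) for a in ("x", "y", "z")) + "\n")
        for p in mesh.panels:
            coords = "\t".join(f"{v:.9g}" for v in p.vertices.ravel())
            fh.write(f"{p.id}\t{p.surface}\t{coords}\n")
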