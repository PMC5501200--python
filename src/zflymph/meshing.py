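"""Unstructured triangular meshing of the trunk slice.

A force-equilibrium mesher in the style of Persson & Strang's distmesh:
points relax under repulsive bar forces on the Delaunay edge graph of the
current point set, with a signed-distance description of the domain
(rectangle minus vessel lumina) and a size field graded towards the circular
features.  Vertices seeded on the circles are held fixed, which makes the
triangulation conform to the vessel boundaries and to the LEC interface;
the LEC disc itself is meshed and its triangles are tagged as a separate
subdomain.

The element size is controlled by two knobs: ``h_circle`` on the circle
boundaries and ``h_max`` in the far field, with linear grading in between.
``resolution`` scales both, so halving it roughly quadruples the element
count (used by the convergence study).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
from scipy.spatial import Delaunay, cKDTree

from .geometry import TrunkGeometry, GeometryError

__all__ = ["Mesh", "MeshError", "generate_mesh"]


class MeshError(RuntimeError):
    """The mesher failed to produce a valid, fully tagged triangulation."""


# boundary tag names
VESSEL_TAGS = ("PCV", "DA", "DLAV")
OUTER_TAG = "outer"
SYMMETRY_TAG = "symmetry"
LEC_INTERFACE_TAG = "LEC"


@dataclass
class Mesh:
    """Conforming triangulation with subdomain and boundary tags.

    ``points`` are nondimensional coordinates; ``triangles`` are CCW vertex
    index triples; ``tri_region`` is 0 for interstitial space, 1 for the LEC
    disc.  ``boundary_edges[tag]`` holds (n, 2) vertex-index arrays for each
    exterior boundary piece, and ``interface_edges`` the interior edges on
    the LEC circle (shared by one IS and one LEC triangle).
    """

    geometry: TrunkGeometry
    points: np.ndarray
    triangles: np.ndarray
    tri_region: np.ndarray
    boundary_edges: Dict[str, np.ndarray]
    interface_edges: np.ndarray
    resolution: float = 1.0

    # -- basic derived quantities -----------------------------------------
    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def tri_areas(self) -> np.ndarray:
        p = self.points
        t = self.triangles
        d1 = p[t[:, 1]] - p[t[:, 0]]
        d2 = p[t[:, 2]] - p[t[:, 0]]
        return 0.5 * (d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0])

    def min_angle_deg(self) -> float:
        p = self.points
        t = self.triangles
        a = np.linalg.norm(p[t[:, 1]] - p[t[:, 2]], axis=1)
        b = np.linalg.norm(p[t[:, 0]] - p[t[:, 2]], axis=1)
        c = np.linalg.norm(p[t[:, 0]] - p[t[:, 1]], axis=1)
        angles = []
        for x, y, z in ((a, b, c), (b, c, a), (c, a, b)):
            cosang = np.clip((y**2 + z**2 - x**2) / (2 * y * z), -1, 1)
            angles.append(np.degrees(np.arccos(cosang)))
        return float(np.min(angles))

    def region_nodes(self, region: int) -> np.ndarray:
        """Sorted unique vertex indices of triangles in a subdomain."""
        return np.unique(self.triangles[self.tri_region == region])

    def boundary_nodes(self, tag: str) -> np.ndarray:
        e = self.boundary_edges.get(tag)
        if e is None or len(e) == 0:
            return np.array([], dtype=int)
        return np.unique(e)

    def interface_nodes(self) -> np.ndarray:
        if len(self.interface_edges) == 0:
            return np.array([], dtype=int)
        return np.unique(self.interface_edges)

    def edge_lengths(self, edges: np.ndarray) -> np.ndarray:
        d = self.points[edges[:, 0]] - self.points[edges[:, 1]]
        return np.hypot(d[:, 0], d[:, 1])

    def tagged_boundary_length(self, tag: str) -> float:
        e = self.boundary_edges.get(tag, np.empty((0, 2), dtype=int))
        return float(self.edge_lengths(e).sum()) if len(e) else 0.0


# ---------------------------------------------------------------------------
# distance and size fields
# ---------------------------------------------------------------------------


def _d_rect(p: np.ndarray, g: TrunkGeometry) -> np.ndarray:
    # approximate signed distance to rectangle (negative inside)
    return np.maximum.reduce([
        g.x_min - p[:, 0], p[:, 0] - g.x_max,
        g.y_min - p[:, 1], p[:, 1] - g.y_max,
    ])


def _d_circ(p: np.ndarray, cx: float, cy: float, r: float) -> np.ndarray:
    return np.hypot(p[:, 0] - cx, p[:, 1] - cy) - r


def _signed_distance(p: np.ndarray, g: TrunkGeometry) -> np.ndarray:
    d = _d_rect(p, g)
    for name in g.vessel_names:
        c = g.circles[name]
        d = np.maximum(d, -_d_circ(p, c.cx, c.cy, c.r))
    return d


def _size_field(p: np.ndarray, g: TrunkGeometry, h_circle: float,
                h_max: float, grade: float) -> np.ndarray:
    h = np.full(len(p), h_max)
    for c in g.circles.values():  # includes the LEC: refine near the interface
        dist = np.abs(_d_circ(p, c.cx, c.cy, c.r))
        h = np.minimum(h, h_circle + grade * dist)
    return np.clip(h, h_circle, h_max)


def _fixed_points(g: TrunkGeometry, h_circle: float) -> np.ndarray:
    pts = [(g.x_min, g.y_min), (g.x_min, g.y_max),
           (g.x_max, g.y_min), (g.x_max, g.y_max)]
    for c in g.circles.values():
        if g.half_domain:
            # arc x <= 0, endpoints exactly on the symmetry line
            n = max(8, int(round(math.pi * c.r / h_circle)))
            theta = np.linspace(0.5 * math.pi, 1.5 * math.pi, n + 1)
        else:
            n = max(16, int(round(2 * math.pi * c.r / h_circle)))
            theta = np.linspace(0.0, 2 * math.pi, n, endpoint=False)
        for t in theta:
            pts.append((c.cx + c.r * math.cos(t), c.cy + c.r * math.sin(t)))
    arr = np.array(pts)
    # snap arc endpoints exactly onto the symmetry line
    arr[np.abs(arr[:, 0]) < 1e-12, 0] = 0.0
    return arr


# ---------------------------------------------------------------------------
# the mesher
# ---------------------------------------------------------------------------


def _triangulate(p: np.ndarray, g: TrunkGeometry, geps: float) -> np.ndarray:
    tri = Delaunay(p).simplices
    cent = p[tri].mean(axis=1)
    keep = _signed_distance(cent, g) < -geps
    tri = tri[keep]
    # enforce CCW orientation
    d1 = p[tri[:, 1]] - p[tri[:, 0]]
    d2 = p[tri[:, 2]] - p[tri[:, 0]]
    flip = d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0] < 0
    tri[flip] = tri[flip][:, [0, 2, 1]]
    return tri


def _project_back(p: np.ndarray, g: TrunkGeometry, outside: np.ndarray) -> None:
    # move points that escaped the domain back to its boundary along the
    # numerical gradient of the signed distance
    if not outside.any():
        return
    deps = 1e-8
    d = _signed_distance(p[outside], g)
    dx = (_signed_distance(p[outside] + [deps, 0.0], g) - d) / deps
    dy = (_signed_distance(p[outside] + [0.0, deps], g) - d) / deps
    norm = np.maximum(dx**2 + dy**2, 1e-30)
    p[outside, 0] -= d * dx / norm
    p[outside, 1] -= d * dy / norm


def generate_mesh(g: TrunkGeometry,
                  resolution: float = 1.0,
                  h_circle: float = 0.0015,
                  h_max: float = 0.005,
                  grade: float = 0.20,
                  seed: int = 0,
                  max_iter: int = 140,
                  min_angle_floor: float = 20.0) -> Mesh:
    """Generate a conforming, tagged triangulation of the slice.

    ``resolution`` multiplies both size knobs; smaller is finer.  The mesher
    raises :class:`MeshError` if the triangulation fails validation
    (untagged boundary edges, inverted or too-distorted triangles, triangles
    straddling the LEC interface).
    """
    g.validate()
    h_circle = h_circle * resolution
    h_max = h_max * resolution
    h0 = h_circle
    geps = 1e-3 * h0
    fixed = _fixed_points(g, h_circle)
    nfix = len(fixed)

    # initial points: equilateral lattice + density-matched rejection
    rng = np.random.default_rng(seed)
    xs = np.arange(g.x_min, g.x_max + h0, h0)
    ys = np.arange(g.y_min, g.y_max + h0 * math.sqrt(3) / 2,
                   h0 * math.sqrt(3) / 2)
    X, Y = np.meshgrid(xs, ys)
    X[1::2] += h0 / 2
    p = np.column_stack([X.ravel(), Y.ravel()])
    p = p[_signed_distance(p, g) < geps]
    r0 = 1.0 / _size_field(p, g, h_circle, h_max, grade) ** 2
    p = p[rng.random(len(p)) < r0 / r0.max()]
    # drop initial points that sit on top of fixed points
    tree = cKDTree(fixed)
    close = tree.query_ball_point(p, r=0.6 * h0)
    p = p[[len(c) == 0 for c in close]]
    p = np.vstack([fixed, p])

    Fscale, deltat, ttol, dptol = 1.2, 0.2, 0.1, 1e-3
    pold = np.full_like(p, np.inf)
    tri = None
    bars = None
    for _ in range(max_iter):
        if np.max(np.hypot(*(p - pold).T)) > ttol * h0:
            pold = p.copy()
            tri = _triangulate(p, g, geps)
            bars = np.unique(np.sort(np.vstack([
                tri[:, [0, 1]], tri[:, [1, 2]], tri[:, [2, 0]]]), axis=1), axis=0)
        barvec = p[bars[:, 0]] - p[bars[:, 1]]
        Lbar = np.hypot(barvec[:, 0], barvec[:, 1])
        hbars = _size_field(0.5 * (p[bars[:, 0]] + p[bars[:, 1]]),
                            g, h_circle, h_max, grade)
        L0 = hbars * Fscale * math.sqrt((Lbar**2).sum() / (hbars**2).sum())
        F = np.maximum(L0 - Lbar, 0.0)
        Fvec = (F / np.maximum(Lbar, 1e-30))[:, None] * barvec
        move = np.zeros_like(p)
        np.add.at(move, bars[:, 0], Fvec)
        np.add.at(move, bars[:, 1], -Fvec)
        move[:nfix] = 0.0
        p = p + deltat * move
        d = _signed_distance(p, g)
        _project_back(p, g, d > 0)
        interior = _signed_distance(p, g) < -geps
        interior[:nfix] = False
        if len(p[interior]):
            maxmove = np.max(np.hypot(*(deltat * move[interior]).T))
            if maxmove < dptol * math.sqrt((Lbar**2).sum() / len(Lbar)):
                break

    # final clean triangulation, hull snapping, and sliver cleanup: slivers
    # occasionally form where a free point is squeezed against the fixed
    # circle points; deleting the free vertex and retriangulating heals them
    is_fixed = np.zeros(len(p), dtype=bool)
    is_fixed[:nfix] = True
    for _round in range(12):
        tri = _triangulate(p, g, geps)
        used = np.unique(tri)
        if not is_fixed[np.setdiff1d(np.arange(len(p)), used)].any():
            remap = -np.ones(len(p), dtype=int)
            remap[used] = np.arange(len(used))
            p, is_fixed = p[used], is_fixed[used]
            tri = remap[tri]
        _snap_boundary(p, tri, g, h0)
        tri = _triangulate(p, g, geps)
        bad = _min_angles(p, tri) < min_angle_floor
        if not bad.any():
            break
        drop = np.zeros(len(p), dtype=bool)
        for tverts in tri[bad]:
            free = [v for v in tverts if not is_fixed[v]]
            if not free:
                raise MeshError("sliver triangle with only fixed vertices")
            # drop the free vertex closest to another vertex of the sliver
            dmin, vdrop = np.inf, free[0]
            for v in free:
                others = [w for w in tverts if w != v]
                dd = min(np.hypot(*(p[v] - p[w])) for w in others)
                if dd < dmin:
                    dmin, vdrop = dd, v
            drop[vdrop] = True
        keep = ~drop
        p, is_fixed = p[keep], is_fixed[keep]
    tri = _triangulate(p, g, geps)

    mesh = _finalize(p, tri, g, resolution)
    _validate(mesh, min_angle_floor)
    return mesh


def _min_angles(p: np.ndarray, tri: np.ndarray) -> np.ndarray:
    a = np.linalg.norm(p[tri[:, 1]] - p[tri[:, 2]], axis=1)
    b = np.linalg.norm(p[tri[:, 0]] - p[tri[:, 2]], axis=1)
    c = np.linalg.norm(p[tri[:, 0]] - p[tri[:, 1]], axis=1)
    out = np.full(len(tri), 180.0)
    for x, y, z in ((a, b, c), (b, c, a), (c, a, b)):
        cosang = np.clip((y**2 + z**2 - x**2) / (2 * y * z), -1, 1)
        out = np.minimum(out, np.degrees(np.arccos(cosang)))
    return out


def _snap_boundary(p: np.ndarray, tri: np.ndarray, g: TrunkGeometry,
                   h0: float) -> None:
    """Project hull vertices exactly onto the nearest geometric feature."""
    edges = np.sort(np.vstack([tri[:, [0, 1]], tri[:, [1, 2]], tri[:, [2, 0]]]), axis=1)
    uniq, counts = np.unique(edges, axis=0, return_counts=True)
    bnodes = np.unique(uniq[counts == 1])
    tol = 0.45 * h0
    for i in bnodes:
        x, y = p[i]
        # circles first (vessel walls and LEC interface)
        best = None
        for c in g.circles.values():
            d = abs(math.hypot(x - c.cx, y - c.cy) - c.r)
            if d < tol and (best is None or d < best[0]):
                best = (d, c)
        if best is not None:
            c = best[1]
            ang = math.atan2(y - c.cy, x - c.cx)
            p[i] = (c.cx + c.r * math.cos(ang), c.cy + c.r * math.sin(ang))
            x, y = p[i]
        for val, axis in ((g.x_min, 0), (g.x_max, 0), (g.y_min, 1), (g.y_max, 1)):
            if abs(p[i, axis] - val) < tol:
                p[i, axis] = val


def _finalize(p: np.ndarray, tri: np.ndarray, g: TrunkGeometry,
              resolution: float) -> Mesh:
    lec = g.circles["LEC"]
    cent = p[tri].mean(axis=1)
    region = (np.hypot(cent[:, 0] - lec.cx, cent[:, 1] - lec.cy)
              < lec.r).astype(np.int8)

    edges = np.sort(np.vstack([tri[:, [0, 1]], tri[:, [1, 2]], tri[:, [2, 0]]]), axis=1)
    uniq, inverse, counts = np.unique(edges, axis=0, return_inverse=True,
                                      return_counts=True)
    boundary = uniq[counts == 1]

    tol = 1e-9
    tags: Dict[str, list] = {t: [] for t in (*VESSEL_TAGS, OUTER_TAG, SYMMETRY_TAG)}
    untagged = []
    for e in boundary:
        a, b = p[e[0]], p[e[1]]
        tag = None
        for name in g.vessel_names:
            c = g.circles[name]
            if (abs(math.hypot(*(a - [c.cx, c.cy])) - c.r) < tol
                    and abs(math.hypot(*(b - [c.cx, c.cy])) - c.r) < tol):
                tag = name
                break
        if tag is None and g.half_domain and abs(a[0]) < tol and abs(b[0]) < tol:
            tag = SYMMETRY_TAG
        if tag is None:
            on_rect = all(
                min(abs(q[0] - g.x_min), abs(q[0] - g.x_max),
                    abs(q[1] - g.y_min), abs(q[1] - g.y_max)) < tol
                for q in (a, b))
            if on_rect:
                tag = OUTER_TAG
        if tag is None:
            untagged.append(e)
        else:
            tags[tag].append(e)
    if untagged:
        raise MeshError(f"{len(untagged)} untagged boundary edges; "
                        f"geometry: {g}")

    # interior edges lying on the LEC circle, shared by an IS and a LEC triangle
    lec_edges = []
    shared = uniq[counts == 2]
    c = lec
    onlec = (np.abs(np.hypot(p[:, 0] - c.cx, p[:, 1] - c.cy) - c.r) < tol)
    for e in shared:
        if onlec[e[0]] and onlec[e[1]]:
            lec_edges.append(e)

    boundary_edges = {k: (np.array(v, dtype=int) if v else np.empty((0, 2), dtype=int))
                      for k, v in tags.items()}
    return Mesh(geometry=g, points=p, triangles=tri, tri_region=region,
                boundary_edges=boundary_edges,
                interface_edges=(np.array(lec_edges, dtype=int)
                                 if lec_edges else np.empty((0, 2), dtype=int)),
                resolution=resolution)


def _validate(mesh: Mesh, min_angle_floor: float) -> None:
    areas = mesh.tri_areas()
    if (areas <= 0).any():
        raise MeshError("inverted or degenerate triangles present")
    ang = mesh.min_angle_deg()
    if ang < min_angle_floor:
        raise MeshError(f"minimum triangle angle {ang:.1f} deg below floor "
                        f"{min_angle_floor:.1f} deg")
    g = mesh.geometry
    # triangles must not straddle the LEC interface: every interface edge is
    # shared by exactly one IS and one LEC triangle
    if len(mesh.interface_edges):
        lec = g.circles["LEC"]
        cent = mesh.points[mesh.triangles].mean(axis=1)
        inside = np.hypot(cent[:, 0] - lec.cx, cent[:, 1] - lec.cy) < lec.r
        if not (inside == (mesh.tri_region == 1)).all():
            raise MeshError("inconsistent LEC subdomain classification")
    # tagged boundary length within 2% of the analytic circumference
    frac = 0.5 if g.half_domain else 1.0
    for name in g.vessel_names:
        c = g.circles[name]
        target = 2 * math.pi * c.r * frac
        got = mesh.tagged_boundary_length(name)
        if abs(got - target) > 0.02 * target:
            raise MeshError(f"{name} boundary length {got:.4g} deviates >2% "
                            f"from {target:.4g}")
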