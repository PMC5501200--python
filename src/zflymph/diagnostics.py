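"""Diagnostics and serialisation: Peclet fields, cut lines, convergence.

Cut-line extraction mirrors the reference figures: a straight sample line
(default 500 points) across the nondimensional domain, with samples falling
inside the vessel lumina or the LEC flagged by a point-in-circle test
against the *geometry* (not the mesh), which keeps the gaps mesh-
independent.  Field output is legacy-VTK ASCII (triangle meshes with point
data) and plain CSV tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .flow import FlowField
from .geometry import TrunkGeometry
from .meshing import Mesh
from .parameters import DimensionlessGroups

__all__ = [
    "DiagnosticsError",
    "CutLineProfile",
    "ConvergenceReport",
    "peclet_field",
    "extract_cutline",
    "convergence_study",
    "interpolate_field",
    "write_vtk",
    "write_cutline_csv",
    "read_cutline_csv",
]


class DiagnosticsError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Peclet measure
# ---------------------------------------------------------------------------


def peclet_field(flow: FlowField, species: str,
                 groups: DimensionlessGroups) -> np.ndarray:
    """Local convection-dominance measure |u~| * Pe per IS element.

    Pe = lam7 / lam1_i is the Peclet number built on the velocity scale;
    weighting by the local |u~| gives the pointwise measure whose value
    above one marks convection dominance.
    """
    pe = groups.lam["7"] / groups.lam_1[species]
    return flow.speed_elem() * pe


# ---------------------------------------------------------------------------
# interpolation and cut lines
# ---------------------------------------------------------------------------


def _locate(mesh: Mesh, xy: np.ndarray):
    """Barycentric location of sample points in the triangulation."""
    from scipy.spatial import Delaunay  # noqa: F401  (kept for API parity)
    pts = mesh.points
    tris = mesh.triangles
    # brute-force bounding-box prefilter, fine for <=1e3 samples
    p0 = pts[tris[:, 0]]
    p1 = pts[tris[:, 1]]
    p2 = pts[tris[:, 2]]
    tri_idx = np.full(len(xy), -1, dtype=int)
    bary = np.zeros((len(xy), 3))
    mins = np.minimum(np.minimum(p0, p1), p2)
    maxs = np.maximum(np.maximum(p0, p1), p2)
    for k, q in enumerate(xy):
        cand = np.where((mins[:, 0] <= q[0] + 1e-12) & (maxs[:, 0] >= q[0] - 1e-12)
                        & (mins[:, 1] <= q[1] + 1e-12) & (maxs[:, 1] >= q[1] - 1e-12))[0]
        if len(cand) == 0:
            continue
        a, b, c = p0[cand], p1[cand], p2[cand]
        det = (b[:, 1] - c[:, 1]) * (a[:, 0] - c[:, 0]) \
            + (c[:, 0] - b[:, 0]) * (a[:, 1] - c[:, 1])
        l1 = ((b[:, 1] - c[:, 1]) * (q[0] - c[:, 0])
              + (c[:, 0] - b[:, 0]) * (q[1] - c[:, 1])) / det
        l2 = ((c[:, 1] - a[:, 1]) * (q[0] - c[:, 0])
              + (a[:, 0] - c[:, 0]) * (q[1] - c[:, 1])) / det
        l3 = 1.0 - l1 - l2
        ok = np.where((l1 >= -1e-9) & (l2 >= -1e-9) & (l3 >= -1e-9))[0]
        if len(ok):
            j = ok[0]
            tri_idx[k] = cand[j]
            bary[k] = (l1[j], l2[j], l3[j])
    return tri_idx, bary


def interpolate_field(mesh: Mesh, nodal: np.ndarray, xy: np.ndarray
                      ) -> np.ndarray:
    """P1 interpolation of a nodal field at sample points (NaN outside)."""
    tri_idx, bary = _locate(mesh, np.asarray(xy, dtype=float))
    out = np.full(len(xy), np.nan)
    ok = tri_idx >= 0
    verts = mesh.triangles[tri_idx[ok]]
    out[ok] = np.einsum("sk,sk->s", bary[ok], nodal[verts])
    return out


@dataclass
class CutLineProfile:
    """Sampled profile along a straight line with exclusion masking."""

    start: Tuple[float, float]
    end: Tuple[float, float]
    coords: np.ndarray                 # (n, 2) sample positions
    arclength: np.ndarray              # distance from the start point
    values: Dict[str, np.ndarray]      # per-field samples (NaN where absent)
    mask: np.ndarray                   # True where the sample is inside an exclusion
    excluded_by: List[str] = field(default_factory=list)

    def masked_intervals(self) -> List[Tuple[int, int]]:
        """Contiguous index ranges of masked samples (the profile 'gaps')."""
        out = []
        inside = False
        for i, m in enumerate(self.mask):
            if m and not inside:
                start = i
                inside = True
            elif not m and inside:
                out.append((start, i - 1))
                inside = False
        if inside:
            out.append((start, len(self.mask) - 1))
        return out


def extract_cutline(mesh: Mesh, fields: Mapping[str, np.ndarray],
                    start: Tuple[float, float], end: Tuple[float, float],
                    n_samples: int = 500,
                    exclude: Sequence[str] = ("PCV", "DA", "DLAV", "LEC"),
                    ) -> CutLineProfile:
    """Sample nodal fields along a straight cut line.

    ``fields`` maps names to full-length nodal arrays.  Samples inside the
    named geometry circles are masked (these produce the characteristic
    gaps of the profile plots).  Raises if the line misses the bounding box
    entirely.
    """
    g = mesh.geometry
    start = tuple(map(float, start))
    end = tuple(map(float, end))
    for q in (start, end):
        if not (g.x_min - 1e-9 <= q[0] <= (0.5 * g.width / g.height) + 1e-9
                and g.y_min - 1e-9 <= q[1] <= g.y_max + 1e-9):
            raise DiagnosticsError(f"cut-line endpoint {q} outside bounding box")
    t = np.linspace(0.0, 1.0, n_samples)
    coords = np.column_stack([start[0] + t * (end[0] - start[0]),
                              start[1] + t * (end[1] - start[1])])
    arclength = t * np.hypot(end[0] - start[0], end[1] - start[1])
    mask = np.zeros(n_samples, dtype=bool)
    names = []
    for name in exclude:
        c = g.circles[name]
        inside = (coords[:, 0] - c.cx) ** 2 + (coords[:, 1] - c.cy) ** 2 < c.r ** 2
        if inside.any():
            names.append(name)
        mask |= inside
    values = {k: interpolate_field(mesh, np.asarray(v, dtype=float), coords)
              for k, v in fields.items()}
    return CutLineProfile(start=start, end=end, coords=coords,
                          arclength=arclength, values=values, mask=mask,
                          excluded_by=names)


# ---------------------------------------------------------------------------
# convergence studies
# ---------------------------------------------------------------------------


@dataclass
class ConvergenceReport:
    """Functional values along a refinement sequence."""

    label: str
    sizes: np.ndarray                 # element counts or max-step values
    values: np.ndarray
    observed_order: Optional[float] = None

    def relative_changes(self) -> np.ndarray:
        v = self.values
        return np.abs(np.diff(v)) / np.maximum(np.abs(v[1:]), 1e-300)


def convergence_study(run: Callable[[float], Tuple[float, float]],
                      levels: Sequence[float], label: str,
                      estimate_order: bool = False) -> ConvergenceReport:
    """Evaluate a scalar functional across a refinement sequence.

    ``run(level)`` returns (problem_size, functional_value); ``levels`` must
    be monotone (finest last).  With ``estimate_order`` the observed order
    is fitted from the last three values assuming geometric refinement.
    """
    if len(levels) < 3:
        raise DiagnosticsError("need at least three refinement levels")
    sizes, values = [], []
    for lv in levels:
        n, v = run(lv)
        sizes.append(n)
        values.append(v)
    order = None
    if estimate_order:
        # Richardson: order p from three successive errors assuming the
        # level parameter halves the grid spacing each refinement
        e = np.abs(np.diff(values))
        if np.all(e > 0):
            order = float(np.log2(e[-2] / e[-1]))
    return ConvergenceReport(label=label, sizes=np.asarray(sizes),
                             values=np.asarray(values), observed_order=order)


# ---------------------------------------------------------------------------
# serialisation
# ---------------------------------------------------------------------------


def write_vtk(path, mesh: Mesh, point_data: Mapping[str, np.ndarray] = (),
              cell_data: Mapping[str, np.ndarray] = ()) -> None:
    """Write the mesh and fields as legacy-VTK ASCII (UNSTRUCTURED_GRID)."""
    pts = mesh.points
    tris = mesh.triangles
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nzflymph fields\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {len(pts)} double\n")
        for x, y in pts:
            fh.write(f"{x:.15g} {y:.15g} 0\n")
        fh.write(f"CELLS {len(tris)} {4 * len(tris)}\n")
        for a, b, c in tris:
            fh.write(f"3 {a} {b} {c}\n")
        fh.write(f"CELL_TYPES {len(tris)}\n")
        fh.write("5\n" * len(tris))
        if point_data:
            fh.write(f"POINT_DATA {len(pts)}\n")
            for name, arr in dict(point_data).items():
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                for v in np.asarray(arr, dtype=float):
                    fh.write(f"{v:.15g}\n")
        cd = dict(cell_data)
        if cd:
            fh.write(f"CELL_DATA {len(tris)}\n")
            for name, arr in cd.items():
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                for v in np.asarray(arr, dtype=float):
                    fh.write(f"{v:.15g}\n")


def write_cutline_csv(path, profile: CutLineProfile) -> None:
    """Round-trippable CSV of a cut-line profile (15 significant digits)."""
    df = pd.DataFrame({"s": profile.arclength,
                       "x": profile.coords[:, 0],
                       "y": profile.coords[:, 1],
                       "masked": profile.mask.astype(int)})
    for k, v in profile.values.items():
        df[k] = v
    df.to_csv(path, index=False, float_format="%.15g")


def read_cutline_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_run_manifest(path, manifest: Mapping) -> None:
    with open(path, "w") as fh:
        json.dump(dict(manifest), fh, indent=2, sort_keys=True, default=str)
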