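import numpy as np
import pytest

from zflymph import (ParameterSet, TransportConfig, TransportSystem,
                     build_geometry, compute_groups, compute_scales,
                     generate_mesh)
from zflymph.meshing import Mesh

PRIMARY_SPECIES = ("VC", "M2", "M2P", "M2T2", "T2", "C1", "VCC1",
                   "MT1", "MT1T2", "MT1T2M2P")


@pytest.fixture(scope="session")
def params():
    return ParameterSet()


@pytest.fixture(scope="session")
def scales(params):
    return compute_scales(params)


@pytest.fixture(scope="session")
def groups(params, scales):
    return compute_groups(params, scales)


@pytest.fixture(scope="session")
def coarse_mesh():
    """Half-domain mesh at test resolution (~1300 elements)."""
    geo = build_geometry(half_domain=True)
    return generate_mesh(geo, seed=0, h_circle=0.003, h_max=0.012)


@pytest.fixture(scope="session")
def primary_coarse(coarse_mesh, groups):
    """The full-network reference run on the coarse test mesh."""
    cfg = TransportConfig(species=PRIMARY_SPECIES, C1_initial=1.0)
    system = TransportSystem(coarse_mesh, groups, cfg)
    return system.advance(t_end=1.0)


def rect_mesh(nx: int, ny: int, lx: float = 1.0, ly: float = 1.0) -> Mesh:
    """Structured rectangle triangulation with side-named boundary tags.

    Used by the manufactured-solution and analytic-profile flow oracles,
    which need hole-free domains with Dirichlet data on straight sides.
    """
    xs = np.linspace(0.0, lx, nx + 1)
    ys = np.linspace(0.0, ly, ny + 1)
    X, Y = np.meshgrid(xs, ys)
    pts = np.column_stack([X.ravel(), Y.ravel()])

    def idx(i, j):
        return j * (nx + 1) + i

    tris = []
    for j in range(ny):
        for i in range(nx):
            a, b, c, d = idx(i, j), idx(i + 1, j), idx(i + 1, j + 1), idx(i, j + 1)
            tris += [[a, b, c], [a, c, d]]
    be = {"left": [], "right": [], "bottom": [], "top": []}
    for j in range(ny):
        be["left"].append([idx(0, j), idx(0, j + 1)])
        be["right"].append([idx(nx, j), idx(nx, j + 1)])
    for i in range(nx):
        be["bottom"].append([idx(i, 0), idx(i + 1, 0)])
        be["top"].append([idx(i, ny), idx(i + 1, ny)])
    return Mesh(geometry=None, points=pts, triangles=np.array(tris),
                tri_region=np.zeros(2 * nx * ny, dtype=np.int8),
                boundary_edges={k: np.array(v) for k, v in be.items()},
                interface_edges=np.empty((0, 2), dtype=int))
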