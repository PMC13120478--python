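"""Shared fixtures: small synthetic surfaces, meshes and F-shapes."""

import numpy as np
import pytest

from fshapems.grids import ROIFrame, ThicknessGrid
from fshapems.meshing import FShape, build_tri_mesh


@pytest.fixture(scope="session")
def small_roi() -> ROIFrame:
    """Annular ROI on a 41×41 lattice, geometrically similar to the default frame."""
    return ROIFrame(outer_x=(3, 38), outer_y=(3, 38), inner_x=(16, 24), inner_y=(16, 24))


@pytest.fixture(scope="session")
def dome_surface() -> ThicknessGrid:
    """Smooth ILM-like dome heightfield (µm) on a 41×41 lattice, 6 mm field."""
    h = w = 41
    pitch = 6.0 / (w - 1)
    yy, xx = np.mgrid[0:h, 0:w]
    r = np.hypot((xx - 20) * pitch, (yy - 20) * pitch)
    return ThicknessGrid(300.0 * np.exp(-(r**2) / 8.0), pitch, layer_tag="ILM_elevation")


@pytest.fixture(scope="session")
def small_fshape(small_roi, dome_surface) -> FShape:
    """~77-vertex F-shape with an annular-peak thickness signal."""
    mesh = build_tri_mesh(small_roi, dome_surface, 0.04, side=4.92)
    pitch = dome_surface.pixel_pitch
    lat = mesh.lattice_index
    r = np.hypot((lat[:, 0] - 20) * pitch, (lat[:, 1] - 20) * pitch)
    signal = 75.0 - 40.0 * np.exp(-(((r - 1.0) / 0.8) ** 2))
    return FShape(mesh, signal)


def tiny_fshape(seed: int = 0, n: int = 4, signal_scale: float = 5.0) -> FShape:
    """Random small F-shape (~2n² faces) for brute-force oracle comparisons."""
    from fshapems.meshing import TriMesh

    rng = np.random.default_rng(seed)
    xs = np.arange(n + 1, dtype=float)
    vid = {}
    verts, faces, lat = [], [], []
    for j in range(n + 1):
        for i in range(n + 1):
            vid[(i, j)] = len(verts)
            verts.append([xs[i], xs[j], rng.normal(scale=50.0)])
            lat.append([i, j])
    for j in range(n):
        for i in range(n):
            v00, v10 = vid[(i, j)], vid[(i + 1, j)]
            v01, v11 = vid[(i, j + 1)], vid[(i + 1, j + 1)]
            faces.append([v00, v10, v11])
            faces.append([v00, v11, v01])
    mesh = TriMesh(np.array(verts), np.array(faces), np.array(lat), pixel_pitch=0.3)
    signal = 70.0 + signal_scale * rng.standard_normal(len(verts))
    return FShape(mesh, signal)
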