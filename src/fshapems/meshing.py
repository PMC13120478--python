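"""Decimated triangular meshes on the ROI and F-shape assembly.

The ROI lattice is covered by a coarse square grid whose ideal side length
``s`` is snapped to integer lattice coordinates, producing rectangles whose
sides differ by at most one lattice unit (4 and 5 units at the standard
density).  Each rectangle is split along its main diagonal into two
right-angled triangles.  Mapping a subject's GCIPL thickness onto its ILM
surface geometry at the mesh vertices yields the F-shape object (X, f):
a surface together with a scalar signal living on it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .grids import ROIFrame, SubjectRecord, ThicknessGrid

__all__ = [
    "TriMesh",
    "FShape",
    "plan_square_grid",
    "build_tri_mesh",
    "assemble_fshape",
    "mesh_in_mm",
    "vertex_area_weights",
    "export_ply",
    "export_vtk",
]

#: side length (lattice units) the standard 4% decimation uses; snapping it
#: yields the characteristic mix of 4- and 5-unit rectangle legs
PAPER_SIDE_4PCT = 4.92


@dataclass
class TriMesh:
    """Triangular surface mesh over ROI lattice points.

    vertices: (V, 3) float — x, y in lattice units, z elevation in µm.
    faces: (F, 3) int vertex triples.
    lattice_index: (V, 2) int — the (x, y) lattice point of each vertex.
    pixel_pitch: mm per lattice unit (metadata for unit conversion).
    """

    vertices: np.ndarray
    faces: np.ndarray
    lattice_index: np.ndarray
    pixel_pitch: float = 1.0

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=int)
        self.lattice_index = np.asarray(self.lattice_index, dtype=int)
        if self.faces.size and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise ValueError("face references out-of-range vertex")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def edges(self) -> np.ndarray:
        """Unique undirected edges as a sorted (E, 2) array."""
        e = np.vstack(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        e.sort(axis=1)
        return np.unique(e, axis=0)

    def euler_characteristic(self) -> int:
        return self.n_vertices - len(self.edges()) + self.n_faces


@dataclass
class FShape:
    """An F-shape object: mesh geometry X plus per-vertex scalar signal f (µm)."""

    mesh: TriMesh
    signal: np.ndarray

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if len(self.signal) != self.mesh.n_vertices:
            raise ValueError("signal length must equal vertex count")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal contains non-finite values")


def plan_square_grid(
    roi: ROIFrame, fraction: float, side: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Snapped cut positions covering the outer rectangle.

    The ideal square side is ``s = sqrt(1/fraction)`` lattice units (one mesh
    vertex per s×s cell keeps the stated fraction of lattice points), unless
    ``side`` overrides it.  Ideal cuts at multiples of s from the low edge are
    rounded to the nearest lattice integer; the final cut is forced onto the
    high edge.  Returns (x_cuts, y_cuts).
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must lie in (0, 1)")
    s = float(side) if side is not None else math.sqrt(1.0 / fraction)
    if s < 2.0:
        raise ValueError(f"ideal square side {s:.3f} < 2 lattice units")

    def cuts(lo: int, hi: int) -> np.ndarray:
        n = int(math.floor((hi - lo) / s))
        ideal = lo + s * np.arange(n + 1)
        snapped = np.rint(ideal).astype(int)
        snapped[0] = lo
        if snapped[-1] != hi:
            # force the high edge; absorb the last cut into it when the
            # leftover sliver would be shorter than half a square side
            if hi - snapped[-1] < s / 2.0:
                snapped[-1] = hi
            else:
                snapped = np.append(snapped, hi)
        keep = np.concatenate([[True], np.diff(snapped) > 0])
        return snapped[keep]

    return cuts(*roi.outer_x), cuts(*roi.outer_y)


def build_tri_mesh(
    roi: ROIFrame,
    surface: ThicknessGrid,
    fraction: float,
    side: float | None = None,
    with_hole: bool = True,
) -> TriMesh:
    """Decimated triangular mesh over the ROI of ``surface``.

    Vertices sit on snapped cut intersections; rectangles whose open interior
    meets the inner rectangle's open interior are dropped whole, so every face
    stays a right triangle with axis-aligned legs.  Vertex z is read from the
    surface at the vertex's lattice point.
    """
    h, w = surface.values.shape
    if roi.outer_x[1] >= w or roi.outer_y[1] >= h:
        raise ValueError("surface does not cover the ROI")
    xc, yc = plan_square_grid(roi, fraction, side)
    ix0, ix1 = roi.inner_x
    iy0, iy1 = roi.inner_y

    nx, ny = len(xc), len(yc)
    vid = -np.ones((ny, nx), dtype=int)
    verts: list[tuple[int, int]] = []
    faces: list[tuple[int, int, int]] = []

    def get_vid(iy: int, ix: int) -> int:
        if vid[iy, ix] < 0:
            vid[iy, ix] = len(verts)
            verts.append((int(xc[ix]), int(yc[iy])))
        return vid[iy, ix]

    for iy in range(ny - 1):
        for ix in range(nx - 1):
            xa, xb = xc[ix], xc[ix + 1]
            ya, yb = yc[iy], yc[iy + 1]
            if with_hole and xb > ix0 and xa < ix1 and yb > iy0 and ya < iy1:
                continue  # rectangle overlaps the inner open interior
            v00 = get_vid(iy, ix)
            v10 = get_vid(iy, ix + 1)
            v01 = get_vid(iy + 1, ix)
            v11 = get_vid(iy + 1, ix + 1)
            # main diagonal lower-left → upper-right
            faces.append((v00, v10, v11))
            faces.append((v00, v11, v01))

    if not faces:
        raise ValueError("no mesh cells survive the inner-hole exclusion at this density")
    lattice = np.array(verts, dtype=int)
    zs = surface.values[lattice[:, 1], lattice[:, 0]]
    vertices = np.column_stack([lattice[:, 0], lattice[:, 1], zs]).astype(float)
    return TriMesh(vertices, np.array(faces, dtype=int), lattice, surface.pixel_pitch)


def assemble_fshape(rec: SubjectRecord, mesh_template: TriMesh) -> FShape:
    """F-shape for one eye: ILM elevation as geometry, GCIPL thickness as signal.

    Connectivity (faces, lattice_index) is shared verbatim from the template
    mesh, so all subjects built from the same ROI/fraction are in lattice
    correspondence before registration.
    """
    lat = mesh_template.lattice_index
    h, w = rec.thickness.values.shape
    if lat[:, 0].max() >= w or lat[:, 1].max() >= h or lat.min() < 0:
        raise ValueError("mesh lattice index outside subject grid")
    z = rec.ilm.values[lat[:, 1], lat[:, 0]]
    f = rec.thickness.values[lat[:, 1], lat[:, 0]]
    bad = ~np.isfinite(f) | ~np.isfinite(z)
    if bad.any():
        i = int(np.nonzero(bad)[0][0])
        raise ValueError(
            f"non-finite grid value at lattice point {tuple(lat[i])} for eye {rec.eye_id}"
        )
    vertices = np.column_stack([lat[:, 0], lat[:, 1], z]).astype(float)
    mesh = TriMesh(
        vertices, mesh_template.faces.copy(), lat.copy(), rec.thickness.pixel_pitch
    )
    return FShape(mesh, f)


def mesh_in_mm(mesh: TriMesh) -> np.ndarray:
    """Vertex coordinates converted to a common length unit (mm).

    Lateral lattice units scale by pixel pitch; axial elevation converts
    from µm.  Registration kernels operate on these coordinates.
    """
    v = mesh.vertices.copy()
    v[:, 0] *= mesh.pixel_pitch
    v[:, 1] *= mesh.pixel_pitch
    v[:, 2] *= 1e-3
    return v


def vertex_area_weights(vertices_mm: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Each vertex's share of mesh area (one third of adjacent face areas, mm²)."""
    a = vertices_mm[faces[:, 0]]
    b = vertices_mm[faces[:, 1]]
    c = vertices_mm[faces[:, 2]]
    areas = 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)
    w = np.zeros(len(vertices_mm))
    for k in range(3):
        np.add.at(w, faces[:, k], areas / 3.0)
    return w


# ---------------------------------------------------------------------------
# Export


def export_ply(fshape: FShape, path: str | Path) -> None:
    """ASCII PLY with the signal as a per-vertex scalar property."""
    import trimesh

    tm = trimesh.Trimesh(
        vertices=fshape.mesh.vertices, faces=fshape.mesh.faces, process=False
    )
    tm.vertex_attributes["signal"] = fshape.signal.astype(np.float32)
    tm.export(Path(path), file_type="ply", encoding="ascii")


def export_vtk(fshape: FShape, path: str | Path, name: str = "signal") -> None:
    """Legacy-ASCII VTK PolyData with one scalar point-data channel."""
    m = fshape.mesh
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nfshape surface\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {m.n_vertices} float\n")
        for v in m.vertices:
            fh.write(f"{v[0]:.6g} {v[1]:.6g} {v[2]:.6g}\n")
        fh.write(f"POLYGONS {m.n_faces} {4 * m.n_faces}\n")
        for f in m.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")
        fh.write(f"POINT_DATA {m.n_vertices}\n")
        fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
        for s in fshape.signal:
            fh.write(f"{s:.6g}\n")
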