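"""Thickness-map grids, file I/O, eye-orientation normalization and ROI extraction.

A retinal layer thickness map is a 2D scalar field on a pixel lattice
(values in micrometres).  The same container carries ILM surface elevation
fields.  Left-eye maps are mirrored about the vertical midline so every
record follows the right-eye (OD) convention before any downstream step.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "EyeSide",
    "Label",
    "ThicknessGrid",
    "ROIFrame",
    "SubjectRecord",
    "GridFormatError",
    "read_grid",
    "write_grid",
    "normalize_orientation",
    "extract_roi",
    "roi_point_count",
    "roi_mask",
    "read_manifest",
    "write_manifest",
]


class EyeSide(str, enum.Enum):
    LEFT = "left"
    RIGHT = "right"


class Label(str, enum.Enum):
    HEALTHY = "healthy"
    MS = "MS"


class GridFormatError(ValueError):
    """Raised when a grid file is ragged, non-numeric or otherwise malformed."""


@dataclass
class ThicknessGrid:
    """A 2D scalar field on a pixel lattice.

    values[y, x] is the field value at lattice point (x, y), in µm.
    ``pixel_pitch`` is the (isotropic) lattice spacing in mm.
    """

    values: np.ndarray
    pixel_pitch: float
    eye_side: EyeSide = EyeSide.RIGHT
    layer_tag: str = "GCIPL"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("grid values must be a non-empty 2D array")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"grid '{self.layer_tag}' contains non-finite values")

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class ROIFrame:
    """Annular region between two axis-aligned pixel rectangles.

    Bounds are inclusive lattice indices.  The retained region is every
    lattice point inside the outer rectangle except points strictly
    interior to the inner rectangle (the inner boundary is kept), so the
    ROI is a closed rectangular frame.
    """

    outer_x: tuple[int, int] = (65, 395)
    outer_y: tuple[int, int] = (75, 360)
    inner_x: tuple[int, int] = (205, 275)
    inner_y: tuple[int, int] = (200, 250)

    def __post_init__(self) -> None:
        ox0, ox1 = self.outer_x
        oy0, oy1 = self.outer_y
        ix0, ix1 = self.inner_x
        iy0, iy1 = self.inner_y
        if not (ox0 < ox1 and oy0 < oy1 and ix0 < ix1 and iy0 < iy1):
            raise ValueError("rectangle bounds must be increasing")
        if not (ox0 < ix0 and ix1 < ox1 and oy0 < iy0 and iy1 < oy1):
            raise ValueError("inner rectangle must be strictly contained in outer rectangle")

    @classmethod
    def from_one_based(
        cls,
        outer_x: tuple[int, int],
        outer_y: tuple[int, int],
        inner_x: tuple[int, int],
        inner_y: tuple[int, int],
    ) -> "ROIFrame":
        """Build a frame from 1-based pixel coordinates.

        Internally all coordinates are 0-based lattice indices; published
        pixel positions quoted with a 1-based convention shift by one step.
        """
        sub = lambda pair: (pair[0] - 1, pair[1] - 1)
        return cls(sub(outer_x), sub(outer_y), sub(inner_x), sub(inner_y))

    def scaled_to(self, width: int, height: int, reference: "ROIFrame" | None = None) -> "ROIFrame":
        """Proportionally rescale the frame onto a ``width``×``height`` lattice.

        The default coordinates assume a lattice of at least 396×361 points;
        reduced synthetic lattices use a geometrically similar frame.
        """
        ref = reference if reference is not None else ROIFrame()
        # the default frame coordinates were drawn on a nominal 461×461 lattice
        sx = (width - 1) / 460.0
        sy = (height - 1) / 460.0

        def sc(pair, s):
            return (int(round(pair[0] * s)), int(round(pair[1] * s)))

        return ROIFrame(
            outer_x=sc(ref.outer_x, sx),
            outer_y=sc(ref.outer_y, sy),
            inner_x=sc(ref.inner_x, sx),
            inner_y=sc(ref.inner_y, sy),
        )


@dataclass
class SubjectRecord:
    """One eye: GCIPL thickness map + ILM elevation field + class label."""

    subject_id: str
    eye_id: str
    label: Label
    thickness: ThicknessGrid
    ilm: ThicknessGrid
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.thickness.values.shape != self.ilm.values.shape:
            raise ValueError("thickness and ILM grids must share lattice dimensions")
        if self.thickness.pixel_pitch != self.ilm.pixel_pitch:
            raise ValueError("thickness and ILM grids must share pixel pitch")


# ---------------------------------------------------------------------------
# File I/O

_MAGIC = "FSHAPEMS-GRID-1"


def read_grid(
    path: str | Path,
    format: str = "delimited_text",
    pixel_pitch: float | None = None,
    eye_side: EyeSide = EyeSide.RIGHT,
    layer_tag: str = "GCIPL",
) -> ThicknessGrid:
    """Read a grid from a CSV file or the package's ``.npz`` binary container."""
    path = Path(path)
    if format == "binary_container":
        with np.load(path) as nz:
            if str(nz["magic"]) != _MAGIC:
                raise GridFormatError(f"{path}: not a {_MAGIC} container")
            return ThicknessGrid(
                values=nz["values"],
                pixel_pitch=float(nz["pixel_pitch"]),
                eye_side=EyeSide(str(nz["eye_side"])),
                layer_tag=str(nz["layer_tag"]),
            )
    if format != "delimited_text":
        raise ValueError(f"unknown grid format {format!r}")

    rows: list[list[float]] = []
    with open(path) as fh:
        for r, line in enumerate(fh):
            line = line.strip()
            if not line:
                continue
            cells = line.split(",")
            row = []
            for c, cell in enumerate(cells):
                try:
                    row.append(float(cell))
                except ValueError:
                    raise GridFormatError(
                        f"{path}: non-numeric cell at row {r}, column {c}: {cell!r}"
                    ) from None
            rows.append(row)
    if not rows:
        raise GridFormatError(f"{path}: empty grid file")
    ncols = {len(r) for r in rows}
    if len(ncols) != 1:
        raise GridFormatError(f"{path}: ragged rows (lengths {sorted(ncols)})")
    values = np.array(rows, dtype=float)
    if pixel_pitch is None:
        # 6 mm scan width divided by lattice width, the instrument's field of view
        pixel_pitch = 6.0 / values.shape[1]
    return ThicknessGrid(values, pixel_pitch, eye_side, layer_tag)


def write_grid(grid: ThicknessGrid, path: str | Path, format: str = "delimited_text") -> None:
    path = Path(path)
    if format == "binary_container":
        np.savez(
            path,
            magic=_MAGIC,
            values=grid.values,
            pixel_pitch=grid.pixel_pitch,
            eye_side=grid.eye_side.value,
            layer_tag=grid.layer_tag,
        )
        return
    if format != "delimited_text":
        raise ValueError(f"unknown grid format {format!r}")
    np.savetxt(path, grid.values, delimiter=",", fmt="%.10g")


# ---------------------------------------------------------------------------
# Orientation and ROI


def normalize_orientation(rec: SubjectRecord) -> SubjectRecord:
    """Mirror left-eye maps about the vertical midline (x → width−1−x).

    After this every record follows right-eye orientation, so nasal/temporal
    anatomy lines up across eyes.  Right-eye records pass through unchanged.
    """
    if rec.thickness.eye_side == EyeSide.RIGHT:
        return rec

    def flip(g: ThicknessGrid) -> ThicknessGrid:
        return ThicknessGrid(g.values[:, ::-1].copy(), g.pixel_pitch, EyeSide.RIGHT, g.layer_tag)

    return SubjectRecord(
        rec.subject_id, rec.eye_id, rec.label, flip(rec.thickness), flip(rec.ilm), dict(rec.meta)
    )


def roi_mask(grid_shape: tuple[int, int], roi: ROIFrame) -> np.ndarray:
    """Boolean (height, width) mask of retained ROI lattice points."""
    h, w = grid_shape
    if roi.outer_x[1] >= w or roi.outer_y[1] >= h or roi.outer_x[0] < 0 or roi.outer_y[0] < 0:
        raise ValueError("ROI exceeds grid bounds")
    yy, xx = np.mgrid[0:h, 0:w]
    in_outer = (
        (xx >= roi.outer_x[0])
        & (xx <= roi.outer_x[1])
        & (yy >= roi.outer_y[0])
        & (yy <= roi.outer_y[1])
    )
    in_inner_open = (
        (xx > roi.inner_x[0])
        & (xx < roi.inner_x[1])
        & (yy > roi.inner_y[0])
        & (yy < roi.inner_y[1])
    )
    return in_outer & ~in_inner_open


def extract_roi(grid: ThicknessGrid, roi: ROIFrame) -> pd.DataFrame:
    """Retained lattice points with their values: columns x, y, value."""
    mask = roi_mask(grid.values.shape, roi)
    ys, xs = np.nonzero(mask)
    return pd.DataFrame({"x": xs, "y": ys, "value": grid.values[ys, xs]})


def roi_point_count(roi: ROIFrame) -> int:
    """Closed-form retained point count: outer area minus inner open interior."""
    ow = roi.outer_x[1] - roi.outer_x[0] + 1
    oh = roi.outer_y[1] - roi.outer_y[0] + 1
    iw = max(roi.inner_x[1] - roi.inner_x[0] - 1, 0)
    ih = max(roi.inner_y[1] - roi.inner_y[0] - 1, 0)
    return ow * oh - iw * ih


# ---------------------------------------------------------------------------
# Dataset manifest

_MANIFEST_COLS = ["subject_id", "eye_id", "label", "side", "thickness_path", "ilm_path"]


def write_manifest(rows: list[dict], path: str | Path) -> None:
    df = pd.DataFrame(rows, columns=_MANIFEST_COLS)
    df.to_csv(path, index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(Path(path))
    missing = set(_MANIFEST_COLS) - set(df.columns)
    if missing:
        raise GridFormatError(f"manifest missing columns: {sorted(missing)}")
    return df


def load_record(row: pd.Series, base_dir: str | Path = ".") -> SubjectRecord:
    """Materialize a SubjectRecord from one manifest row."""
    base = Path(base_dir)

    def _load(p: str, tag: str) -> ThicknessGrid:
        p = Path(p)
        if not p.is_absolute():
            p = base / p
        fmt = "binary_container" if p.suffix == ".npz" else "delimited_text"
        g = read_grid(p, fmt, eye_side=EyeSide(row["side"]), layer_tag=tag)
        return g

    return SubjectRecord(
        subject_id=str(row["subject_id"]),
        eye_id=str(row["eye_id"]),
        label=Label(row["label"]),
        thickness=_load(row["thickness_path"], "GCIPL"),
        ilm=_load(row["ilm_path"], "ILM_elevation"),
    )
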