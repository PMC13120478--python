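"""ETDRS nine-sector macular grid and sector-mean thickness features.

The ETDRS grid partitions the macula into a central 1 mm disc (CF) and
inner (1–3 mm) and outer (3–6 mm) rings, each ring split into superior,
nasal, inferior and temporal quadrants by the two ±45° diagonals through
the fovea.  Sector-mean thicknesses are the classic nine-feature baseline
the dense F-shape residual features are compared against.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import ThicknessGrid

__all__ = ["SECTOR_ORDER", "EtdrsGrid", "build_etdrs_grid", "sector_means"]

SECTOR_ORDER = ["CF", "IS", "IN", "II", "IT", "OS", "ON", "OI", "OT"]

#: radius bands in mm: central disc, inner ring, outer ring
_BANDS = (0.5, 1.5, 3.0)


@dataclass
class EtdrsGrid:
    center: tuple[float, float]  # lattice (x, y) of the fovea
    pixel_pitch: float
    sector_masks: dict[str, np.ndarray]  # 9 disjoint boolean masks

    def labels_image(self) -> np.ndarray:
        """Integer label map: 0 outside the 6 mm disc, 1..9 in SECTOR_ORDER."""
        shape = next(iter(self.sector_masks.values())).shape
        img = np.zeros(shape, dtype=int)
        for i, name in enumerate(SECTOR_ORDER, start=1):
            img[self.sector_masks[name]] = i
        return img


def build_etdrs_grid(
    grid_shape: tuple[int, int],
    pixel_pitch: float,
    center: tuple[float, float] | None = None,
) -> EtdrsGrid:
    """Per-pixel sector masks for the nine ETDRS sectors.

    Pixels are assigned by center-of-pixel radius; exact band-boundary ties
    go to the inner band.  Quadrants follow the two ±45° diagonals, nasal on
    the right (right-eye convention), superior at the top (smaller y).
    """
    h, w = grid_shape
    if center is None:
        center = ((w - 1) / 2.0, (h - 1) / 2.0)
    cx, cy = center
    if not (0 <= cx < w and 0 <= cy < h):
        raise ValueError("center outside grid")
    yy, xx = np.mgrid[0:h, 0:w]
    dx = (xx - cx) * pixel_pitch
    dy = (yy - cy) * pixel_pitch
    r = np.hypot(dx, dy)
    if _BANDS[2] > min(cx, w - 1 - cx, cy, h - 1 - cy) * pixel_pitch:
        warnings.warn("6 mm ETDRS disc clipped by the grid", RuntimeWarning, stacklevel=2)

    cf = r <= _BANDS[0]
    inner = (r > _BANDS[0]) & (r <= _BANDS[1])
    outer = (r > _BANDS[1]) & (r <= _BANDS[2])
    # quadrants split by diagonals y = ±x through the center; superior has
    # dy < 0 (image rows grow downward), nasal has dx > 0 for a right eye
    sup = (dy <= -np.abs(dx)) & ~((dy == 0) & (dx == 0))
    inf = dy >= np.abs(dx)
    nas = dx > np.abs(dy)
    tem = dx < -np.abs(dy)
    # boundary pixels exactly on a diagonal (|dx| == |dy|) tie-break to the
    # vertical (superior/inferior) quadrants via the inclusive comparisons
    masks = {
        "CF": cf,
        "IS": inner & sup,
        "IN": inner & nas,
        "II": inner & inf,
        "IT": inner & tem,
        "OS": outer & sup,
        "ON": outer & nas,
        "OI": outer & inf,
        "OT": outer & tem,
    }
    return EtdrsGrid(center=(cx, cy), pixel_pitch=pixel_pitch, sector_masks=masks)


def sector_means(thickness: ThicknessGrid, grid: EtdrsGrid) -> pd.Series:
    """Mean thickness (µm) per sector, in the fixed CF…OT order."""
    shape = next(iter(grid.sector_masks.values())).shape
    if thickness.values.shape != shape:
        raise ValueError("thickness map shape does not match ETDRS grid")
    out = {}
    for name in SECTOR_ORDER:
        mask = grid.sector_masks[name]
        if not mask.any():
            warnings.warn(f"sector {name} empty after clipping", RuntimeWarning, stacklevel=2)
            out[name] = float("nan")
        else:
            out[name] = float(thickness.values[mask].mean())
    return pd.Series(out, name="sector_mean_um")
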