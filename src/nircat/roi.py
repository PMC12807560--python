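"""ROI-grid construction, trace extraction, and active-site classification.

The field of view is tiled into square ROIs (7 x 7 um by default; 4 and 10 um
grids are used as resolution controls).  Tiling uses ceiling division on each
axis anchored at the FOV origin, so partial edge tiles are retained — a
178 x 142 um FOV at 7 um gives ceil(178/7) x ceil(142/7) = 26 x 21 = 546 ROIs.

Per ROI, dF/F0 is the fractional change of the tile-mean intensity over its
pre-stimulation baseline.  An ROI is an active release site when its peak
post-stimulation dF/F0 exceeds three times the standard deviation of its
baseline dF/F0 fluctuations (plus a small absolute floor guarding the
noiseless sigma=0 degeneracy).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .stack_io import FluorescenceStack

__all__ = [
    "RoiGrid",
    "RoiTrace",
    "ActiveCall",
    "build_grid",
    "extract_traces",
    "call_active",
    "site_density",
    "calls_frame",
]

#: Absolute dF/F0 floor for an active call; real acquisitions always have
#: baseline noise, so this only guards synthetic noiseless input.
DEFAULT_EPS_ABS = 0.005


@dataclass(frozen=True)
class Tile:
    """Half-open pixel rectangle [row0, row1) x [col0, col1) with um bounds."""

    index: int
    row0: int
    row1: int
    col0: int
    col1: int
    x0_um: float
    x1_um: float
    y0_um: float
    y1_um: float

    @property
    def n_pixels(self) -> int:
        return (self.row1 - self.row0) * (self.col1 - self.col0)


@dataclass(frozen=True)
class RoiGrid:
    tile_um: float
    n_tiles_x: int
    n_tiles_y: int
    n_rows_px: int
    n_cols_px: int
    um_per_pixel: float
    tiles: tuple[Tile, ...]

    @property
    def n_tiles(self) -> int:
        return self.n_tiles_x * self.n_tiles_y


def _edges_px(extent_um: float, tile_um: float, um_per_pixel: float, n_px: int) -> list[int]:
    if tile_um < um_per_pixel:
        raise ValueError(
            f"tile size {tile_um} um is below the pixel pitch ({um_per_pixel} um/px)"
        )
    n_tiles = math.ceil(extent_um / tile_um - 1e-12)
    edges = [min(int(math.floor(k * tile_um / um_per_pixel + 1e-9)), n_px) for k in range(n_tiles)]
    edges.append(n_px)
    # a nominal FOV extent that is not a whole number of pixels can leave the
    # last nominal tile without any pixel of its own; drop such empty tiles
    out = [edges[0]]
    for e in edges[1:]:
        if e > out[-1]:
            out.append(e)
    return out


def build_grid(
    fov_width_um: float,
    fov_height_um: float,
    tile_um: float,
    um_per_pixel: float,
) -> RoiGrid:
    """Tile the FOV into a grid of square ROIs with retained edge remainders.

    Tiles are indexed row-major (top-left first).  The tiles partition the
    pixel frame exactly: every pixel belongs to exactly one tile.
    """
    if min(fov_width_um, fov_height_um, tile_um, um_per_pixel) <= 0:
        raise ValueError("all grid arguments must be positive")
    n_rows = int(round(fov_height_um / um_per_pixel))
    n_cols = int(round(fov_width_um / um_per_pixel))
    col_edges = _edges_px(fov_width_um, tile_um, um_per_pixel, n_cols)
    row_edges = _edges_px(fov_height_um, tile_um, um_per_pixel, n_rows)
    n_x = len(col_edges) - 1
    n_y = len(row_edges) - 1
    tiles = []
    for i in range(n_y):
        for j in range(n_x):
            idx = i * n_x + j
            tiles.append(
                Tile(
                    index=idx,
                    row0=row_edges[i],
                    row1=row_edges[i + 1],
                    col0=col_edges[j],
                    col1=col_edges[j + 1],
                    x0_um=col_edges[j] * um_per_pixel,
                    x1_um=col_edges[j + 1] * um_per_pixel,
                    y0_um=row_edges[i] * um_per_pixel,
                    y1_um=row_edges[i + 1] * um_per_pixel,
                )
            )
    return RoiGrid(
        tile_um=tile_um,
        n_tiles_x=n_x,
        n_tiles_y=n_y,
        n_rows_px=n_rows,
        n_cols_px=n_cols,
        um_per_pixel=um_per_pixel,
        tiles=tuple(tiles),
    )


@dataclass
class RoiTrace:
    """Per-ROI time series: raw tile mean, baseline stats, and dF/F0."""

    roi_index: int
    raw: np.ndarray
    f0: float
    baseline_sd: float
    dff: np.ndarray


def extract_traces(
    stack: FluorescenceStack,
    grid: RoiGrid,
    stim_frame: int | None = None,
) -> list[RoiTrace]:
    """Tile-mean traces with per-ROI baseline normalization.

    raw[t] is the unweighted mean over the tile's pixels at frame t; f0 is
    the mean of raw over the baseline frames [0, stim_frame); baseline_sd is
    the sample (n-1) standard deviation of dF/F0 over the same window, so the
    activity threshold is unit-free.
    """
    if stim_frame is None:
        stim_frame = stack.protocol.stim_frame
    if stim_frame < 2:
        raise ValueError("stim_frame must be >= 2 to define baseline variability")
    if grid.n_rows_px != stack.data.shape[1] or grid.n_cols_px != stack.data.shape[2]:
        raise ValueError(
            f"grid pixel geometry {grid.n_rows_px}x{grid.n_cols_px} does not match "
            f"stack frames of {stack.data.shape[1]}x{stack.data.shape[2]}"
        )
    traces = []
    data = stack.data
    for tile in grid.tiles:
        raw = data[:, tile.row0 : tile.row1, tile.col0 : tile.col1].mean(axis=(1, 2))
        f0 = float(raw[:stim_frame].mean())
        if f0 <= 0:
            raise ValueError(f"ROI {tile.index}: baseline mean must be positive")
        dff = (raw - f0) / f0
        baseline_sd = float(dff[:stim_frame].std(ddof=1))
        traces.append(
            RoiTrace(roi_index=tile.index, raw=raw, f0=f0, baseline_sd=baseline_sd, dff=dff)
        )
    return traces


@dataclass(frozen=True)
class ActiveCall:
    roi_index: int
    is_active: bool
    peak_dff: float
    threshold: float


def call_active(
    traces: Sequence[RoiTrace],
    stim_frame: int,
    k: float = 3.0,
    eps_abs: float = DEFAULT_EPS_ABS,
) -> list[ActiveCall]:
    """Classify ROIs as active release sites.

    An ROI is active when its peak dF/F0 over [stim_frame, end] strictly
    exceeds both k x baseline_sd and the absolute floor eps_abs.  Equality
    at either threshold is inactive.
    """
    calls = []
    for tr in traces:
        peak = float(tr.dff[stim_frame:].max())
        threshold = k * tr.baseline_sd
        is_active = bool(peak > threshold and peak > eps_abs)
        calls.append(
            ActiveCall(roi_index=tr.roi_index, is_active=is_active, peak_dff=peak, threshold=threshold)
        )
    return calls


def site_density(calls: Sequence[ActiveCall], grid: RoiGrid) -> float:
    """Active ROIs as a percentage of all ROIs in the field of view."""
    if len(calls) != grid.n_tiles:
        raise ValueError(f"expected {grid.n_tiles} calls (one per tile), got {len(calls)}")
    n_active = sum(c.is_active for c in calls)
    return 100.0 * n_active / grid.n_tiles


def calls_frame(
    traces: Sequence[RoiTrace], calls: Sequence[ActiveCall], grid: RoiGrid
) -> pd.DataFrame:
    """Tabular per-ROI output: index, pixel bounds, baseline stats, call."""
    by_idx = {t.index: t for t in grid.tiles}
    rows = []
    for tr, c in zip(traces, calls):
        tile = by_idx[tr.roi_index]
        rows.append(
            {
                "roi_index": tr.roi_index,
                "row0": tile.row0,
                "col0": tile.col0,
                "row1": tile.row1,
                "col1": tile.col1,
                "f0": tr.f0,
                "baseline_sd": tr.baseline_sd,
                "peak_dff": c.peak_dff,
                "threshold": c.threshold,
                "is_active": c.is_active,
            }
        )
    return pd.DataFrame(rows)
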