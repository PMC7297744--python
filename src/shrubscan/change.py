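"""Two-epoch biomass differencing and coarse-grid aggregation.

Per-pixel biomass rasters from two survey epochs are differenced
(epoch 2 minus epoch 1; negative = decline), masked to the area densely
sampled in both epochs, and summed into 2.5 m reporting cells. A cell is
comparable only where both epochs have at least two returns in it and each
epoch's mean nearest-neighbour point spacing in the cell is below a cutoff
(default 3 cm) — a guard against apparent change that is really uneven
scan coverage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .pointcloud import PointCloud

__all__ = [
    "ChangeGrid", "ChangeSummary", "shared_origin", "overlap_mask",
    "diff_biomass", "aggregate", "summarize",
]


@dataclass
class ChangeGrid:
    """Coarse grid of summed biomass deltas (grams per cell) with a
    validity mask; invalid cells carry no delta (nan)."""

    origin: tuple[float, float]
    cell_size: float
    delta: np.ndarray  # grams per cell, nan where invalid
    valid: np.ndarray  # bool


@dataclass
class ChangeSummary:
    """Landscape totals over the valid cells of a change grid."""

    total_delta_kg: float
    valid_area_m2: float
    mean_delta_g_per_m2: float
    n_valid_cells: int


def shared_origin(cloud_a: PointCloud, cloud_b: PointCloud,
                  cell_size: float = 2.5) -> tuple[float, float]:
    """Joint lower-left bound of both epochs snapped down to a cell
    multiple — the common grid origin for bit-reproducible co-registration."""
    ax0, ay0, _, _ = cloud_a.bounds
    bx0, by0, _, _ = cloud_b.bounds
    x0 = np.floor(min(ax0, bx0) / cell_size) * cell_size
    y0 = np.floor(min(ay0, by0) / cell_size) * cell_size
    return float(x0), float(y0)


def _cell_spacing_ok(pts: np.ndarray, max_spacing: float) -> bool:
    """Mean 3-D nearest-neighbour distance among >= 2 points below cutoff."""
    if pts.shape[0] < 2:
        return False
    tree = cKDTree(pts)
    d, _ = tree.query(pts, k=2)
    return bool(d[:, 1].mean() < max_spacing)


def overlap_mask(cloud_a: PointCloud, cloud_b: PointCloud,
                 cell_size: float = 2.5, max_spacing: float = 0.03,
                 origin: tuple[float, float] | None = None,
                 shape: tuple[int, int] | None = None) -> np.ndarray:
    """Validity mask of the comparison cells.

    A cell is valid iff both epochs place at least two returns in it and
    each epoch's mean nearest-neighbour 3-D distance within the cell is
    below ``max_spacing``.
    """
    if origin is None:
        origin = shared_origin(cloud_a, cloud_b, cell_size)
    if shape is None:
        xmax = max(cloud_a.bounds[2], cloud_b.bounds[2])
        ymax = max(cloud_a.bounds[3], cloud_b.bounds[3])
        nc = max(1, int(np.ceil((xmax - origin[0]) / cell_size)))
        nr = max(1, int(np.ceil((ymax - origin[1]) / cell_size)))
    else:
        nr, nc = shape
    mask = np.ones((nr, nc), dtype=bool)
    for cloud in (cloud_a, cloud_b):
        col = np.clip(((cloud.x - origin[0]) / cell_size).astype(np.int64),
                      0, nc - 1)
        row = np.clip(((cloud.y - origin[1]) / cell_size).astype(np.int64),
                      0, nr - 1)
        flat = row * nc + col
        order = np.argsort(flat, kind="stable")
        flat_sorted = flat[order]
        starts = np.searchsorted(flat_sorted, np.arange(nr * nc))
        ends = np.searchsorted(flat_sorted, np.arange(nr * nc), side="right")
        xyz = cloud.xyz[order]
        ok = np.zeros(nr * nc, dtype=bool)
        for cell in np.flatnonzero(ends - starts >= 2):
            ok[cell] = _cell_spacing_ok(xyz[starts[cell]:ends[cell]],
                                        max_spacing)
        mask &= ok.reshape(nr, nc)
    return mask


def diff_biomass(biomass_a: np.ndarray, biomass_b: np.ndarray) -> np.ndarray:
    """Per-pixel biomass difference (epoch 2 minus epoch 1, grams).

    The rasters must already be co-registered (same shape on the same
    grid); a shape mismatch is an error, not an implicit resample.
    """
    a = np.asarray(biomass_a, dtype=np.float64)
    b = np.asarray(biomass_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(
            f"epoch rasters are not co-registered: shapes {a.shape} vs {b.shape}")
    return b - a


def aggregate(delta: np.ndarray, mask: np.ndarray,
              origin: tuple[float, float] = (0.0, 0.0),
              fine_cell: float = 0.05, coarse_cell: float = 2.5) -> ChangeGrid:
    """Sum the fine delta raster into coarse reporting cells.

    The aggregation factor is ``round(coarse_cell / fine_cell)`` (50 for
    the 5 cm -> 2.5 m default); partial blocks at the raster edge sum only
    their existing pixels. ``mask`` is given at the coarse-cell level.
    """
    factor = int(round(coarse_cell / fine_cell))
    if factor < 1:
        raise ValueError("coarse cell must be at least one fine pixel")
    nr, nc = delta.shape
    cr = int(np.ceil(nr / factor))
    cc = int(np.ceil(nc / factor))
    padded = np.zeros((cr * factor, cc * factor))
    padded[:nr, :nc] = delta
    sums = padded.reshape(cr, factor, cc, factor).sum(axis=(1, 3))
    valid = np.zeros((cr, cc), dtype=bool)
    mr = min(cr, mask.shape[0])
    mc = min(cc, mask.shape[1])
    valid[:mr, :mc] = mask[:mr, :mc]
    out = np.where(valid, sums, np.nan)
    return ChangeGrid(origin=origin, cell_size=coarse_cell, delta=out,
                      valid=valid)


def summarize(change: ChangeGrid) -> ChangeSummary:
    """Total delta (kg), valid area (m^2) and mean delta (g/m^2) over the
    valid cells; negative values are biomass decline."""
    if not change.valid.any():
        warnings.warn("no valid cells in the change grid; totals are zero",
                      stacklevel=2)
        return ChangeSummary(0.0, 0.0, 0.0, 0)
    vals = change.delta[change.valid]
    area = change.valid.sum() * change.cell_size ** 2
    total = float(vals.sum())
    return ChangeSummary(total_delta_kg=total / 1000.0,
                         valid_area_m2=float(area),
                         mean_delta_g_per_m2=total / float(area),
                         n_valid_cells=int(change.valid.sum()))
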