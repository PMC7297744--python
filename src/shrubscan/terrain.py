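"""Terrain model, height normalization and threshold layering.

The digital terrain model (DTM) is the per-cell minimum point height on a
fixed 1 m grid; empty cells are filled from the nearest non-empty cell so
that every point inside the cloud's bounds has a terrain value. Point
heights are then normalized (``NormZ = z - DTM(x, y)``) and partitioned
into ground (< 0.15 m), low vegetation (< 0.3 m), the shrub layer
(0.3–3.5 m, the stratum classified into taxa) and high vegetation
(> 3.5 m). Returns more than 5 cm below the terrain surface are flagged
as noise and excluded from layering.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .pointcloud import Layer, PointCloud

__all__ = [
    "DtmGrid", "LayerThresholds", "build_dtm", "normalize_heights",
    "assign_layers", "NOISE_FLOOR",
]

#: NormZ below which a return is treated as below-terrain noise (metres).
NOISE_FLOOR = -0.05


@dataclass(frozen=True)
class LayerThresholds:
    """Height-band cut points in metres of NormZ.

    Ground and low-vegetation bands are half-open at the top; the shrub
    layer is closed at both ends so that no point is left unlabelled:
    ground [noise floor, ground_max), low veg [ground_max, low_max),
    shrub layer [low_max, high_min], high veg (high_min, inf).
    """

    ground_max: float = 0.15
    low_max: float = 0.3
    high_min: float = 3.5

    def __post_init__(self) -> None:
        if not (0 < self.ground_max < self.low_max < self.high_min):
            raise ValueError(
                "thresholds must satisfy 0 < ground_max < low_max < high_min "
                f"(got {self.ground_max}, {self.low_max}, {self.high_min})")


@dataclass
class DtmGrid:
    """Minimum-height terrain raster.

    ``values[r, c]`` is the minimum z of the points whose (x, y) falls in the
    cell with lower-left corner ``(x0 + c*cell, y0 + r*cell)``; cells that
    held no points are filled from the nearest filled cell (planar distance,
    ties by row-major scan order) and flagged in ``filled_from_neighbor``.
    """

    origin: tuple[float, float]
    cell_size: float
    values: np.ndarray
    filled_from_neighbor: np.ndarray  # bool mask

    def cell_index(self, x: np.ndarray, y: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray]:
        col = np.floor((np.asarray(x) - self.origin[0]) / self.cell_size)
        row = np.floor((np.asarray(y) - self.origin[1]) / self.cell_size)
        return row.astype(np.int64), col.astype(np.int64)

    def sample(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Terrain value of the containing cell; error outside the extent."""
        row, col = self.cell_index(x, y)
        nr, nc = self.values.shape
        # points sitting exactly on the top/right edge belong to the last cell
        row = np.where((row == nr) & np.isclose(
            np.asarray(y), self.origin[1] + nr * self.cell_size), nr - 1, row)
        col = np.where((col == nc) & np.isclose(
            np.asarray(x), self.origin[0] + nc * self.cell_size), nc - 1, col)
        if np.any((row < 0) | (row >= nr) | (col < 0) | (col >= nc)):
            bad = int(np.flatnonzero((row < 0) | (row >= nr)
                                     | (col < 0) | (col >= nc))[0])
            raise ValueError(f"point {bad} lies outside the DTM extent")
        return self.values[row, col]

    def to_ascii_grid(self, path: str | Path, nodata: float = -9999.0) -> None:
        write_ascii_grid(path, self.values, self.origin, self.cell_size,
                         nodata=nodata)


def write_ascii_grid(path: str | Path, values: np.ndarray,
                     origin: tuple[float, float], cell_size: float,
                     nodata: float = -9999.0) -> None:
    """Write a 2-D array as an ESRI ASCII raster (row 0 = southern row,
    so rows are emitted north-to-south as the dialect requires)."""
    nr, nc = values.shape
    out = np.where(np.isfinite(values), values, nodata)
    with open(path, "w") as fh:
        fh.write(f"ncols {nc}\nnrows {nr}\n")
        fh.write(f"xllcorner {origin[0]:.6f}\nyllcorner {origin[1]:.6f}\n")
        fh.write(f"cellsize {cell_size:.6f}\nNODATA_value {nodata}\n")
        for r in range(nr - 1, -1, -1):
            fh.write(" ".join(f"{v:.6f}" for v in out[r]) + "\n")


def read_ascii_grid(path: str | Path
                    ) -> tuple[np.ndarray, tuple[float, float], float]:
    """Read an ESRI ASCII raster; returns (values, (x0, y0), cell_size)
    with row 0 as the southern row and NODATA as nan."""
    with open(path) as fh:
        head = {}
        for _ in range(6):
            key, val = fh.readline().split()
            head[key.lower()] = float(val)
        data = np.loadtxt(fh)
    data = np.atleast_2d(data)[::-1]
    data = np.where(data == head.get("nodata_value", -9999.0), np.nan, data)
    return data, (head["xllcorner"], head["yllcorner"]), head["cellsize"]


def build_dtm(cloud: PointCloud, cell_size: float = 1.0) -> DtmGrid:
    """Grid of per-cell minimum point heights covering the cloud bounds.

    Cells without points take the value of the nearest filled cell (planar
    centre-to-centre distance; exact ties resolved by row-major scan order
    of the filled cells).
    """
    if cell_size <= 0:
        raise ValueError(f"cell_size must be positive (got {cell_size})")
    if len(cloud) == 0:
        raise ValueError("cannot build a DTM from an empty cloud")
    xmin, ymin, xmax, ymax = cloud.bounds
    x0 = np.floor(xmin / cell_size) * cell_size
    y0 = np.floor(ymin / cell_size) * cell_size
    nc = max(1, int(np.ceil((xmax - x0) / cell_size)))
    nr = max(1, int(np.ceil((ymax - y0) / cell_size)))
    # points exactly on the top/right bound fold into the last cell
    col = np.minimum(((cloud.x - x0) / cell_size).astype(np.int64), nc - 1)
    row = np.minimum(((cloud.y - y0) / cell_size).astype(np.int64), nr - 1)
    values = np.full((nr, nc), np.inf)
    np.minimum.at(values, (row, col), cloud.z)
    empty = ~np.isfinite(values)
    filled_mask = empty.copy()
    if empty.any():
        if empty.all():  # unreachable: bounds come from the points
            raise ValueError("no filled DTM cells")
        # nearest filled cell by centre distance; ties -> row-major order.
        fr, fc = np.nonzero(~empty)
        er, ec = np.nonzero(empty)
        d2 = ((er[:, None] - fr[None, :]) ** 2
              + (ec[:, None] - fc[None, :]) ** 2)
        nearest = np.argmin(d2, axis=1)  # argmin takes the first = scan order
        values[er, ec] = values[fr[nearest], fc[nearest]]
    return DtmGrid(origin=(float(x0), float(y0)), cell_size=cell_size,
                   values=values, filled_from_neighbor=filled_mask)


def normalize_heights(cloud: PointCloud, dtm: DtmGrid) -> PointCloud:
    """Set ``norm_z = z - DTM(x, y)`` on a copy of the cloud.

    NormZ may be slightly negative where returns scatter below the terrain
    model; values below the -0.05 m noise floor are clamped there and the
    point is flagged ``Layer.NOISE`` (excluded from layering).
    """
    out = cloud.copy()
    ground = dtm.sample(cloud.x, cloud.y)
    nz = cloud.z - ground
    noise = nz < NOISE_FLOOR
    out.norm_z = np.where(noise, NOISE_FLOOR, nz)
    out.layer = np.where(noise, np.uint8(Layer.NOISE), out.layer)
    return out


def assign_layers(cloud: PointCloud,
                  thr: LayerThresholds = LayerThresholds()) -> PointCloud:
    """Partition non-noise points into the four height layers."""
    if np.any(~np.isfinite(cloud.norm_z)):
        raise ValueError("norm_z is unset; run normalize_heights first")
    out = cloud.copy()
    nz = out.norm_z
    layer = np.full(len(out), np.uint8(Layer.SHRUB_LAYER))
    layer[nz < thr.ground_max] = Layer.GROUND
    layer[(nz >= thr.ground_max) & (nz < thr.low_max)] = Layer.LOW_VEG
    layer[nz > thr.high_min] = Layer.HIGH_VEG
    layer[out.layer == Layer.NOISE] = Layer.NOISE
    out.layer = layer
    return out
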