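"""Volume rasterization and linear biomass allometry.

Normalized heights of the target-class points (filtered by their fuzzy
class probability) are rasterized on a 5 cm grid; the per-pixel statistic
of NormZ (mean, max or range) times the 25 cm^2 pixel area gives a volume
metric in m^3. Harvested shrubs are delimited by the 2-D convex hull of
their manual delineation clouds, the summed in-hull pixel volumes are
regressed against oven-dry mass by OLS (mass [g] = a + b * volume [m^3]),
and the fitted model — or the shipped reference fits — converts a volume
raster into a biomass raster, either per pixel or per connected segment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats
from shapely.geometry import MultiPoint, Point

from .pointcloud import HarvestRecord, PointCloud

__all__ = [
    "VolumeRaster", "BiomassModel", "rasterize_volume", "shrub_volume",
    "fit_biomass_model", "reference_models", "predict_biomass",
]

VOLUME_STATS = ("mean", "max", "range")


@dataclass
class VolumeRaster:
    """5 cm grid of NormZ-derived volumes (m^3 per pixel; empty pixels 0).

    ``counts`` records how many surviving points fell in each pixel, which
    distinguishes a truly empty pixel from one whose statistic happens to
    be zero (e.g. range of a single point).
    """

    origin: tuple[float, float]
    cell_size: float
    statistic: str
    values: np.ndarray
    counts: np.ndarray

    @property
    def total_volume(self) -> float:
        return float(self.values.sum())

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        nr, nc = self.values.shape
        cx = self.origin[0] + (np.arange(nc) + 0.5) * self.cell_size
        cy = self.origin[1] + (np.arange(nr) + 0.5) * self.cell_size
        return cx, cy


def _snap_origin(xmin: float, ymin: float, cell: float,
                 ) -> tuple[float, float]:
    return (np.floor(xmin / cell) * cell, np.floor(ymin / cell) * cell)


def rasterize_volume(cloud: PointCloud, target_class: int,
                     statistic: str = "max", cell_size: float = 0.05,
                     prob_min: float = 0.6,
                     extent: tuple[float, float, float, float] | None = None,
                     ) -> VolumeRaster:
    """Rasterize the target class's NormZ statistic times the pixel area.

    Points whose fuzzy probability for ``target_class`` is below
    ``prob_min`` are excluded. ``extent`` (xmin, ymin, xmax, ymax) forces a
    common grid for two-epoch co-registration; by default the grid is
    snapped down to a cell multiple of the cloud bounds.
    """
    if statistic not in VOLUME_STATS:
        raise ValueError(f"statistic must be one of {VOLUME_STATS}")
    if not (0 <= prob_min <= 1):
        raise ValueError("prob_min must lie in [0, 1]")
    if cloud.class_probs is None:
        raise ValueError("cloud carries no class probabilities; classify first")
    if np.any(~np.isfinite(cloud.norm_z)):
        raise ValueError("norm_z is unset; run normalize_heights first")
    probs = cloud.class_probs[:, target_class]
    keep = probs >= prob_min
    if extent is None:
        xmin, ymin, xmax, ymax = cloud.bounds
    else:
        xmin, ymin, xmax, ymax = extent
    x0, y0 = _snap_origin(xmin, ymin, cell_size)
    nc = max(1, int(np.ceil((xmax - x0) / cell_size)))
    nr = max(1, int(np.ceil((ymax - y0) / cell_size)))
    values = np.zeros((nr, nc))
    counts = np.zeros((nr, nc), dtype=np.int64)
    if keep.any():
        x = cloud.x[keep]
        y = cloud.y[keep]
        nz = cloud.norm_z[keep]
        col = np.clip(((x - x0) / cell_size).astype(np.int64), 0, nc - 1)
        row = np.clip(((y - y0) / cell_size).astype(np.int64), 0, nr - 1)
        np.add.at(counts, (row, col), 1)
        if statistic == "mean":
            np.add.at(values, (row, col), nz)
            nonzero = counts > 0
            values[nonzero] /= counts[nonzero]
        else:
            hi = np.full((nr, nc), -np.inf)
            np.maximum.at(hi, (row, col), nz)
            if statistic == "max":
                values = np.where(counts > 0, hi, 0.0)
            else:  # range = max - min
                lo = np.full((nr, nc), np.inf)
                np.minimum.at(lo, (row, col), nz)
                values = np.where(counts > 0, hi - lo, 0.0)
        values = values * cell_size ** 2
        values[counts == 0] = 0.0
    return VolumeRaster(origin=(float(x0), float(y0)), cell_size=cell_size,
                        statistic=statistic, values=values, counts=counts)


def shrub_volume(raster: VolumeRaster, harvest: HarvestRecord) -> float:
    """Summed raster volume inside the shrub's delineation footprint.

    The footprint is the 2-D convex hull of the delineation points; pixels
    whose centres fall inside or on the hull boundary contribute.
    """
    hull = MultiPoint(harvest.delineation_points[:, :2]).convex_hull
    if hull.area <= 0:
        raise ValueError(
            f"shrub {harvest.shrub_id}: delineation hull is degenerate "
            "(zero area)")
    cx, cy = raster.pixel_centers()
    minx, miny, maxx, maxy = hull.bounds
    ci = np.flatnonzero((cx >= minx) & (cx <= maxx))
    ri = np.flatnonzero((cy >= miny) & (cy <= maxy))
    total = 0.0
    for r in ri:
        for c in ci:
            if hull.covers(Point(cx[c], cy[r])):  # covers: boundary-inclusive
                total += raster.values[r, c]
    return float(total)


def adjusted_r2(r2: float, n: int, p: int = 1) -> float:
    """Small-sample-penalized coefficient of determination
    ``1 - (1 - R^2) (n - 1) / (n - p - 1)``."""
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


@dataclass(frozen=True)
class BiomassModel:
    """Linear allometry mass [g] = intercept + slope * volume [m^3]."""

    metric: str
    intercept: float
    slope: float
    r2_adj: float
    spearman_rho: float
    n: int

    def predict(self, volume) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(volume, dtype=float)


def fit_biomass_model(volumes, masses, metric: str = "max") -> BiomassModel:
    """OLS fit of dry mass on volume with small-sample diagnostics.

    Reports the adjusted coefficient of determination
    ``1 - (1 - R^2) (n - 1) / (n - 2)`` (one predictor) and the Spearman
    rank correlation of volumes and masses.
    """
    v = np.asarray(volumes, dtype=np.float64)
    m = np.asarray(masses, dtype=np.float64)
    if v.size != m.size:
        raise ValueError("volumes and masses differ in length")
    if v.size < 3:
        raise ValueError(f"need at least 3 shrubs to fit (got {v.size})")
    if np.ptp(v) == 0:
        raise ValueError("volumes have zero variance; slope is undefined")
    fit = stats.linregress(v, m)
    n = v.size
    r2_adj = adjusted_r2(fit.rvalue ** 2, n)
    rho = stats.spearmanr(v, m).statistic
    return BiomassModel(metric=metric, intercept=float(fit.intercept),
                        slope=float(fit.slope), r2_adj=float(r2_adj),
                        spearman_rho=float(rho), n=n)


def reference_models() -> dict[str, BiomassModel]:
    """The three published allometric fits (10 harvested broom shrubs).

    Coefficients are model-native: grams of dry mass per m^3 of the
    respective 5 cm volume metric.
    """
    return {
        "mean": BiomassModel("mean", 92.49, 4575.88, 0.72, 0.87, 10),
        "max": BiomassModel("max", 77.12, 4696.16, 0.77, 0.88, 10),
        "range": BiomassModel("range", 92.98, 12327.87, 0.61, 0.88, 10),
    }


def predict_biomass(model: BiomassModel, raster: VolumeRaster,
                    mode: str = "per_pixel") -> np.ndarray:
    """Biomass raster in grams from a volume raster.

    ``per_pixel`` applies the allometry to every occupied pixel's volume
    (empty pixels stay 0 — the intercept is never spread over empty
    ground). ``per_segment`` groups occupied pixels into 8-connected
    segments, applies the model to each segment's summed volume, and
    distributes the segment mass over its pixels proportionally to pixel
    volume (equally if the segment volume is 0), which keeps the intercept
    counted once per shrub-like segment.
    """
    occupied = raster.counts > 0
    out = np.zeros_like(raster.values)
    if mode == "per_pixel":
        out[occupied] = model.predict(raster.values[occupied])
        return out
    if mode != "per_segment":
        raise ValueError(f"unknown mode {mode!r}")
    labels, n_seg = ndimage.label(occupied, structure=np.ones((3, 3)))
    for seg in range(1, n_seg + 1):
        sel = labels == seg
        vol = raster.values[sel]
        seg_mass = float(model.predict(vol.sum()))
        total = vol.sum()
        if total > 0:
            out[sel] = seg_mass * vol / total
        else:
            out[sel] = seg_mass / sel.sum()
    return out
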