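"""Point-based structural features of the shrub layer.

Seven per-point attributes describe the local canopy structure of every
shrub-layer return, each computed in a metric search neighbourhood:

================== ========== =====================================================
attribute          radius (m) meaning
================== ========== =====================================================
pseudowaveform     0.5        variance of heights about an orthogonally fitted
                              plane — surface roughness / structural complexity
point_count        0.5        neighbourhood size — surface area and density
ground_point_count 0.1        returns of any layer in a vertical cylinder —
                              light penetration through the canopy
rank               0.1        relative height position in the neighbourhood,
                              scaled 0 (lowest) to 100 (highest)
negative_openness  0.1        mean nadir angle to neighbours — downward-looking
                              concaveness (surface gaps)
point_distance     0.1        mean 3-D distance to neighbours — inverse density
n_echoes_mean      0.1        mean pulse echo count — decreases with penetration
================== ========== =====================================================

Neighbourhoods are closed balls (distance <= r). Counts and means over the
neighbourhood include the focal point itself; pairwise distance and angle
means exclude it. Empty-neighbourhood sentinels: variance 0, rank 100,
openness 90 deg, distance = r_small, echo mean = focal's own echo count.

The variable-selection procedure drops, from every pair of features with
Spearman |rho| above a cutoff (default 0.75), the one with the lower
leave-one-out importance (decrease in overall accuracy when the variable is
left out, averaged over stratified splits).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

from .pointcloud import Layer, PointCloud

__all__ = [
    "FeatureConfig", "FEATURE_NAMES", "ImportanceReport",
    "neighbors", "pseudowaveform", "point_count", "ground_point_count",
    "rank", "negative_openness", "point_distance", "n_echoes_mean",
    "compute_features", "variable_selection",
]

FEATURE_NAMES = (
    "pseudowaveform", "point_count", "ground_point_count", "rank",
    "negative_openness", "point_distance", "n_echoes_mean",
)


@dataclass(frozen=True)
class FeatureConfig:
    """Search radii (metres) and the plane-fit minimum neighbourhood size."""

    r_large: float = 0.5
    r_small: float = 0.1
    min_neighbors_plane: int = 3

    def __post_init__(self) -> None:
        if self.r_small <= 0 or self.r_large <= 0:
            raise ValueError("search radii must be positive")
        if self.r_large < self.r_small:
            raise ValueError("r_large must be >= r_small")


# ---------------------------------------------------------------------------
# neighbourhood primitives


def neighbors(cloud: PointCloud, focal: int, radius: float,
              mode: str = "sphere") -> np.ndarray:
    """Indices of points within ``radius`` of point ``focal`` (self included).

    ``mode='sphere'`` uses 3-D Euclidean distance, ``mode='cylinder'`` the
    planar x-y distance. Closed-ball convention: boundary points included.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if mode == "sphere":
        tree = cKDTree(cloud.xyz)
        q = cloud.xyz[focal]
    elif mode == "cylinder":
        xy = np.column_stack([cloud.x, cloud.y])
        tree = cKDTree(xy)
        q = xy[focal]
    else:
        raise ValueError(f"unknown neighbourhood mode {mode!r}")
    idx = np.asarray(sorted(tree.query_ball_point(q, radius)), dtype=np.int64)
    return idx


def _plane_residual_variance(pts: np.ndarray) -> float:
    """Population variance of signed orthogonal distances to the orthogonal
    least-squares plane of ``pts`` (the smallest eigenvalue direction of the
    neighbourhood covariance)."""
    centred = pts - pts.mean(axis=0)
    cov = centred.T @ centred / pts.shape[0]
    evals, evecs = np.linalg.eigh(cov)  # ascending eigenvalues
    normal = evecs[:, 0]
    # canonical representative: non-negative z, then y, then x component
    for comp in (2, 1, 0):
        if abs(normal[comp]) > 1e-12:
            if normal[comp] < 0:
                normal = -normal
            break
    resid = centred @ normal
    return float(np.mean(resid ** 2))


def pseudowaveform(cloud: PointCloud, focal: int,
                   cfg: FeatureConfig = FeatureConfig()) -> float:
    """Height variance about a normal-fitted plane in the r_large sphere.

    Returns 0 when the neighbourhood is smaller than
    ``cfg.min_neighbors_plane``.
    """
    idx = neighbors(cloud, focal, cfg.r_large, "sphere")
    if idx.size < cfg.min_neighbors_plane:
        return 0.0
    return _plane_residual_variance(cloud.xyz[idx])


def point_count(cloud: PointCloud, focal: int,
                cfg: FeatureConfig = FeatureConfig()) -> int:
    """Size of the r_large spherical neighbourhood (self included)."""
    return int(neighbors(cloud, focal, cfg.r_large, "sphere").size)


def ground_point_count(full_cloud: PointCloud, x: float, y: float,
                       cfg: FeatureConfig = FeatureConfig()) -> int:
    """Returns of any layer within a vertical cylinder of r_small around
    (x, y), ground echoes included — the light-penetration proxy.

    A 0.1 m sphere around an elevated canopy point could never contain
    ground echoes; the cylinder is what makes this attribute sensitive to
    penetration.
    """
    d2 = (full_cloud.x - x) ** 2 + (full_cloud.y - y) ** 2
    return int(np.count_nonzero(d2 <= cfg.r_small ** 2 + 1e-12))


def rank(cloud: PointCloud, focal: int,
         cfg: FeatureConfig = FeatureConfig()) -> float:
    """Relative height position in the r_small sphere, scaled to [0, 100].

    The focal height is ranked among the n neighbourhood heights (1 =
    lowest; ties get the mean of their tied ranks) and mapped by
    ``100 * (k - 1) / (n - 1)``; an isolated point scores 100.
    """
    idx = neighbors(cloud, focal, cfg.r_small, "sphere")
    n = idx.size
    if n <= 1:
        return 100.0
    ranks = stats.rankdata(cloud.z[idx], method="average")
    k = float(ranks[np.flatnonzero(idx == focal)[0]])
    return 100.0 * (k - 1.0) / (n - 1.0)


def negative_openness(cloud: PointCloud, focal: int,
                      cfg: FeatureConfig = FeatureConfig()) -> float:
    """Mean nadir angle (degrees) from the focal point to its r_small
    neighbours: 0 deg for a neighbour straight below, 90 deg for one at the
    same height, 180 deg straight above. No neighbours -> 90."""
    idx = neighbors(cloud, focal, cfg.r_small, "sphere")
    idx = idx[idx != focal]
    if idx.size == 0:
        return 90.0
    v = cloud.xyz[idx] - cloud.xyz[focal]
    d = np.linalg.norm(v, axis=1)
    keep = d > 1e-12  # coincident duplicates carry no direction
    if not keep.any():
        return 90.0
    cos = -v[keep, 2] / d[keep]
    return float(np.degrees(np.arccos(np.clip(cos, -1.0, 1.0))).mean())


def point_distance(cloud: PointCloud, focal: int,
                   cfg: FeatureConfig = FeatureConfig()) -> float:
    """Mean 3-D distance to r_small neighbours (self excluded); r_small
    when the focal point is isolated."""
    idx = neighbors(cloud, focal, cfg.r_small, "sphere")
    idx = idx[idx != focal]
    if idx.size == 0:
        return cfg.r_small
    d = np.linalg.norm(cloud.xyz[idx] - cloud.xyz[focal], axis=1)
    return float(d.mean())


def n_echoes_mean(cloud: PointCloud, focal: int,
                  cfg: FeatureConfig = FeatureConfig()) -> float:
    """Mean pulse echo count over the r_small sphere (self included)."""
    idx = neighbors(cloud, focal, cfg.r_small, "sphere")
    return float(cloud.num_echoes[idx].mean())


# ---------------------------------------------------------------------------
# batch computation


def compute_features(full_cloud: PointCloud,
                     cfg: FeatureConfig = FeatureConfig()) -> pd.DataFrame:
    """All seven features for every SHRUB_LAYER point of ``full_cloud``.

    Spherical neighbourhoods are taken within the shrub-layer subset (the
    classified stratum); only ``ground_point_count`` sees the full cloud.
    Returns a DataFrame indexed by the point's position in ``full_cloud``
    with columns x, y, z, norm_z and the seven features; deterministic and
    invariant to input point order.
    """
    shrub_idx = np.flatnonzero(full_cloud.layer == Layer.SHRUB_LAYER)
    cols = {n: np.zeros(shrub_idx.size) for n in FEATURE_NAMES}
    if shrub_idx.size == 0:
        out = pd.DataFrame(
            {c: np.zeros(0) for c in ("x", "y", "z", "norm_z", *FEATURE_NAMES)})
        out.index.name = "point"
        return out
    shrub = full_cloud.select(shrub_idx)
    pts = shrub.xyz
    tree = cKDTree(pts)
    full_xy_tree = cKDTree(np.column_stack([full_cloud.x, full_cloud.y]))

    nb_large = tree.query_ball_point(pts, cfg.r_large)
    nb_small = tree.query_ball_point(pts, cfg.r_small)
    nb_cyl = full_xy_tree.query_ball_point(
        np.column_stack([shrub.x, shrub.y]), cfg.r_small)

    z = shrub.z
    ne = shrub.num_echoes.astype(np.float64)
    for i in range(shrub_idx.size):
        large = np.asarray(nb_large[i], dtype=np.int64)
        small = np.asarray(nb_small[i], dtype=np.int64)
        cols["point_count"][i] = large.size
        cols["ground_point_count"][i] = len(nb_cyl[i])
        cols["n_echoes_mean"][i] = ne[small].mean()
        if large.size >= cfg.min_neighbors_plane:
            cols["pseudowaveform"][i] = _plane_residual_variance(pts[large])
        n = small.size
        if n <= 1:
            cols["rank"][i] = 100.0
        else:
            ranks = stats.rankdata(z[small], method="average")
            k = float(ranks[np.flatnonzero(small == i)[0]])
            cols["rank"][i] = 100.0 * (k - 1.0) / (n - 1.0)
        others = small[small != i]
        if others.size == 0:
            cols["negative_openness"][i] = 90.0
            cols["point_distance"][i] = cfg.r_small
        else:
            v = pts[others] - pts[i]
            d = np.linalg.norm(v, axis=1)
            keep = d > 1e-12
            if keep.any():
                cos = np.clip(-v[keep, 2] / d[keep], -1.0, 1.0)
                cols["negative_openness"][i] = float(
                    np.degrees(np.arccos(cos)).mean())
            else:
                cols["negative_openness"][i] = 90.0
            cols["point_distance"][i] = float(d.mean())
    out = pd.DataFrame(
        {"x": shrub.x, "y": shrub.y, "z": shrub.z, "norm_z": shrub.norm_z,
         **cols},
        index=pd.Index(shrub_idx, name="point"))
    return out


def write_feature_table(features: pd.DataFrame, path) -> None:
    """Export the feature table as delimited text (one row per point)."""
    features.to_csv(path, index=True, float_format="%.8g")


# ---------------------------------------------------------------------------
# variable selection


@dataclass
class ImportanceReport:
    """Leave-one-out importances, the Spearman correlation matrix and the
    retained variable list of the selection procedure."""

    importance: pd.Series
    correlation: pd.DataFrame
    retained: list[str]


def variable_selection(features: pd.DataFrame, labels: np.ndarray,
                       schema: tuple[str, ...], rho_max: float = 0.75,
                       n_iter: int = 10, base_seed: int = 0,
                       train_frac: float = 0.9, cp: float = 0.001,
                       feature_names: tuple[str, ...] = FEATURE_NAMES,
                       ) -> ImportanceReport:
    """Correlation filter plus leave-one-out importance ranking.

    ``importance(v)`` is the mean over ``n_iter`` stratified splits of
    ``OA(all variables) - OA(all minus v)``; among every pair of variables
    with Spearman ``|rho| > rho_max`` the lower-importance member is
    dropped (ties drop the later variable).
    """
    from .classify import LabeledFeatureSet, evaluate, stratified_split, train_tree

    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("variable selection requires at least 2 classes")
    names = list(feature_names)
    X = features[names].to_numpy(dtype=np.float64)

    def mean_oa(columns: list[int]) -> float:
        data = LabeledFeatureSet(X[:, columns], labels, schema,
                                 tuple(names[c] for c in columns))
        oas = []
        for it in range(n_iter):
            train, test = stratified_split(data, train_frac, base_seed + it)
            model = train_tree(train, cp=cp)
            rep = evaluate(model.predict(test.features), test.labels,
                           len(schema))
            oas.append(rep.overall_accuracy)
        return float(np.mean(oas))

    all_cols = list(range(len(names)))
    oa_full = mean_oa(all_cols)
    importance = pd.Series(
        {names[v]: oa_full - mean_oa([c for c in all_cols if c != v])
         for v in all_cols})

    corr = pd.DataFrame(X, columns=names).corr(method="spearman")

    retained = list(names)
    while True:
        worst = None
        for i, a in enumerate(retained):
            for b in retained[i + 1:]:
                if abs(corr.loc[a, b]) > rho_max:
                    drop = b if importance[a] >= importance[b] else a
                    if worst is None or importance[drop] < importance[worst]:
                        worst = drop
        if worst is None:
            break
        retained.remove(worst)
    return ImportanceReport(importance=importance, correlation=corr,
                            retained=retained)
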