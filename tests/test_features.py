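"""Structural features against independently coded oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import shrubscan as ss
from shrubscan.features import (FEATURE_NAMES, FeatureConfig, neighbors,
                                negative_openness, n_echoes_mean,
                                point_count, point_distance, pseudowaveform,
                                rank, variable_selection)
from shrubscan.features import ground_point_count
from shrubscan.pointcloud import Layer

from conftest import make_cloud


# ---------------------------------------------------------------------------
# independent oracles (deliberately different code paths)


def oracle_neighbors(cloud, focal, radius, mode):
    out = []
    for j in range(len(cloud)):
        dx = cloud.x[j] - cloud.x[focal]
        dy = cloud.y[j] - cloud.y[focal]
        dz = cloud.z[j] - cloud.z[focal]
        d = math.hypot(dx, dy) if mode == "cylinder" else \
            math.sqrt(dx * dx + dy * dy + dz * dz)
        if d <= radius:
            out.append(j)
    return out


def oracle_plane_variance(pts):
    """SVD route (vs the implementation's covariance eigen-decomposition)."""
    centred = pts - pts.mean(axis=0)
    _, s, vt = np.linalg.svd(centred, full_matrices=False)
    normal = vt[-1]
    resid = centred @ normal
    return float((resid ** 2).sum() / pts.shape[0])


def oracle_openness(cloud, focal, radius):
    angles = []
    for j in oracle_neighbors(cloud, focal, radius, "sphere"):
        if j == focal:
            continue
        v = cloud.xyz[j] - cloud.xyz[focal]
        nv = np.linalg.norm(v)
        if nv < 1e-12:
            continue
        angles.append(math.degrees(math.acos(
            max(-1.0, min(1.0, float(np.dot(v / nv, [0, 0, -1])))))))
    return float(np.mean(angles)) if angles else 90.0


def simple_cloud(xyz, num_echoes=None):
    xyz = np.asarray(xyz, dtype=float)
    n = xyz.shape[0]
    ne = np.ones(n, int) if num_echoes is None else np.asarray(num_echoes)
    return ss.PointCloud(xyz[:, 0], xyz[:, 1], xyz[:, 2],
                         np.ones(n, int), ne)


# ---------------------------------------------------------------------------


class TestNeighbors:
    def test_isolated_focal_returns_itself(self):
        c = simple_cloud([[0, 0, 0], [10, 10, 10]])
        assert list(neighbors(c, 0, 0.5)) == [0]

    def test_boundary_point_included(self):
        c = simple_cloud([[0, 0, 0], [0.5, 0, 0]])
        assert list(neighbors(c, 0, 0.5)) == [0, 1]

    @pytest.mark.parametrize("mode", ["sphere", "cylinder"])
    def test_matches_exhaustive_scan(self, mode):
        c = make_cloud(300, seed=21, extent=3.0)
        rng = np.random.default_rng(0)
        for focal in rng.integers(0, 300, 20):
            got = sorted(neighbors(c, int(focal), 0.7, mode))
            assert got == oracle_neighbors(c, int(focal), 0.7, mode)


class TestPseudowaveform:
    def test_coplanar_points_have_zero_variance(self):
        rng = np.random.default_rng(1)
        uv = rng.uniform(-0.3, 0.3, (10, 2))
        # tilted plane z = 0.2x + 0.1y
        pts = np.column_stack([uv[:, 0], uv[:, 1],
                               0.2 * uv[:, 0] + 0.1 * uv[:, 1]])
        c = simple_cloud(pts)
        assert pseudowaveform(c, 0) == pytest.approx(0.0, abs=1e-12)

    def test_below_min_neighbors_returns_zero(self):
        c = simple_cloud([[0, 0, 0], [0.1, 0, 0]])
        assert pseudowaveform(c, 0) == 0.0

    def test_noisy_plane_variance_and_dual_implementation(self):
        rng = np.random.default_rng(2)
        uv = rng.uniform(-0.3, 0.3, (50, 2))
        z = rng.normal(0, 0.05, 50)
        pts = np.vstack([[0.0, 0.0, 0.0], np.column_stack([uv, z])])
        c = simple_cloud(pts)
        got = pseudowaveform(c, 0)
        # every point falls inside the focal origin's 0.5 m sphere
        idx = neighbors(c, 0, 0.5)
        assert len(idx) == 51
        assert got == pytest.approx(oracle_plane_variance(pts), abs=1e-10)
        assert got == pytest.approx(0.0025, rel=0.5)  # sigma^2 = 0.0025 m^2

    def test_rigid_rotation_invariance(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(-0.2, 0.2, (30, 3)) * [1, 1, 0.2]
        c = simple_cloud(pts)
        base = pseudowaveform(c, 0)
        theta = 0.7
        rot = np.array([[1, 0, 0],
                        [0, math.cos(theta), -math.sin(theta)],
                        [0, math.sin(theta), math.cos(theta)]])
        c2 = simple_cloud(pts @ rot.T)
        assert pseudowaveform(c2, 0) == pytest.approx(base, abs=1e-10)


class TestCountsAndDistances:
    def test_point_count_includes_self(self):
        c = simple_cloud([[0, 0, 0]] + [[0.1 * k, 0, 0] for k in range(1, 5)])
        assert point_count(c, 0) == 5
        lone = simple_cloud([[0, 0, 0], [9, 9, 9]])
        assert point_count(lone, 0) == 1

    def test_ground_count_cylinder_vs_sphere_geometry(self):
        # a canopy point 1 m up with a ground echo 5 cm away in x-y:
        # the cylinder sees both, a 0.1 m sphere would see only the focal
        c = simple_cloud([[0, 0, 1.0], [0.05, 0, 0.0]])
        assert ground_point_count(c, 0.0, 0.0) == 2
        assert len(neighbors(c, 0, 0.1, "sphere")) == 1

    def test_point_distance_single_neighbor_and_sentinel(self):
        c = simple_cloud([[0, 0, 0], [0.05, 0, 0]])
        assert point_distance(c, 0) == pytest.approx(0.05)
        lone = simple_cloud([[0, 0, 0], [5, 5, 5]])
        assert point_distance(lone, 0) == pytest.approx(0.1)  # = r_small

    def test_echo_mean(self):
        c = simple_cloud([[0, 0, 0], [0.02, 0, 0], [0.04, 0, 0],
                          [0.06, 0, 0]], num_echoes=[1, 1, 2, 2])
        assert n_echoes_mean(c, 0) == pytest.approx(1.5)
        ones = simple_cloud([[0, 0, 0], [0.02, 0, 0]])
        assert n_echoes_mean(ones, 0) == pytest.approx(1.0)


class TestRank:
    def test_midpoint_and_extremes(self):
        zs = [0.01, 0.02, 0.03, 0.04, 0.05]
        pts = [[0.01 * k, 0, z] for k, z in enumerate(zs)]
        c = simple_cloud(pts)
        assert rank(c, 2) == pytest.approx(50.0)
        assert rank(c, 4) == pytest.approx(100.0)
        assert rank(c, 0) == pytest.approx(0.0)

    def test_all_tied_heights(self):
        pts = [[0.01 * k, 0, 1.0] for k in range(4)]
        c = simple_cloud(pts)
        # mean tied rank 2.5 -> (2.5 - 1) / 3 * 100
        assert rank(c, 0) == pytest.approx(50.0)

    def test_isolated_point(self):
        c = simple_cloud([[0, 0, 0], [9, 9, 9]])
        assert rank(c, 0) == pytest.approx(100.0)


class TestNegativeOpenness:
    def test_neighbor_below_is_zero_degrees(self):
        c = simple_cloud([[0, 0, 1.0], [0, 0, 0.95]])
        assert negative_openness(c, 0) == pytest.approx(0.0, abs=1e-9)

    def test_neighbor_at_same_height_is_ninety(self):
        c = simple_cloud([[0, 0, 1.0], [0.05, 0, 1.0]])
        assert negative_openness(c, 0) == pytest.approx(90.0, abs=1e-9)

    def test_matches_acos_oracle_on_random_neighbors(self):
        rng = np.random.default_rng(4)
        pts = np.vstack([[0, 0, 0], rng.uniform(-0.07, 0.07, (100, 3))])
        c = simple_cloud(pts)
        assert negative_openness(c, 0) == pytest.approx(
            oracle_openness(c, 0, 0.1), abs=1e-9)


class TestComputeFeatures:
    def _layered(self, cloud):
        dtm = ss.build_dtm(cloud)
        return ss.assign_layers(ss.normalize_heights(cloud, dtm))

    def test_two_point_shrub_cloud_gives_two_rows(self):
        cloud = ss.PointCloud([0.5, 0.6, 0.7], [0.5, 0.6, 0.7],
                              [40.0, 41.0, 41.1], [1, 1, 1], [1, 1, 1])
        table = ss.compute_features(self._layered(cloud))
        assert len(table) == 2  # the terrain-minimum point is GROUND
        assert set(FEATURE_NAMES) <= set(table.columns)

    def test_permutation_invariance(self):
        cloud = make_cloud(200, seed=22, extent=4.0, zlo=40.0, zhi=43.0)
        layered = self._layered(cloud)
        t1 = ss.compute_features(layered)
        rng = np.random.default_rng(1)
        perm = rng.permutation(len(cloud))
        t2 = ss.compute_features(layered.select(perm))
        # map each original shrub point to its permuted row
        inv = np.empty(len(cloud), dtype=int)
        inv[perm] = np.arange(len(cloud))
        t2 = t2.loc[inv[t1.index.to_numpy()]]
        for col in FEATURE_NAMES:
            np.testing.assert_allclose(t2[col].to_numpy(), t1[col].to_numpy(),
                                       atol=1e-9)

    def test_translation_invariance(self):
        cloud = make_cloud(150, seed=23, extent=4.0, zlo=40.0, zhi=43.0)
        layered = self._layered(cloud)
        t1 = ss.compute_features(layered)
        shifted = layered.copy()
        shifted.x = layered.x + 1000.0
        shifted.y = layered.y - 500.0
        shifted.z = layered.z + 77.0
        t2 = ss.compute_features(shifted)
        for col in FEATURE_NAMES:
            np.testing.assert_allclose(t2[col].to_numpy(), t1[col].to_numpy(),
                                       atol=1e-7)

    def test_full_oracle_comparison_small_scene(self):
        cloud = make_cloud(300, seed=24, extent=3.0, zlo=40.0, zhi=43.0)
        layered = self._layered(cloud)
        table = ss.compute_features(layered)
        shrub_idx = np.flatnonzero(layered.layer == Layer.SHRUB_LAYER)
        shrub = layered.select(shrub_idx)
        cfg = FeatureConfig()
        rng = np.random.default_rng(5)
        for local in rng.integers(0, len(shrub), 15):
            local = int(local)
            row = table.iloc[local]
            sphere = oracle_neighbors(shrub, local, cfg.r_large, "sphere")
            assert row["point_count"] == len(sphere)
            if len(sphere) >= cfg.min_neighbors_plane:
                assert row["pseudowaveform"] == pytest.approx(
                    oracle_plane_variance(shrub.xyz[sphere]), abs=1e-10)
            cyl = [j for j in range(len(layered))
                   if math.hypot(layered.x[j] - shrub.x[local],
                                 layered.y[j] - shrub.y[local]) <= cfg.r_small]
            assert row["ground_point_count"] == len(cyl)
            assert row["negative_openness"] == pytest.approx(
                oracle_openness(shrub, local, cfg.r_small), abs=1e-9)
            small = [j for j in oracle_neighbors(shrub, local, cfg.r_small,
                                                 "sphere") if j != local]
            if small:
                dists = [float(np.linalg.norm(shrub.xyz[j] - shrub.xyz[local]))
                         for j in small]
                assert row["point_distance"] == pytest.approx(
                    np.mean(dists), abs=1e-10)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.lists(st.tuples(
    st.floats(-0.1, 0.1), st.floats(-0.1, 0.1), st.floats(-0.1, 0.1)),
    min_size=1, max_size=20), st.integers(0, 10 ** 6))
def test_rank_and_openness_ranges(offsets, salt):
    """rank in [0, 100] and openness in [0, 180] on arbitrary neighbourhoods."""
    pts = np.array([[0.0, 0.0, 0.0]] + [list(o) for o in offsets])
    n = pts.shape[0]
    c = ss.PointCloud(pts[:, 0], pts[:, 1], pts[:, 2],
                      np.ones(n, int), np.ones(n, int))
    r = rank(c, 0)
    o = negative_openness(c, 0)
    assert 0.0 <= r <= 100.0
    assert 0.0 <= o <= 180.0


class TestVariableSelection:
    def _separable(self, n=60, seed=0):
        rng = np.random.default_rng(seed)
        labels = np.repeat([0, 1], n // 2)
        sep = np.where(labels == 0, 0.0, 10.0) + rng.normal(0, 0.5, n)
        noise = rng.normal(0, 1, n)
        import pandas as pd
        df = pd.DataFrame({"sep": sep, "dup": sep * 2.0 + 1.0, "noise": noise})
        return df, labels

    def test_duplicated_variable_drops_exactly_one(self):
        df, labels = self._separable()
        rep = variable_selection(df, labels, ("a", "b"), n_iter=3,
                                 feature_names=("sep", "dup", "noise"))
        assert ("sep" in rep.retained) != ("dup" in rep.retained)
        assert rep.correlation.loc["sep", "dup"] == pytest.approx(1.0)

    def test_noise_variable_has_near_zero_importance(self):
        df, labels = self._separable()
        rep = variable_selection(df, labels, ("a", "b"), n_iter=5,
                                 feature_names=("sep", "noise"))
        assert abs(rep.importance["noise"]) <= 0.02

    def test_perfect_separator_has_highest_importance(self):
        df, labels = self._separable()
        rep = variable_selection(df, labels, ("a", "b"), n_iter=5,
                                 feature_names=("sep", "noise"))
        assert rep.importance.idxmax() == "sep"

    def test_single_class_is_error(self):
        df, labels = self._separable()
        with pytest.raises(ValueError, match="2 classes"):
            variable_selection(df, np.zeros_like(labels), ("a",), n_iter=2,
                               feature_names=("sep", "noise"))

    def test_correlation_matrix_symmetric_unit_diagonal(self):
        df, labels = self._separable()
        rep = variable_selection(df, labels, ("a", "b"), n_iter=2,
                                 feature_names=("sep", "dup", "noise"))
        m = rep.correlation.to_numpy()
        np.testing.assert_allclose(m, m.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(m), 1.0)
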