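"""KDE bandwidths, sampling-grid construction, nearest-image sampling."""

import numpy as np
import pandas as pd
import pytest

from cellqc import (
    BandwidthSet,
    ImageFeatureTable,
    PhenotypeSampler,
    build_grid,
    build_grid_bruteforce,
    filter_outlier_images,
    fit_bandwidths,
    sample_images,
)
from cellqc.exceptions import ParameterError

from .conftest import make_gaussian_clusters


def _table_from_array(X, prefix="w"):
    X = np.atleast_2d(np.asarray(X, float))
    frame = pd.DataFrame(
        X,
        columns=[f"f{j}" for j in range(X.shape[1])],
        index=pd.Index([f"{prefix}{i:05d}" for i in range(len(X))], name="image_id"),
    )
    return ImageFeatureTable(frame)


class TestFitBandwidths:
    def test_normal_sample_near_reference_rule(self):
        """CV-selected h for a standard normal should sit within a factor
        of two of the asymptotic reference 1.06*sigma*n^(-1/5)."""
        rng = np.random.default_rng(123)
        x = rng.normal(size=2000)
        table = _table_from_array(np.column_stack([x, rng.normal(size=2000)]))
        bw = fit_bandwidths(table, features=["f0"], seed=5)
        ref = 1.06 * x.std() * 2000 ** (-1 / 5)
        assert ref / 2 < bw.h["f0"] < ref * 2

    def test_scale_equivariance(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=1500)
        t1 = _table_from_array(np.column_stack([x, x * 10.0]))
        bw = fit_bandwidths(t1, seed=5)
        # same sample, same fold shuffling: h scales with the data up to
        # the (log-spaced) candidate-grid resolution
        ratio = bw.h["f1"] / bw.h["f0"]
        assert 10 / 1.5 < ratio < 10 * 1.5

    def test_constant_feature_names_the_culprit(self):
        t = _table_from_array(np.column_stack([np.ones(100), np.arange(100.0)]))
        with pytest.raises(ParameterError, match="f0"):
            fit_bandwidths(t)

    def test_too_few_rows(self):
        t = _table_from_array(np.random.default_rng(0).normal(size=(6, 2)))
        with pytest.raises(ParameterError):
            fit_bandwidths(t, folds=5)


def _manual_bw(h: dict) -> BandwidthSet:
    return BandwidthSet(h=h)


class TestBuildGrid:
    def test_data_on_lattice_all_retained(self):
        """When the data ARE the lattice points, nothing is pruned."""
        xs, ys = np.meshgrid(np.arange(5.0), np.arange(4.0), indexing="ij")
        data = np.column_stack([xs.ravel(), ys.ravel()])
        table = _table_from_array(data)
        grid = build_grid(table, _manual_bw({"f0": 1.0, "f1": 1.0}), K=1)
        assert len(grid) == 20
        got = {tuple(p) for p in grid.points}
        assert got == {tuple(d) for d in data}

    def test_empty_quadrant_has_no_points(self):
        rng = np.random.default_rng(1)
        data = np.abs(rng.normal(size=(400, 2)))  # first quadrant only
        table = _table_from_array(data)
        grid = build_grid(table, _manual_bw({"f0": 0.3, "f1": 0.3}), K=1)
        assert len(grid) > 0
        r = np.sqrt(0.3**2 + 0.3**2)
        assert (grid.points >= -r).all()

    def test_support_radius_invariant_exact(self):
        """Every retained point has a data point within the final radius."""
        table, _ = make_gaussian_clusters(3, np.array([[0, 0, 0], [8, 8, 8.0]]), 150)
        bw = _manual_bw({"f0": 0.8, "f1": 0.8, "f2": 0.8})
        grid = build_grid(table, bw, K=2)
        from scipy.spatial import cKDTree

        dist, _ = cKDTree(table.matrix(grid.dims)).query(grid.points)
        assert (dist <= bw.radius(grid.dims) + 1e-12).all()

    def test_iterative_subset_of_bruteforce(self):
        """3-D isotropic clusters: the iterative grid is always a subset of
        the single full-lattice prune (early pruning can only remove)."""
        table, _ = make_gaussian_clusters(
            17, np.array([[0, 0, 0], [10, 0, 5], [0, 12, -6.0]]), 300
        )
        bw = fit_bandwidths(table, seed=2)
        grid = build_grid(table, bw, K=2)
        brute = build_grid_bruteforce(table, bw, K=2)
        it_set = {tuple(np.round(p, 9)) for p in grid.points}
        bf_set = {tuple(np.round(p, 9)) for p in brute}
        assert it_set <= bf_set

    def test_oracle_equality_on_shipped_fixture(self, oracle_fixture):
        """On the shipped 3-feature fixture early pruning loses nothing:
        the discrepancy shell has width ~ h3^2 / (2 r2), negligible when
        the last dimension's bandwidth is small against the 2-D radius."""
        table = oracle_fixture
        bw = fit_bandwidths(table, seed=2)
        dims = ["f0", "f1", "f2"]  # fine dimension last: harmless early pruning
        grid = build_grid(table, bw, K=2, dim_order=dims)
        brute = build_grid_bruteforce(table, bw, K=2, dim_order=dims)
        it_set = {tuple(np.round(p, 9)) for p in grid.points}
        bf_set = {tuple(np.round(p, 9)) for p in brute}
        assert it_set == bf_set

    def test_fewer_than_two_dims_rejected(self):
        table = _table_from_array(np.random.default_rng(0).normal(size=(50, 2)))
        with pytest.raises(ParameterError):
            build_grid(table, _manual_bw({"f0": 1.0}), K=1, dim_order=["f0"])

    def test_invalid_K(self):
        table = _table_from_array(np.random.default_rng(0).normal(size=(50, 2)))
        with pytest.raises(ParameterError):
            build_grid(table, _manual_bw({"f0": 1.0, "f1": 1.0}), K=0)


class TestSampleImages:
    def test_grid_point_on_data_point_samples_it(self):
        data = np.array([[0.0, 0.0], [5.0, 5.0], [9.0, 1.0]])
        table = _table_from_array(data)
        grid = build_grid(table, _manual_bw({"f0": 2.0, "f1": 2.0}), K=1)
        sampled = sample_images(grid, table)
        assert "w00000" in sampled.image_ids  # lattice anchors at the minimum

    def test_duplicate_matches_deduplicated(self):
        data = np.array([[0.0, 0.0], [100.0, 100.0]])
        table = _table_from_array(data)
        grid = build_grid(table, _manual_bw({"f0": 30.0, "f1": 30.0}), K=1)
        sampled = sample_images(grid, table)
        assert len(grid) > 2
        assert len(sampled.image_ids) <= 2
        assert len(sampled.image_ids) == len(set(sampled.image_ids))

    def test_tie_broken_by_lowest_image_id(self):
        # two data points equidistant from the single lattice point between
        data = np.array([[0.0, 0.0], [2.0, 0.0]])
        frame = pd.DataFrame(data, columns=["f0", "f1"],
                             index=pd.Index(["zz", "aa"], name="image_id"))
        table = ImageFeatureTable(frame)
        grid_points = np.array([[1.0, 0.0]])
        from cellqc.sampler import SamplingGrid

        grid = SamplingGrid(
            dims=["f0", "f1"], spacing={"f0": 1.0, "f1": 1.0},
            origins={"f0": 0.0, "f1": 0.0}, points=grid_points, K=1,
        )
        sampled = sample_images(grid, table)
        assert sampled.matches.tolist() == ["aa"]

    def test_empty_grid_advises_smaller_K(self):
        table = _table_from_array(np.random.default_rng(0).normal(size=(30, 2)))
        from cellqc.sampler import SamplingGrid

        grid = SamplingGrid(
            dims=["f0", "f1"], spacing={}, origins={},
            points=np.empty((0, 2)), K=5,
        )
        with pytest.raises(ParameterError, match="K"):
            sample_images(grid, table)


@pytest.fixture(scope="module")
def clustered():
    centers = np.array(
        [[0, 0, 0], [10, 0, 4], [0, 12, -5], [10, 12, 0], [5, 6, 10.0]]
    )
    return make_gaussian_clusters(31, centers, [150, 120, 110, 100, 110], sigma=0.8)


class TestSamplerProperties:
    def test_every_cluster_represented_at_K2(self, clustered):
        table, labels = clustered
        sampler = PhenotypeSampler(K=2, seed=4)
        sampled = sampler.fit_sample(table)
        got = labels[[table.image_ids.index(i) for i in sampled.image_ids]]
        assert set(got) == set(range(5))

    def test_sample_size_non_increasing_in_K(self, clustered):
        table, _ = clustered
        sizes = [len(PhenotypeSampler(K=K, seed=4).fit_sample(table)) for K in (1, 2, 4)]
        assert sizes[0] >= sizes[1] >= sizes[2] > 0

    def test_determinism(self, clustered):
        table, _ = clustered
        a = PhenotypeSampler(K=2, seed=9).fit_sample(table)
        b = PhenotypeSampler(K=2, seed=9).fit_sample(table)
        assert a.image_ids == b.image_ids
        np.testing.assert_array_equal(a.matches, b.matches)

    def test_rare_phenotype_retained(self, default_assay):
        """A 1%-weight planted phenotype still contributes samples."""
        img, _, truth = default_assay
        inliers, _ = filter_outlier_images(img)
        sampled = PhenotypeSampler(K=2, seed=4).fit_sample(inliers)
        rare = (truth.image_phenotype.reindex(sampled.image_ids) == 4).sum()
        assert rare >= 1
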