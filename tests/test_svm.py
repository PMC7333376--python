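"""One-class SVM ensemble: training contract, unanimity rule, screening."""

import numpy as np
import pandas as pd
import pytest

from cellqc import (
    CellFeatureTable,
    OneClassSVMEnsemble,
    classify_cells,
    collect_training_cells,
    group_phenotypes,
    record_verdicts,
    screen_training_cells,
    train_ensemble,
)
from cellqc.exceptions import ParameterError, SchemaError
from cellqc.grouping import EXCLUDE, INCLUDE

from .conftest import make_gaussian_clusters

RNG = np.random.default_rng(77)


def _cells(n, center, sigma=1.0, image_id="w0", start_obj=1, rng=RNG):
    d = len(center)
    X = np.asarray(center) + sigma * rng.normal(size=(n, d))
    frame = pd.DataFrame(X, columns=[f"d{k}" for k in range(d)])
    frame.insert(0, "area_px", rng.integers(80, 400, size=n))
    frame.insert(0, "object_id", np.arange(start_obj, start_obj + n))
    frame.insert(0, "image_id", image_id)
    return frame


class TestScreenTrainingCells:
    def test_planted_extremes_removed(self):
        rng = np.random.default_rng(5)
        good = _cells(500, np.zeros(8), rng=rng)
        bad = _cells(10, np.full(8, 25.0), image_id="w1", rng=rng)
        cells = pd.concat([good, bad], ignore_index=True)
        names = [f"d{k}" for k in range(8)]
        kept = screen_training_cells(cells, names, contamination=10 / 510)
        removed = cells.index.difference(kept.index)
        assert len(set(removed) & set(bad.index + 500)) >= 9

    def test_contamination_zero_is_identity(self):
        cells = _cells(100, np.zeros(4))
        kept = screen_training_cells(cells, [f"d{k}" for k in range(4)], contamination=0.0)
        pd.testing.assert_frame_equal(kept, cells)

    def test_tiny_subset_skipped(self, caplog):
        cells = _cells(5, np.zeros(4))
        with caplog.at_level("WARNING", logger="cellqc"):
            kept = screen_training_cells(cells, [f"d{k}" for k in range(4)], n_neighbors=20)
        assert len(kept) == 5


@pytest.fixture(scope="module")
def training():
    rng = np.random.default_rng(11)
    X = np.vstack(
        [
            rng.normal(size=(800, 8)),
            np.array([0, 20, 0, 0, 0, 0, 0, 0]) + rng.normal(size=(700, 8)),
        ]
    )
    y = np.concatenate([np.zeros(800), np.ones(700)]).astype(int)
    return X, y


class TestEnsembleTrainingContract:
    def test_gamma_reciprocal_of_descriptor_count(self, training):
        X, y = training
        ens = OneClassSVMEnsemble().fit(X, y)
        assert ens.gamma_ == pytest.approx(1 / 8)

    def test_self_classification_rate_bound(self, training):
        """nu bounds the training-error fraction: with nu = 1e-3 each member
        must accept nearly all of its own screened training cells."""
        X, y = training
        ens = OneClassSVMEnsemble(nu=1e-3, screen_contamination=0.0).fit(X, y)
        for m in ens.members_:
            Xg = X[y == m.group_id]
            rate = m.is_inlier(Xg).mean()
            assert rate >= 1 - 1e-3 - 0.01

    def test_raising_nu_tightens_boundary(self, training):
        X, y = training
        loose = OneClassSVMEnsemble(nu=1e-3, screen_contamination=0.0).fit(X, y)
        tight = OneClassSVMEnsemble(nu=0.5, screen_contamination=0.0).fit(X, y)
        for ml, mt in zip(loose.members_, tight.members_):
            Xg = X[y == ml.group_id]
            assert mt.is_inlier(Xg).mean() < ml.is_inlier(Xg).mean()

    def test_far_field_cell_is_artifact(self, training):
        X, y = training
        ens = OneClassSVMEnsemble().fit(X, y)
        far = np.full((1, 8), 100.0)
        assert ens.predict(far)[0] == -1

    def test_training_support_vector_is_valid(self, training):
        X, y = training
        ens = OneClassSVMEnsemble(screen_contamination=0.0).fit(X, y)
        m = ens.members_[0]
        sv_std = m.svm.support_vectors_[:1]
        sv_raw = m.scaler.inverse_transform(sv_std)
        assert m.is_inlier(sv_raw)[0]

    def test_small_groups_dropped(self, training):
        X, y = training
        y2 = y.copy()
        y2[:10] = 7  # a 10-cell group, below min_train_cells
        ens = OneClassSVMEnsemble(min_train_cells=50).fit(X, y2)
        assert 7 not in [m.group_id for m in ens.members_]

    def test_no_trainable_group_is_error(self):
        X = np.random.default_rng(0).normal(size=(30, 4))
        with pytest.raises(ParameterError):
            OneClassSVMEnsemble(min_train_cells=50).fit(X, np.zeros(30))

    def test_invalid_nu(self, training):
        X, y = training
        with pytest.raises(ParameterError):
            OneClassSVMEnsemble(nu=1.5).fit(X, y)


@pytest.fixture(scope="module")
def fixture_cells(default_assay):
    _, cells, _ = default_assay
    return cells


@pytest.fixture(scope="module")
def ensemble(default_assay):
    """Ensemble trained on planted phenotype labels: the unanimity tests
    exercise the decision algebra, not the sampling pipeline."""
    img, cells, truth = default_assay
    key = cells.frame.set_index(["image_id", "object_id"]).index
    lab = truth.cell_label.reindex(key).to_numpy()
    valid = lab >= 0
    return OneClassSVMEnsemble().fit(
        cells.descriptors()[valid][:12000],
        lab[valid][:12000],
        descriptor_names=cells.descriptor_names,
    )


class TestUnanimityRule:
    def test_artifact_set_is_intersection_of_member_outlier_sets(self, ensemble, fixture_cells):
        X = fixture_cells.descriptors()[:10000]
        member_ok = ensemble.membership(X)
        artifact = ensemble.predict(X) == -1
        outlier_sets = [set(np.flatnonzero(~member_ok[:, j])) for j in range(member_ok.shape[1])]
        expected = set.intersection(*outlier_sets)
        assert set(np.flatnonzero(artifact)) == expected

    def test_adding_member_never_grows_artifact_set(self, ensemble, fixture_cells):
        X = fixture_cells.descriptors()[:10000]
        full = set(np.flatnonzero(ensemble.predict(X) == -1))
        import copy

        reduced = copy.deepcopy(ensemble)
        reduced.members_ = reduced.members_[:-1]
        smaller = set(np.flatnonzero(reduced.predict(X) == -1))
        assert full <= smaller

    def test_verdict_frame_consistency(self, ensemble, fixture_cells):
        sub = CellFeatureTable(
            fixture_cells.frame.iloc[:5000].copy(), list(fixture_cells.descriptor_names)
        )
        verdicts = classify_cells(ensemble, sub)
        inlier_cols = [c for c in verdicts.columns if c.startswith("inlier_")]
        np.testing.assert_array_equal(
            verdicts["is_artifact"], ~verdicts[inlier_cols].any(axis=1)
        )

    def test_batched_classification_identical(self, ensemble, fixture_cells):
        sub = CellFeatureTable(
            fixture_cells.frame.iloc[:8000].copy(), list(fixture_cells.descriptor_names)
        )
        whole = classify_cells(ensemble, sub)
        batched = classify_cells(ensemble, sub, batch_images=17)
        pd.testing.assert_frame_equal(
            whole.sort_values(["image_id", "object_id"]).reset_index(drop=True),
            batched.sort_values(["image_id", "object_id"]).reset_index(drop=True),
        )

    def test_descriptor_mismatch_names_columns(self, ensemble, fixture_cells):
        frame = fixture_cells.frame.iloc[:50].copy()
        frame = frame.rename(columns={"solidity": "roundness"})
        bad = CellFeatureTable(frame)
        with pytest.raises(SchemaError, match="solidity"):
            classify_cells(ensemble, bad)

    def test_determinism(self, ensemble, fixture_cells):
        X = fixture_cells.descriptors()[:3000]
        np.testing.assert_array_equal(ensemble.predict(X), ensemble.predict(X))


class TestCollectTrainingCells:
    def _setup(self):
        table, _ = make_gaussian_clusters(5, np.array([[0, 0], [12, 0.0]]), 30)
        grouping = group_phenotypes(table, n_up=2, seed=0, min_members=5)
        ids = np.asarray(table.image_ids)
        frames = [
            _cells(3, np.zeros(4), image_id=i, rng=np.random.default_rng(j))
            for j, i in enumerate(ids[:40])
        ]
        cells = CellFeatureTable(pd.concat(frames, ignore_index=True))
        return grouping, cells

    def test_excluded_group_contributes_nothing(self):
        grouping, cells = self._setup()
        g0, g1 = grouping.effective_groups[:2]
        record_verdicts(grouping, {g0: INCLUDE, g1: EXCLUDE})
        per_group = collect_training_cells(cells, grouping)
        assert set(per_group) == {g0}
        allowed = set(grouping.images_in(g0))
        assert set(per_group[g0]["image_id"]) <= allowed

    def test_zero_cell_group_dropped_with_warning(self, caplog):
        grouping, cells = self._setup()
        g0, g1 = grouping.effective_groups[:2]
        record_verdicts(grouping, {g0: INCLUDE, g1: INCLUDE})
        # keep only cells of g0's images: g1 becomes an empty-well group
        keep = cells.frame["image_id"].isin(set(grouping.images_in(g0)))
        cells_g0 = CellFeatureTable(cells.frame[keep].copy(), list(cells.descriptor_names))
        with caplog.at_level("WARNING", logger="cellqc"):
            per_group = collect_training_cells(cells_g0, grouping)
        assert set(per_group) == {g0}
        assert "no cells" in caplog.text


def test_train_ensemble_from_tables(default_assay):
    img, cells, truth = default_assay
    table, _ = make_gaussian_clusters(5, np.array([[0, 0], [12, 0.0]]), 30)
    grouping = group_phenotypes(table, n_up=2, seed=0, min_members=5)
    ids = list(table.frame.index)
    rng = np.random.default_rng(3)
    frames = [
        _cells(20, np.zeros(6), image_id=i, rng=rng) for i in ids
    ]
    cells = CellFeatureTable(pd.concat(frames, ignore_index=True))
    record_verdicts(grouping, {g: INCLUDE for g in grouping.effective_groups})
    ens = train_ensemble(cells, grouping, min_train_cells=50)
    assert len(ens.members_) >= 1
    assert ens.descriptor_names_ == cells.descriptor_names
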