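"""Per-target models: balancing, splitting, training, applicability domain."""

import numpy as np
import pytest

from targetfish.curation import ACTIVE, INACTIVE
from targetfish.featurization import DSC_LENGTH, FGP_BITS
from targetfish.modeling import (
    ALGORITHMS,
    ADRegion,
    TargetClassifier,
    TargetDataset,
    TrainedTCM,
    balance_by_clustering,
    balance_dataset,
    fit_ad,
    in_ad,
    load_models,
    make_split,
    predict_profile,
    save_models,
    train_tcm,
)


class TestBalanceByClustering:
    def test_equal_sizes_returns_everything(self):
        X = np.random.default_rng(0).normal(size=(8, 3))
        assert list(balance_by_clustering(X, 8, seed=0)) == list(range(8))

    def test_two_blobs_sampled_evenly(self):
        rng = np.random.default_rng(3)
        blob_a = rng.normal(0, 0.1, size=(10, 2))
        blob_b = rng.normal(100, 0.1, size=(10, 2))
        X = np.vstack([blob_a, blob_b])
        idx = balance_by_clustering(X, 10, seed=7)
        assert len(idx) == 10
        from_a = int(np.sum(idx < 10))
        assert 4 <= from_a <= 6  # 5 per blob, give or take one

    def test_single_selection(self):
        X = np.random.default_rng(1).normal(size=(5, 2))
        assert len(balance_by_clustering(X, 1, seed=0)) == 1

    def test_oversized_request_raises(self):
        with pytest.raises(ValueError):
            balance_by_clustering(np.zeros((3, 2)), 4, seed=0)

    def test_deterministic_given_seed(self):
        X = np.random.default_rng(5).normal(size=(30, 4))
        a = balance_by_clustering(X, 10, seed=12)
        b = balance_by_clustering(X, 10, seed=12)
        np.testing.assert_array_equal(a, b)

    def test_balance_dataset_exact_counts(self, blob_data):
        X, y = blob_data
        y = y.copy()
        y[:5] = INACTIVE  # 15 actives vs 25 inactives
        ds = TargetDataset("t", X, y, [str(i) for i in range(len(y))], "DSC")
        bal = balance_dataset(ds, seed=0)
        assert int(np.sum(bal.y == ACTIVE)) == int(np.sum(bal.y == INACTIVE)) == 15


class TestMakeSplit:
    def _ds(self, n=20):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(n, 3))
        y = np.array([ACTIVE, INACTIVE] * (n // 2))
        return TargetDataset("t", X, y, [f"c{i}" for i in range(n)], "DSC")

    def test_floor_rounding(self):
        train, test = make_split(self._ds(20), 0.30, seed=0)
        assert len(test.compound_ids) == 6
        assert len(train.compound_ids) == 14

    def test_same_seed_identical(self):
        a = make_split(self._ds(), 0.30, seed=4)
        b = make_split(self._ds(), 0.30, seed=4)
        assert a[1].compound_ids == b[1].compound_ids

    @pytest.mark.parametrize("fraction", [0.0, 1.0, -0.1])
    def test_degenerate_fraction_rejected(self, fraction):
        with pytest.raises(ValueError):
            make_split(self._ds(), fraction, seed=0)

    def test_stratified_both_classes_in_test(self):
        _, test = make_split(self._ds(20), 0.30, seed=0)
        assert set(test.y) == {ACTIVE, INACTIVE}


class TestTargetClassifier:
    def test_separable_blobs_rf_perfect_holdout(self, blob_data):
        X, y = blob_data
        ds = TargetDataset("t", X, y, [str(i) for i in range(len(y))], "DSC")
        train, test = make_split(ds, 0.30, seed=0)
        tcm = train_tcm(train, "RF", seed=0, test=test)
        assert tcm.holdout_metrics["f1"] == 1.0

    @pytest.mark.parametrize("algorithm", ALGORITHMS)
    def test_all_algorithms_separate_blobs(self, algorithm, blob_data):
        # separation >> 4 SD: every learner should reach f1 >= 0.8 on holdout
        X, y = blob_data
        ds = TargetDataset("t", X, y, [str(i) for i in range(len(y))], "DSC")
        train, test = make_split(ds, 0.30, seed=1)
        tcm = train_tcm(train, algorithm, seed=1, test=test)
        assert tcm.holdout_metrics["f1"] >= 0.8

    def test_probabilities_valid_and_sum_to_one(self, blob_data):
        X, y = blob_data
        clf = TargetClassifier(algorithm="SVM", kind="DSC", random_state=0).fit(X, y)
        proba = clf.predict_proba(X)
        assert np.all((proba >= 0) & (proba <= 1))
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-9)

    def test_single_class_raises(self):
        X = np.random.default_rng(0).normal(size=(10, 3))
        with pytest.raises(ValueError):
            TargetClassifier().fit(X, np.array([ACTIVE] * 10))

    def test_balancing_equalizes_training_classes(self, blob_data):
        X, y = blob_data
        y = y.copy()
        y[:8] = INACTIVE  # imbalance 12 vs 28
        clf = TargetClassifier(algorithm="DT", kind="DSC", random_state=0).fit(X, y)
        assert clf.n_train_ == 24  # 12 + 12

    def test_determinism(self, blob_data):
        X, y = blob_data
        runs = []
        for _ in range(2):
            ds = TargetDataset("t", X, y, [str(i) for i in range(len(y))], "DSC")
            train, test = make_split(ds, 0.3, seed=9)
            tcm = train_tcm(train, "RF", seed=9, test=test)
            runs.append(tcm.holdout_metrics)
        assert runs[0] == runs[1]


class TestApplicabilityDomain:
    def test_centroid_is_inside(self):
        X = np.random.default_rng(0).normal(size=(30, 4))
        region = fit_ad(X, "DSC", k=3.0)
        assert in_ad(region, X.mean(axis=0))

    def test_distant_point_outside(self):
        X = np.random.default_rng(0).normal(size=(30, 4))
        region = fit_ad(X, "DSC", k=3.0)
        far = X.mean(axis=0) + 1000.0
        assert not in_ad(region, far)

    def test_all_training_points_inside_dsc_k3(self, blob_data):
        X, _ = blob_data
        region = fit_ad(X, "DSC", k=3.0)
        assert np.all(region.contains(X))

    def test_fgp_majority_vote_centroid_tie_to_zero(self):
        X = np.array([[1, 1, 0, 0], [1, 0, 1, 0], [0, 1, 1, 1], [0, 0, 0, 1]], float)
        region = fit_ad(X, "FGP", k=3.0)
        # every column is a 2-2 tie -> centroid all zeros
        np.testing.assert_array_equal(region.centroid_, np.zeros(4))

    def test_fus_requires_both_subregions(self):
        rng = np.random.default_rng(2)
        fgp = (rng.random((40, FGP_BITS)) < 0.1).astype(float)
        dsc = rng.normal(size=(40, DSC_LENGTH))
        X = np.hstack([fgp, dsc])
        region = fit_ad(X, "FUS", k=3.0)
        probe = X[0].copy()
        probe[FGP_BITS:] += 1000.0  # wreck only the DSC block
        assert region.fgp_.contains(probe[:FGP_BITS])
        assert not region.dsc_.contains(probe[FGP_BITS:])
        assert not region.contains(probe)

    def test_dimension_mismatch_raises(self):
        region = fit_ad(np.zeros((5, 4)), "DSC")
        with pytest.raises(ValueError, match="dimension"):
            region.contains(np.zeros(7))


class TestPredictProfile:
    def _models(self, blob_data, n=2):
        X, y = blob_data
        out = []
        for i in range(n):
            ds = TargetDataset(f"t{i}", X, y, [str(j) for j in range(len(y))], "DSC")
            train, test = make_split(ds, 0.3, seed=i)
            out.append(train_tcm(train, "RF", seed=i, test=test))
        return out

    def test_zero_models_empty_profile(self):
        profile = predict_profile("c1", {"DSC": np.zeros(5)}, [])
        assert len(profile) == 0

    def test_profile_carries_probabilities_and_flags(self, blob_data):
        X, _ = blob_data
        models = self._models(blob_data)
        profile = predict_profile("c1", {"DSC": X[0]}, models)
        assert len(profile) == 2
        for e in profile.entries:
            assert 0.0 <= e.p_active <= 1.0
            assert isinstance(e.in_ad, bool)

    def test_out_of_domain_flagged_not_suppressed(self, blob_data):
        X, _ = blob_data
        models = self._models(blob_data)
        far = X[0] + 1e6
        profile = predict_profile("c1", {"DSC": far}, models)
        assert len(profile) == 2
        assert all(not e.in_ad for e in profile.entries)

    def test_missing_kind_raises(self, blob_data):
        models = self._models(blob_data)
        with pytest.raises(ValueError, match="descriptor kind"):
            predict_profile("c1", {"FGP": np.zeros(FGP_BITS)}, models)


def test_model_persistence_roundtrip(tmp_path, blob_data):
    X, y = blob_data
    ds = TargetDataset("t0", X, y, [str(i) for i in range(len(y))], "DSC")
    train, test = make_split(ds, 0.3, seed=0)
    tcm = train_tcm(train, "DT", seed=0, test=test)
    save_models([tcm], tmp_path / "models")
    loaded = load_models(tmp_path / "models")
    assert len(loaded) == 1
    np.testing.assert_array_equal(
        loaded[0].model.predict_proba_active(X), tcm.model.predict_proba_active(X)
    )
    assert (tmp_path / "models" / "manifest.json").exists()
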