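import hashlib

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from neohrv import (
    ModelConfig,
    grid_search,
    loso_cv,
    mrmr_rank,
    mutual_information,
    normalize_apply,
    normalize_fit,
    predict,
    train,
)
from neohrv._bruteforce import mutual_information_naive
from neohrv.model import _discretize


class TestNormalization:
    def test_train_column_standardized(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        tf = normalize_fit(df, ["a"])
        z = normalize_apply(tf, df)["a"]
        assert z.mean() == pytest.approx(0.0)
        assert z.std(ddof=0) == pytest.approx(1.0)

    def test_constant_column_maps_to_zero(self):
        df = pd.DataFrame({"a": [5.0, 5.0, 5.0]})
        tf = normalize_fit(df, ["a"])
        assert np.all(normalize_apply(tf, df)["a"] == 0.0)

    def test_test_rows_use_train_statistics(self):
        train_df = pd.DataFrame({"a": [0.0, 1.0, 2.0]})
        test_df = pd.DataFrame({"a": [10.0, 20.0]})
        tf = normalize_fit(train_df, ["a"])
        z = normalize_apply(tf, test_df)["a"]
        assert z.mean() != pytest.approx(0.0)          # no test-set leakage
        assert z.iloc[0] == pytest.approx((10.0 - 1.0) / np.std([0, 1, 2]))

    def test_missing_imputed_to_train_mean(self):
        train_df = pd.DataFrame({"a": [0.0, 2.0, np.nan, 4.0]})
        tf = normalize_fit(train_df, ["a"])
        z = normalize_apply(tf, train_df)["a"]
        assert z.iloc[2] == 0.0                         # train mean after z-score
        full = pd.DataFrame({"a": [0.0, 2.0, 4.0]})
        assert np.isfinite(normalize_apply(tf, full)).all().all()

    def test_all_missing_column_zeroed(self):
        df = pd.DataFrame({"a": [np.nan, np.nan]})
        tf = normalize_fit(df, ["a"])
        assert np.all(normalize_apply(tf, df)["a"] == 0.0)


class TestMRMR:
    def test_label_copy_ranked_first(self, rng):
        y = rng.integers(0, 2, size=200)
        X = pd.DataFrame({
            "noise": rng.normal(size=200),
            "copy": y.astype(float),
            "weak": y + rng.normal(0, 3.0, size=200),
        })
        assert mrmr_rank(X, y)[0] == "copy"

    def test_duplicate_penalized_after_top_feature(self, rng):
        y = rng.integers(0, 2, size=300)
        strong = y + rng.normal(0, 0.1, size=300)
        X = pd.DataFrame({
            "strong": strong,
            "dup": strong.copy(),                      # exact duplicate
            "weak": y + rng.normal(0, 2.0, size=300),  # independent, weakly informative
        })
        order = mrmr_rank(X, y)
        assert order[0] == "strong"
        assert order.index("weak") < order.index("dup")

    def test_mi_matches_bruteforce(self, rng):
        a = rng.integers(0, 6, size=80)
        b = rng.integers(0, 4, size=80)
        assert mutual_information(a, b) == pytest.approx(
            mutual_information_naive(a, b), abs=1e-12)
        codes = _discretize(rng.normal(size=80), 10)
        assert mutual_information(codes, a) == pytest.approx(
            mutual_information_naive(codes, a), abs=1e-12)

    def test_too_many_features_rejected(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=10)})
        with pytest.raises(ValueError):
            mrmr_rank(X, rng.integers(0, 2, size=10), k=2)


class TestClassifier:
    def _blobs(self, rng, n=100, margin=5.0):
        X = np.vstack([rng.normal(0, 1, size=(n, 2)),
                       rng.normal(margin, 1, size=(n, 2))])
        y = np.repeat([False, True], n)
        return X, y

    def test_separable_data_perfect_training_accuracy(self, rng):
        X, y = self._blobs(rng)
        for cfg in (ModelConfig(kernel="linear", lam=1e-4),
                    ModelConfig(kernel="gaussian", kernel_scale=2.0)):
            clf = train(cfg, X, y)
            _, labels = predict(clf, X)
            assert np.array_equal(labels, y)

    def test_seizure_cost_raises_recall(self, rng):
        # 9:1 imbalance with overlapping classes
        X = np.vstack([rng.normal(0, 1, size=(450, 2)),
                       rng.normal(1.0, 1, size=(50, 2))])
        y = np.repeat([False, True], [450, 50])
        recalls = []
        for c2 in (1.0, 20.0):
            clf = train(ModelConfig(kernel="gaussian", kernel_scale=2.0, c2=c2), X, y)
            _, labels = predict(clf, X)
            recalls.append(np.mean(labels[y]))
        assert recalls[1] > recalls[0]

    def test_cost_monotonicity_over_grid(self, rng):
        X = np.vstack([rng.normal(0, 1, size=(270, 2)),
                       rng.normal(0.8, 1, size=(30, 2))])
        y = np.repeat([False, True], [270, 30])
        c2_grid = [1.0, 2.0, 5.0, 10.0, 40.0, 100.0]
        recalls = []
        for c2 in c2_grid:
            clf = train(ModelConfig(kernel="gaussian", kernel_scale=2.0, c2=c2), X, y)
            _, labels = predict(clf, X)
            recalls.append(np.mean(labels[y]))
        rho = stats.spearmanr(c2_grid, recalls).statistic
        assert rho > 0.8

    def test_wide_gaussian_kernel_approaches_linear(self, rng):
        X, y = self._blobs(rng, margin=3.0)
        lin = train(ModelConfig(kernel="linear", lam=1e-3), X, y)
        wide = train(ModelConfig(kernel="gaussian", kernel_scale=1e3,
                                 box_constraint=1e4), X, y)
        _, l1 = predict(lin, X)
        _, l2 = predict(wide, X)
        assert np.mean(l1 == l2) >= 0.95

    def test_single_class_fold_rejected(self, rng):
        X = rng.normal(size=(20, 2))
        with pytest.raises(ValueError, match="single class"):
            train(ModelConfig(), X, np.zeros(20, dtype=bool))


def _train_matrix_hash(df, held_out):
    rows = df[df["patient_id"] != held_out]
    return hashlib.sha256(pd.util.hash_pandas_object(rows).to_numpy().tobytes()).hexdigest()


class TestLOSO:
    def test_one_fold_per_patient(self, blob_table):
        folds = loso_cv(blob_table, ModelConfig(n_features=2))
        assert [f.patient_id for f in folds] == [f"P{i}" for i in range(8)]
        for f in folds:
            n = (blob_table["patient_id"] == f.patient_id).sum()
            assert f.scores.size == n

    def test_no_leakage_of_held_out_rows(self, blob_table):
        # deleting the held-out patient before preprocessing is equivalent
        # to the fold's own training matrix
        h1 = _train_matrix_hash(blob_table, "P3")
        h2 = _train_matrix_hash(blob_table.copy(), "P3")
        assert h1 == h2
        folds = loso_cv(blob_table, ModelConfig(n_features=2))
        assert all(f.truth.size == 30 for f in folds)

    def test_patient_order_irrelevant(self, blob_table):
        shuffled = blob_table.sample(frac=1.0, random_state=5)
        a = {f.patient_id: f.scores.sum() for f in loso_cv(blob_table, ModelConfig(n_features=2))}
        b = {f.patient_id: f.scores.sum() for f in loso_cv(shuffled.sort_index(), ModelConfig(n_features=2))}
        for pid in a:
            assert a[pid] == pytest.approx(b[pid])

    def test_determinism(self, blob_table):
        a = loso_cv(blob_table, ModelConfig(n_features=2))
        b = loso_cv(blob_table, ModelConfig(n_features=2))
        for fa, fb in zip(a, b):
            assert fa.selected_features == fb.selected_features
            assert np.array_equal(fa.scores, fb.scores)


class TestGridSearch:
    def test_single_point_grid(self, blob_table):
        cfg = ModelConfig(kernel="gaussian", kernel_scale=2.0)
        best, folds, results = grid_search(blob_table, [cfg], ("full",))
        assert best.kernel_scale == 2.0
        assert len(results) == 1

    def test_results_table_shape(self, blob_table):
        grid = [ModelConfig(kernel_scale=s) for s in (1.0, 2.0)]
        best, _, results = grid_search(blob_table, grid, (2, "full"))
        assert len(results) == 4
        assert {"kernel", "n_features", "mean_pathological_auc"} <= set(results.columns)

    def test_strong_signal_recovered(self, blob_table):
        grid = [ModelConfig(kernel_scale=2.0, c2=c2) for c2 in (1.0, 5.0)]
        best, folds, _ = grid_search(blob_table, grid, (2,))
        from neohrv import mean_pathological_auc
        assert mean_pathological_auc(folds) >= 0.9

    def test_empty_grid_rejected(self, blob_table):
        with pytest.raises(ValueError):
            grid_search(blob_table, [], ("full",))
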