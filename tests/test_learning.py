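"""Metrics, feature assembly, greedy selection, training and CV evaluation."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import ExtraTreesRegressor

from ddgscan.dataset import AffinityRecord, Dataset, lopo_folds
from ddgscan.learning import (
    ModelConfig,
    TrainedModel,
    assemble_features,
    auc,
    bacc,
    confusion,
    evaluate_cv,
    f1,
    greedy_select,
    kendall_tau,
    make_model,
    mcc,
    pearson,
    predict,
    regression_metrics,
    rmse,
    spearman,
    train,
)

# --------------------------------------------------------------------------
# naive reference implementations, kept deliberately elementary
# --------------------------------------------------------------------------


def naive_pearson(a, b):
    am, bm = sum(a) / len(a), sum(b) / len(b)
    num = sum((x - am) * (y - bm) for x, y in zip(a, b))
    den = math.sqrt(sum((x - am) ** 2 for x in a)) * math.sqrt(
        sum((y - bm) ** 2 for y in b)
    )
    return num / den


def naive_rank(v):
    out = [0.0] * len(v)
    order = sorted(range(len(v)), key=lambda i: v[i])
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            out[order[k]] = avg
        i = j + 1
    return out


def naive_spearman(a, b):
    return naive_pearson(naive_rank(a), naive_rank(b))


def naive_kendall_tau_b(a, b):
    conc = disc = ties_a = ties_b = 0
    n = len(a)
    for i in range(n):
        for j in range(i + 1, n):
            da, db = a[i] - a[j], b[i] - b[j]
            if da == 0 and db == 0:
                continue
            if da == 0:
                ties_a += 1
            elif db == 0:
                ties_b += 1
            elif da * db > 0:
                conc += 1
            else:
                disc += 1
    n0 = n * (n - 1) / 2
    denom = math.sqrt((n0 - _tie_term(a)) * (n0 - _tie_term(b)))
    return (conc - disc) / denom


def _tie_term(v):
    from collections import Counter

    return sum(c * (c - 1) / 2 for c in Counter(v).values())


def naive_rmse(a, b):
    return math.sqrt(sum((x - y) ** 2 for x, y in zip(a, b)) / len(a))


def naive_mcc(tn, fp, fn, tp):
    den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    return (tp * tn - fp * fn) / den if den else 0.0


def naive_f1(tn, fp, fn, tp):
    return 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0


def naive_bacc(tn, fp, fn, tp):
    sens = tp / (tp + fn) if (tp + fn) else 0.0
    spec = tn / (tn + fp) if (tn + fp) else 0.0
    return (sens + spec) / 2


def naive_auc(scores, labels):
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum(
        1.0 if p > q else (0.5 if p == q else 0.0)
        for p in pos for q in neg
    )
    return wins / (len(pos) * len(neg))


class TestMetricsAgainstNaive:
    @pytest.mark.parametrize("seed", range(10))
    def test_regression_metrics_match_to_1e12(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 50))
        a = rng.normal(size=n).tolist()
        b = (np.asarray(a) * 0.5 + rng.normal(size=n)).tolist()
        assert pearson(a, b) == pytest.approx(naive_pearson(a, b), abs=1e-12)
        assert spearman(a, b) == pytest.approx(naive_spearman(a, b), abs=1e-12)
        assert kendall_tau(a, b) == pytest.approx(
            naive_kendall_tau_b(a, b), abs=1e-12
        )
        assert rmse(a, b) == pytest.approx(naive_rmse(a, b), abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_classification_metrics_match_to_1e12(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(10, 50))
        y = rng.integers(0, 2, size=n)
        p = rng.integers(0, 2, size=n)
        if len(set(y.tolist())) < 2:
            y[0] = 1 - y[0]
        cm = confusion(y, p)
        tn, fp, fn, tp = cm.ravel()
        assert mcc(cm) == pytest.approx(naive_mcc(tn, fp, fn, tp), abs=1e-12)
        assert f1(cm) == pytest.approx(naive_f1(tn, fp, fn, tp), abs=1e-12)
        assert bacc(cm) == pytest.approx(naive_bacc(tn, fp, fn, tp), abs=1e-12)
        scores = rng.random(size=n)
        assert auc(scores, y) == pytest.approx(
            naive_auc(scores.tolist(), y.tolist()), abs=1e-12
        )

    def test_hand_computed_confusion_matrix(self):
        # TP=3, FP=1, FN=1, TN=5 -> (3*5-1*1)/sqrt(4*4*6*6) = 14/24
        cm = np.array([[5, 1], [1, 3]])
        assert mcc(cm) == pytest.approx(14 / 24)

    def test_degenerate_margin_gives_zero(self):
        assert mcc(np.array([[10, 0], [3, 0]])) == 0.0

    def test_identity_limits(self):
        x = [1.0, 2.0, 5.0, 3.0]
        assert pearson(x, x) == pytest.approx(1.0)
        assert rmse(x, x) == 0.0

    def test_perfect_ranking_auc(self):
        assert auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pearson([1, 2], [1, 2, 3])


# --------------------------------------------------------------------------
# feature assembly
# --------------------------------------------------------------------------


class TestAssembleFeatures:
    def _records(self, small_world, n=2):
        spec = small_world["spec"]
        pocket = spec.n_residues // 2
        s = small_world["complexes"]["DRUG1"].structure
        wt = {r.seqnum: r for r in s.residues}[pocket].one_letter
        mts = [m for m in "ACDEFGHIKLMNPQRSTVWY" if m != wt]
        return [
            AffinityRecord("DRUG1", "A", pocket, wt, mts[i], 0.0)
            for i in range(n)
        ]

    def test_one_row_per_record_with_named_columns(self, small_world):
        recs = self._records(small_world)
        X = assemble_features(recs, small_world["complexes"],
                              small_world["ligands"])
        assert X.shape[0] == 2
        for prefix in ("lig:", "env:", "dpharm:", "wtct:", "dct:", "sig:"):
            assert any(c.startswith(prefix) for c in X.columns)
        assert X.columns.is_unique
        assert not X.isna().any().any()

    def test_assembly_is_deterministic(self, small_world):
        recs = self._records(small_world)
        X1 = assemble_features(recs, small_world["complexes"],
                               small_world["ligands"])
        X2 = assemble_features(recs, small_world["complexes"],
                               small_world["ligands"])
        pd.testing.assert_frame_equal(X1, X2)

    def test_permuting_records_permutes_rows(self, small_world):
        recs = self._records(small_world, n=3)
        X = assemble_features(recs, small_world["complexes"],
                              small_world["ligands"])
        Xr = assemble_features(recs[::-1], small_world["complexes"],
                               small_world["ligands"])
        pd.testing.assert_frame_equal(
            X.iloc[::-1].reset_index(drop=True), Xr
        )

    def test_unknown_drug_reported(self, small_world):
        rec = AffinityRecord("NOSUCH", "A", 6, "T", "I", 0.0)
        with pytest.raises(KeyError, match="NOSUCH"):
            assemble_features([rec], small_world["complexes"],
                              small_world["ligands"])


# --------------------------------------------------------------------------
# greedy selection
# --------------------------------------------------------------------------


def planted_matrix(seed, n=80, noise_cols=20):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        rng.normal(size=(n, noise_cols)),
        columns=[f"noise_{i:02d}" for i in range(noise_cols)],
    )
    X["signal"] = rng.normal(size=n)
    y = X["signal"].to_numpy() + rng.normal(scale=0.05, size=n)
    return X, y


def kfold(n, k, seed):
    rng = np.random.default_rng(seed)
    idx = rng.permutation(n)
    folds = np.array_split(idx, k)
    return [
        (i, np.concatenate([f for j, f in enumerate(folds) if j != i]).tolist(),
         folds[i].tolist())
        for i in range(k)
    ]


class TestGreedySelect:
    def test_planted_signal_selected_first(self):
        X, y = planted_matrix(seed=0)
        sel = greedy_select(
            X, y, kfold(len(y), 5, 0), "pearson",
            lambda: ExtraTreesRegressor(n_estimators=20, random_state=0),
            max_features=2,
        )
        assert sel[0] == "signal"

    def test_max_features_caps_output(self):
        X, y = planted_matrix(seed=1)
        sel = greedy_select(
            X, y, kfold(len(y), 5, 0), "pearson",
            lambda: ExtraTreesRegressor(n_estimators=10, random_state=0),
            max_features=1,
        )
        assert len(sel) == 1

    def test_selection_is_deterministic(self):
        X, y = planted_matrix(seed=2)
        args = (X, y, kfold(len(y), 5, 1), "pearson")
        factory = lambda: ExtraTreesRegressor(n_estimators=10, random_state=0)
        assert greedy_select(*args, factory, max_features=3) == greedy_select(
            *args, factory, max_features=3
        )

    def test_metric_trajectory_never_decreases(self):
        X, y = planted_matrix(seed=3)
        greedy_select(
            X, y, kfold(len(y), 5, 0), "pearson",
            lambda: ExtraTreesRegressor(n_estimators=10, random_state=0),
            max_features=4,
        )
        traj = greedy_select.last_trajectory
        assert all(b >= a for a, b in zip(traj, traj[1:]))

    def test_constant_target_rejected(self):
        X, _ = planted_matrix(seed=4)
        with pytest.raises(ValueError):
            greedy_select(
                X, np.ones(len(X)), kfold(len(X), 5, 0), "pearson",
                lambda: ExtraTreesRegressor(n_estimators=5, random_state=0),
            )


# --------------------------------------------------------------------------
# training, persistence, CV evaluation
# --------------------------------------------------------------------------


class TestTrainPredict:
    def test_tree_ensemble_interpolates_deterministic_target(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"x": rng.permutation(50).astype(float),
                          "junk": rng.normal(size=50)})
        y = 3.0 * X["x"].to_numpy()
        model = train(X, y, ModelConfig("regression", "extra_trees", seed=0))
        assert predict(model, X) == pytest.approx(y)

    def test_save_reload_reproduces_predictions(self, tmp_path):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
        y = X["a"].to_numpy() * 2
        model = train(X, y, ModelConfig("regression", "extra_trees", seed=0))
        model.save(tmp_path / "m")
        back = TrainedModel.load(tmp_path / "m")
        assert predict(back, X) == pytest.approx(predict(model, X))
        assert back.feature_names == model.feature_names

    def test_classifier_separates_linear_toy_set(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame({"x": rng.normal(size=60)})
        y = (X["x"] > 0).astype(int).to_numpy()
        model = train(X, y, ModelConfig("classification", "random_forest", 0))
        labels, scores = predict(model, X)
        assert mcc(confusion(y, labels.astype(int))) == 1.0
        assert ((scores > 0.5) == y.astype(bool)).all()

    def test_predict_names_missing_columns(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [0.0, 1.0, 0.5]})
        model = train(X, X["a"], ModelConfig("regression", "extra_trees", 0))
        with pytest.raises(ValueError, match="b"):
            predict(model, X[["a"]])

    @pytest.mark.parametrize("algorithm", ["extra_trees", "random_forest",
                                           "mlp", "svm"])
    def test_all_algorithm_backends_fit_and_predict(self, algorithm):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("abc"))
        y = X["a"].to_numpy()
        cfg = ModelConfig("regression", algorithm, seed=0)
        model = train(X, y, cfg)
        assert len(predict(model, X)) == 40
        yc = (y > 0).astype(int)
        cfgc = ModelConfig("classification", algorithm, seed=0)
        labels, scores = predict(train(X, yc, cfgc), X)
        assert len(labels) == len(scores) == 40


class TestEvaluateCv:
    def test_perfect_signal_recovers_pooled_correlation(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame({"x": rng.normal(size=100)})
        y = 2.0 * X["x"].to_numpy() + rng.normal(scale=0.01, size=100)
        rep = evaluate_cv(X, y, kfold(100, 5, 0),
                          ModelConfig("regression", "extra_trees", 0))
        assert rep.pooled["pearson"] >= 0.99

    def test_shuffled_labels_destroy_correlation(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame({"x": rng.normal(size=100)})
        y = rng.permutation(2.0 * X["x"].to_numpy())
        rep = evaluate_cv(X, y, kfold(100, 5, 0),
                          ModelConfig("regression", "extra_trees", 0))
        assert abs(rep.pooled["pearson"]) < 0.3

    def test_fold_sizes_partition_dataset(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame({"x": rng.normal(size=50)})
        y = X["x"].to_numpy()
        rep = evaluate_cv(X, y, kfold(50, 5, 0),
                          ModelConfig("regression", "extra_trees", 0))
        assert sum(rep.per_fold_sizes) == 50

    def test_trimmed_metrics_reported_for_regression(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame({"x": rng.normal(size=60)})
        y = X["x"].to_numpy() + rng.normal(scale=0.1, size=60)
        rep = evaluate_cv(X, y, kfold(60, 4, 0),
                          ModelConfig("regression", "extra_trees", 0))
        assert rep.trimmed is not None
        assert rep.trimmed["rmse"] <= rep.pooled["rmse"]

    def test_empty_fold_rejected(self):
        X = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            evaluate_cv(X, X["x"], [(0, [0, 1, 2], [])],
                        ModelConfig("regression", "extra_trees", 0))
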