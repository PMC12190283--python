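import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import matthews_corrcoef

from eegmfe.classify import (
    GridSpec,
    LeakageError,
    SplitPlan,
    default_grids,
    fit_evaluate,
    loso_select,
    make_split,
    mcc_from_counts,
    subject_accuracy,
)


def feature_table(centers, n_subjects=4, n_epochs=6, noise=0.3, seed=0,
                  n_features=2, prefix=""):
    """Two-group table with per-group Gaussian clusters."""
    rng = np.random.default_rng(seed)
    rows = []
    for group, center in centers.items():
        for s in range(n_subjects):
            sid = f"{prefix}{group}{s}"
            for e in range(n_epochs):
                feats = center + noise * rng.standard_normal(n_features)
                row = {"subject_id": sid, "epoch": e, "group": group,
                       "dataset_id": "A", "valid": True}
                row.update({f"f{i}": feats[i] for i in range(n_features)})
                rows.append(row)
    return pd.DataFrame(rows)


SEPARABLE = {"HS": np.array([0.0, 0.0]), "AD": np.array([8.0, 8.0])}


class TestConfusionArithmetic:
    def test_subject_accuracy(self):
        assert subject_accuracy(12, 0, 0, 4) == pytest.approx(0.75)

    def test_perfect_prediction_mcc_one(self):
        assert mcc_from_counts(10, 20, 0, 0) == pytest.approx(1.0)

    def test_balanced_confusion_mcc_zero(self):
        assert mcc_from_counts(7, 7, 7, 7) == pytest.approx(0.0)

    def test_all_wrong_mcc_minus_one(self):
        assert mcc_from_counts(0, 0, 5, 5) == pytest.approx(-1.0)

    def test_label_swap_flips_sign(self):
        tp, tn, fp, fn = 9, 4, 2, 5
        assert mcc_from_counts(tp, tn, fp, fn) == pytest.approx(
            -mcc_from_counts(fp, fn, tp, tn)
        )

    def test_matches_sklearn(self):
        rng = np.random.default_rng(0)
        y_true = rng.integers(0, 2, 200)
        y_pred = rng.integers(0, 2, 200)
        tp = int(((y_pred == 1) & (y_true == 1)).sum())
        tn = int(((y_pred == 0) & (y_true == 0)).sum())
        fp = int(((y_pred == 1) & (y_true == 0)).sum())
        fn = int(((y_pred == 0) & (y_true == 1)).sum())
        assert mcc_from_counts(tp, tn, fp, fn) == pytest.approx(
            matthews_corrcoef(y_true, y_pred), abs=1e-12
        )


class TestSplit:
    def _subjects(self, n_per_cell=6):
        rows = []
        for g in ("HS", "AD"):
            for d in ("A", "B"):
                for i in range(n_per_cell):
                    rows.append({"subject_id": f"{g}{d}{i}", "group": g,
                                 "dataset_id": d})
        return pd.DataFrame(rows)

    def test_disjoint_and_balanced(self):
        plan = make_split(self._subjects(), test_fraction=1 / 3, seed=0)
        assert not set(plan.train_subjects) & set(plan.test_subjects)
        test = [s for s in plan.test_subjects]
        assert sum(s.startswith("HS") for s in test) == sum(
            s.startswith("AD") for s in test
        )
        assert plan.counts[("HS", "A")] == 2

    def test_seed_determinism(self):
        subs = self._subjects()
        a = make_split(subs, seed=4)
        b = make_split(subs, seed=4)
        assert a.test_subjects == b.test_subjects

    def test_overlap_rejected(self):
        with pytest.raises(LeakageError):
            SplitPlan(["s1", "s2"], ["s2", "s3"])


class TestLosoSelect:
    def test_singleton_grid_returned_without_search(self):
        grid = GridSpec("knn", (("n_neighbors", (3,)),))
        table = feature_table(SEPARABLE)
        assert loso_select(table, grid) == {"n_neighbors": 3}

    def test_tie_break_first_declared(self):
        # perfectly separable clusters: every grid point scores 1.0
        grid = GridSpec("knn", (("n_neighbors", (7, 3)), ("weights", ("distance", "uniform"))))
        table = feature_table(SEPARABLE, n_subjects=5)
        assert loso_select(table, grid) == {"n_neighbors": 7, "weights": "distance"}

    def test_matches_naive_reevaluation(self):
        """Selected point must agree with an independent exhaustive loop
        built on sklearn's LeaveOneGroupOut + Pipeline machinery."""
        from sklearn.model_selection import LeaveOneGroupOut, cross_val_score
        from sklearn.neighbors import KNeighborsClassifier
        from sklearn.pipeline import make_pipeline
        from sklearn.preprocessing import StandardScaler

        table = feature_table(
            {"HS": np.array([0.0, 0.0]), "AD": np.array([0.9, 0.6])},
            n_subjects=6, n_epochs=5, noise=1.0, seed=3,
        )
        grid = GridSpec("knn", (("n_neighbors", (3, 5, 9)), ("weights", ("uniform",))))
        chosen = loso_select(table, grid, seed=0)

        X = table[["f0", "f1"]].to_numpy()
        y = (table["group"] == "AD").to_numpy(int)
        groups = table["subject_id"].to_numpy()
        scores = {}
        for k in (3, 5, 9):
            pipe = make_pipeline(StandardScaler(), KNeighborsClassifier(n_neighbors=k))
            folds = cross_val_score(
                pipe, X, y, groups=groups, cv=LeaveOneGroupOut(), scoring="accuracy"
            )
            scores[k] = folds.mean()  # equal fold sizes: == pooled accuracy
        best_k = max(scores, key=lambda k: scores[k])
        assert chosen["n_neighbors"] == best_k

    def test_requires_two_subjects(self):
        table = feature_table(SEPARABLE, n_subjects=1)
        table = table[table["group"] == "HS"]
        with pytest.raises(ValueError):
            loso_select(table, GridSpec("knn", (("n_neighbors", (3,)),)))


class TestFitEvaluate:
    def test_separable_is_perfect(self):
        train = feature_table(SEPARABLE, n_subjects=5, seed=1)
        test = feature_table(SEPARABLE, n_subjects=3, seed=2, prefix="t_")
        rep = fit_evaluate(train, test, "knn", {"n_neighbors": 3}, condition="x")
        assert rep.mean_accuracy == 1.0
        assert rep.mcc == 1.0
        assert rep.fp == rep.fn == 0
        assert rep.tp + rep.tn + rep.fp + rep.fn == len(test)

    def test_per_subject_accuracies(self):
        train = feature_table(SEPARABLE, n_subjects=5, seed=1)
        test = feature_table(SEPARABLE, n_subjects=2, seed=2, prefix="t_")
        rep = fit_evaluate(train, test, "rf", {"n_estimators": 20}, seed=0)
        assert set(rep.per_subject_accuracy) == set(test["subject_id"])
        assert all(0 <= a <= 1 for a in rep.per_subject_accuracy.values())

    def test_leakage_rejected(self):
        table = feature_table(SEPARABLE)
        with pytest.raises(LeakageError):
            fit_evaluate(table, table, "knn", {"n_neighbors": 3})

    def test_uncertainty_is_twice_standard_error(self):
        train = feature_table(SEPARABLE, n_subjects=5, seed=1)
        test = feature_table(
            {"HS": np.array([0.0, 0.0]), "AD": np.array([1.0, 1.0])},
            n_subjects=4, noise=1.5, seed=5, prefix="t_",
        )
        rep = fit_evaluate(train, test, "knn", {"n_neighbors": 3})
        accs = np.array(list(rep.per_subject_accuracy.values()))
        expected = 2.0 * accs.std(ddof=1) / np.sqrt(len(accs))
        assert rep.expanded_uncertainty == pytest.approx(expected)


def test_default_grids_match_declared_search_space():
    grids = default_grids()
    svm = dict(grids["svm"].grid)
    assert svm["C"] == (0.1, 1, 10, 50, 70, 90, 100)
    assert svm["gamma"] == (0.01, 0.05, 0.1, 0.5, 0.7, 0.9, 1)
    rf = dict(grids["rf"].grid)
    assert rf["max_depth"] == (10, 20, None)
    knn = dict(grids["knn"].grid)
    assert knn["metric"] == ("euclidean", "manhattan", "minkowski")
    assert len(list(grids["svm"].combinations())) == 49
    assert len(list(grids["rf"].combinations())) == 81
    assert len(list(grids["knn"].combinations())) == 30
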