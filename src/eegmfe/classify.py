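"""Subject-level split, LOSO grid search, and test-set evaluation.

Epochs of one subject are treated as independent observations but are
never split across train/validation/test boundaries. Model selection is
leave-one-subject-out (LOSO) cross-validation over an explicit,
order-preserving hyperparameter grid: for every grid point each
training subject is held out in turn, features are z-scored on the
remaining subjects only (no leakage), and the point with the highest
validation accuracy over all held-out observations wins, ties going to
the earliest point in declaration order.

Evaluation retrains on the full training set and reports per-subject
accuracy, the mean with its expanded uncertainty (k * SE, coverage
factor k = 2 for a ~95% interval), and the Matthews correlation
coefficient pooled over every test observation:

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

__all__ = [
    "POSITIVE_GROUP",
    "GridSpec",
    "SplitPlan",
    "EvalReport",
    "default_grids",
    "reduced_grids",
    "make_split",
    "loso_select",
    "fit_evaluate",
    "mcc_from_counts",
    "subject_accuracy",
]

#: the disease group is the positive class throughout
POSITIVE_GROUP = "AD"

META_COLS = ("subject_id", "epoch", "group", "dataset_id", "valid")


class LeakageError(ValueError):
    """Train and test subject sets overlap."""


@dataclass(frozen=True)
class GridSpec:
    """One classifier family plus its ordered hyperparameter grid."""

    family: str  # {"svm", "rf", "knn"}
    grid: tuple  # ((name, (values...)), ...) in declaration order

    def combinations(self):
        """Grid points as dicts, in declaration order (first key slowest)."""
        names = [name for name, _ in self.grid]
        for values in itertools.product(*(vals for _, vals in self.grid)):
            yield dict(zip(names, values))


def default_grids() -> dict[str, GridSpec]:
    """The full search grids for the three classifier families."""
    return {
        "svm": GridSpec(
            "svm",
            (
                ("C", (0.1, 1, 10, 50, 70, 90, 100)),
                ("gamma", (0.01, 0.05, 0.1, 0.5, 0.7, 0.9, 1)),
                ("kernel", ("rbf",)),
            ),
        ),
        "rf": GridSpec(
            "rf",
            (
                ("n_estimators", (50, 100, 200)),
                ("max_depth", (10, 20, None)),
                ("min_samples_split", (2, 5, 10)),
                ("min_samples_leaf", (1, 2, 4)),
            ),
        ),
        "knn": GridSpec(
            "knn",
            (
                ("n_neighbors", (3, 5, 7, 9, 11)),
                ("weights", ("uniform", "distance")),
                ("metric", ("euclidean", "manhattan", "minkowski")),
            ),
        ),
    }


def reduced_grids() -> dict[str, GridSpec]:
    """Small grids for desk-scale runs (subset of the full grids)."""
    return {
        "svm": GridSpec("svm", (("C", (1, 10)), ("gamma", (0.05, 0.1)),
                                ("kernel", ("rbf",)))),
        "rf": GridSpec("rf", (("n_estimators", (100,)), ("max_depth", (10, None)),
                              ("min_samples_split", (2,)), ("min_samples_leaf", (1,)))),
        "knn": GridSpec("knn", (("n_neighbors", (5, 11)), ("weights", ("uniform",)),
                                ("metric", ("euclidean",)))),
    }


def make_classifier(family: str, params: dict, seed: int):
    if family == "svm":
        return SVC(random_state=seed, **params)
    if family == "rf":
        return RandomForestClassifier(random_state=seed, **params)
    if family == "knn":
        return KNeighborsClassifier(**params)
    raise ValueError(f"unknown classifier family {family!r}")


# ------------------------------------------------------------------ split

@dataclass
class SplitPlan:
    """Disjoint train/test subject sets, stratified by (group, dataset)."""

    train_subjects: list[str]
    test_subjects: list[str]
    counts: dict = field(default_factory=dict)  # (group, dataset) -> test n
    seed: int = 0

    def __post_init__(self) -> None:
        overlap = set(self.train_subjects) & set(self.test_subjects)
        if overlap:
            raise LeakageError(f"subjects in both sets: {sorted(overlap)}")


def make_split(
    subjects: pd.DataFrame, test_fraction: float = 30 / 104, seed: int = 0
) -> SplitPlan:
    """Random subject-level split with equal HS/AD counts in each set.

    ``subjects`` needs columns ``subject_id``, ``group``, ``dataset_id``
    (one row per subject). Within every (group, dataset) cell,
    ``round(test_fraction * n_cell)`` subjects go to the test set; the
    per-group test counts are then equalized by construction when the
    groups have matching cell sizes.
    """
    rng = np.random.default_rng(seed)
    subjects = subjects.drop_duplicates("subject_id")
    train, test, counts = [], [], {}
    for (group, ds), cell in subjects.groupby(["group", "dataset_id"]):
        ids = sorted(cell["subject_id"])
        n_test = int(round(test_fraction * len(ids)))
        picked = set(rng.choice(ids, size=n_test, replace=False))
        counts[(group, ds)] = n_test
        test += sorted(picked)
        train += [s for s in ids if s not in picked]
    return SplitPlan(train, test, counts=counts, seed=seed)


# ------------------------------------------------------------- selection

def _xy(table: pd.DataFrame):
    feats = [c for c in table.columns if c not in META_COLS]
    X = table[feats].to_numpy(dtype=float)
    y = (table["group"] == POSITIVE_GROUP).to_numpy(dtype=int)
    return X, y


def _drop_invalid(table: pd.DataFrame) -> pd.DataFrame:
    if "valid" in table.columns and not table["valid"].all():
        n_bad = int((~table["valid"]).sum())
        logger.info("dropping %d flagged observations", n_bad)
        table = table[table["valid"]]
    return table


def loso_select(train: pd.DataFrame, grid: GridSpec, seed: int = 0) -> dict:
    """LOSO grid search; returns the winning hyperparameter dict.

    Selection score is observation-level validation accuracy pooled over
    all held-out subjects; ties break to the first grid point declared.
    """
    train = _drop_invalid(train)
    subjects = sorted(train["subject_id"].unique())
    if len(subjects) < 2:
        raise ValueError("LOSO selection needs at least two training subjects")
    X, y = _xy(train)
    sid = train["subject_id"].to_numpy()
    folds = []
    for s in subjects:
        mask = sid == s
        if not mask.any():
            logger.info("subject %s has no valid observations; excluded", s)
            continue
        folds.append((~mask, mask))
    best_params, best_score = None, -np.inf
    for params in grid.combinations():
        correct = total = 0
        for tr_mask, va_mask in folds:
            scaler = StandardScaler().fit(X[tr_mask])
            clf = make_classifier(grid.family, params, seed)
            clf.fit(scaler.transform(X[tr_mask]), y[tr_mask])
            pred = clf.predict(scaler.transform(X[va_mask]))
            correct += int((pred == y[va_mask]).sum())
            total += int(va_mask.sum())
        score = correct / total
        if score > best_score:  # strict: first point wins ties
            best_score, best_params = score, params
    logger.info(
        "%s LOSO selection: %s (validation accuracy %.3f)",
        grid.family, best_params, best_score,
    )
    return best_params


# ------------------------------------------------------------ evaluation

def mcc_from_counts(tp: int, tn: int, fp: int, fn: int) -> float:
    """Matthews correlation coefficient from confusion counts.

    Returns 0 when any marginal is empty (the conventional limit).
    """
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / np.sqrt(denom)


def subject_accuracy(tp: int, tn: int, fp: int, fn: int) -> float:
    """Per-subject classification accuracy (correct / observations)."""
    return (tp + tn) / (tp + tn + fp + fn)


@dataclass
class EvalReport:
    """Test-set performance of one (condition, classifier) cell."""

    condition: str
    classifier: str
    chosen_params: dict
    per_subject_accuracy: dict  # subject_id -> accuracy in [0, 1]
    mean_accuracy: float
    expanded_uncertainty: float
    coverage_factor: float
    mcc: float
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        accs = np.array(list(self.per_subject_accuracy.values()))
        if accs.size and (accs.min() < 0 or accs.max() > 1):
            raise ValueError("per-subject accuracies must lie in [0, 1]")
        if not -1 <= self.mcc <= 1:
            raise ValueError("MCC out of [-1, 1]")

    def to_dict(self) -> dict:
        return {
            "condition": self.condition,
            "classifier": self.classifier,
            "chosen_params": self.chosen_params,
            "per_subject_accuracy": self.per_subject_accuracy,
            "mean_accuracy": self.mean_accuracy,
            "expanded_uncertainty": self.expanded_uncertainty,
            "coverage_factor": self.coverage_factor,
            "mcc": self.mcc,
            "confusion": {"tp": self.tp, "tn": self.tn, "fp": self.fp, "fn": self.fn},
        }


def fit_evaluate(
    train: pd.DataFrame,
    test: pd.DataFrame,
    family: str,
    chosen: dict,
    seed: int = 0,
    condition: str = "",
    coverage_factor: float = 2.0,
) -> EvalReport:
    """Retrain on the full training set and score the held-out subjects."""
    overlap = set(train["subject_id"]) & set(test["subject_id"])
    if overlap:
        raise LeakageError(f"subjects in both sets: {sorted(overlap)}")
    train = _drop_invalid(train)
    test = _drop_invalid(test)
    X_tr, y_tr = _xy(train)
    X_te, y_te = _xy(test)
    scaler = StandardScaler().fit(X_tr)
    clf = make_classifier(family, chosen, seed)
    clf.fit(scaler.transform(X_tr), y_tr)
    pred = clf.predict(scaler.transform(X_te))

    tp = int(((pred == 1) & (y_te == 1)).sum())
    tn = int(((pred == 0) & (y_te == 0)).sum())
    fp = int(((pred == 1) & (y_te == 0)).sum())
    fn = int(((pred == 0) & (y_te == 1)).sum())

    per_subject = {}
    sid = test["subject_id"].to_numpy()
    for s in sorted(test["subject_id"].unique()):
        mask = sid == s
        per_subject[s] = float((pred[mask] == y_te[mask]).mean())
    accs = np.array(list(per_subject.values()))
    se = accs.std(ddof=1) / np.sqrt(len(accs)) if len(accs) > 1 else 0.0
    return EvalReport(
        condition=condition,
        classifier=family,
        chosen_params=chosen,
        per_subject_accuracy=per_subject,
        mean_accuracy=float(accs.mean()),
        expanded_uncertainty=float(coverage_factor * se),
        coverage_factor=coverage_factor,
        mcc=float(mcc_from_counts(tp, tn, fp, fn)),
        tp=tp, tn=tn, fp=fp, fn=fn,
    )
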