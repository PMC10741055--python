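"""Subject-grouped cross-validated multiclass voice classification.

Recordings of one subject (including longitudinal sessions) must never be
split between training and validation, or the classifier learns speaker
identity instead of pathology.  The fold plan therefore assigns subjects,
not recordings, to the 10 folds, greedily balancing class counts.

Three model families are tuned per cohort group — k-nearest neighbors,
Gaussian-kernel SVM and random forest — by a seeded sequential
model-based optimizer (random-forest surrogate, expected-improvement
acquisition) maximizing mean cross-validated global accuracy, with
budgets of 30 evaluations for KNN and 60 for SVM and RF.  Reporting is
per class (precision, recall, specificity, F1, one-vs-rest AUC) plus
global accuracy, each as mean +/- std across folds, in percent.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial.distance import cdist
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.metrics import roc_auc_score
from sklearn.multiclass import OneVsRestClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from voxpheno.cohort import FEATURE_NAMES

N_FOLDS = 10

#: optimizer budgets per family (objective evaluations)
BUDGETS = {"knn": 30, "svm": 60, "rf": 60}

KNN_DISTANCES = (
    "cityblock",
    "chebyshev",
    "correlation",
    "cosine",
    "euclidean",
    "hamming",
    "jaccard",
    "mahalanobis",
    "minkowski",
    "seuclidean",
    "spearman",
)
KNN_WEIGHTS = ("equal", "inverse", "squared_inverse")

#: the "twoing" split criterion has no scikit-learn equivalent and is
#: excluded from the RF space; deviance maps to cross-entropy, gdi to Gini.
RF_CRITERIA = {"deviance": "log_loss", "gdi": "gini"}

_PARAM_SPECS: dict[str, list[tuple]] = {
    "knn": [
        ("k", "int", (2, 27)),
        ("distance", "cat", KNN_DISTANCES),
        ("weight", "cat", KNN_WEIGHTS),
    ],
    "svm": [
        ("coding", "cat", ("one_vs_one", "one_vs_all")),
        ("box_constraint", "log", (1e-3, 1e3)),
        ("kernel_scale", "log", (1e-3, 1e3)),
    ],
    "rf": [
        ("min_leaf", "int", (2, 27)),
        ("max_splits", "int", (2, 27)),
        ("split_criterion", "cat", tuple(RF_CRITERIA)),
        ("n_vars_sampled", "int", (1, 55)),
    ],
}


@dataclass(frozen=True)
class SearchSpace:
    """Hyperparameter search space of one model family."""

    family: str

    def __post_init__(self) -> None:
        if self.family not in _PARAM_SPECS:
            raise ValueError(f"unknown family {self.family!r}")

    @property
    def params(self) -> list[tuple]:
        return _PARAM_SPECS[self.family]

    def sample(self, rng: np.random.Generator) -> dict:
        """Draw one configuration uniformly (log-uniform on log axes)."""
        cfg: dict = {"family": self.family}
        for name, kind, spec in self.params:
            if kind == "int":
                cfg[name] = int(rng.integers(spec[0], spec[1] + 1))
            elif kind == "log":
                cfg[name] = float(
                    10 ** rng.uniform(np.log10(spec[0]), np.log10(spec[1]))
                )
            else:
                cfg[name] = spec[int(rng.integers(len(spec)))]
        return cfg

    def contains(self, cfg: dict) -> bool:
        for name, kind, spec in self.params:
            v = cfg[name]
            if kind == "int" and not (spec[0] <= v <= spec[1]):
                return False
            if kind == "log" and not (spec[0] <= v <= spec[1]):
                return False
            if kind == "cat" and v not in spec:
                return False
        return True

    def encode(self, cfg: dict) -> np.ndarray:
        """Numeric encoding for the surrogate (one-hot categoricals)."""
        parts: list[float] = []
        for name, kind, spec in self.params:
            if kind == "int":
                parts.append(float(cfg[name]))
            elif kind == "log":
                parts.append(float(np.log10(cfg[name])))
            else:
                parts.extend(1.0 if cfg[name] == c else 0.0 for c in spec)
        return np.array(parts)


# ---------------------------------------------------------------------------
# fold plan
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FoldPlan:
    """Subject -> fold assignment for grouped k-fold cross-validation."""

    k: int
    assignment: dict[str, int]

    def __post_init__(self) -> None:
        folds = set(self.assignment.values())
        if not folds <= set(range(self.k)):
            raise ValueError("fold indices must lie in [0, k)")

    def validation_subjects(self, fold: int) -> set[str]:
        return {s for s, f in self.assignment.items() if f == fold}


def grouped_kfold(
    subject_labels: Mapping[str, str], k: int = N_FOLDS, seed: int = 0
) -> FoldPlan:
    """Assign whole subjects to ``k`` folds, balancing classes greedily.

    Subjects are shuffled by ``seed`` within each class (largest classes
    placed first) and each goes to the fold currently holding the fewest
    members of its class, ties broken by lowest total count then lowest
    fold index.  Deterministic for a fixed seed.
    """
    subjects = list(subject_labels)
    if len(subjects) < k:
        raise ValueError(f"need >= {k} subjects, got {len(subjects)}")
    rng = np.random.default_rng(seed)
    by_class: dict[str, list[str]] = {}
    for s in sorted(subjects):
        by_class.setdefault(subject_labels[s], []).append(s)
    class_counts = np.zeros((k,), dtype=int)
    per_class_counts: dict[str, np.ndarray] = {}
    assignment: dict[str, int] = {}
    for label in sorted(by_class, key=lambda c: -len(by_class[c])):
        members = by_class[label]
        rng.shuffle(members)
        counts = per_class_counts.setdefault(label, np.zeros((k,), dtype=int))
        for s in members:
            order = sorted(range(k), key=lambda f: (counts[f], class_counts[f], f))
            f = order[0]
            assignment[s] = f
            counts[f] += 1
            class_counts[f] += 1
    return FoldPlan(k=k, assignment=assignment)


def check_no_leakage(
    plan: FoldPlan, subjects: Sequence[str]
) -> None:
    """Assert that no subject's recordings straddle a train/validation split."""
    subjects = np.asarray(subjects)
    for fold in range(plan.k):
        val = plan.validation_subjects(fold)
        val_set = set(subjects[np.isin(subjects, list(val))])
        train_set = set(subjects[~np.isin(subjects, list(val))])
        overlap = val_set & train_set
        if overlap:
            raise AssertionError(f"subjects in both splits of fold {fold}: {overlap}")


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------

class KNNVoice:
    """k-nearest-neighbor classifier over a broad distance menu.

    Distances are evaluated with scipy ``cdist``; ``spearman`` is the
    correlation distance on within-row ranks and the binary distances
    (hamming, jaccard) act on the sign pattern of the standardized
    features.  Covariance-based distances estimate their parameters on
    the training data only.
    """

    def __init__(self, k: int = 5, distance: str = "euclidean", weight: str = "equal"):
        if distance not in KNN_DISTANCES:
            raise ValueError(f"unknown distance {distance!r}")
        if weight not in KNN_WEIGHTS:
            raise ValueError(f"unknown weight {weight!r}")
        self.k = int(k)
        self.distance = distance
        self.weight = weight

    def _transform(self, X: np.ndarray) -> np.ndarray:
        if self.distance in ("hamming", "jaccard"):
            return (X > 0).astype(float)
        if self.distance == "spearman":
            return sps.rankdata(X, axis=1).astype(float)
        return X

    def fit(self, X: np.ndarray, y: np.ndarray) -> "KNNVoice":
        X = np.asarray(X, dtype=float)
        self._X = self._transform(X)
        self._y = np.asarray(y)
        self.classes_ = np.unique(self._y)
        self._cdist_kw: dict = {}
        metric = self.distance
        if metric == "spearman":
            metric = "correlation"
        elif metric == "minkowski":
            self._cdist_kw["p"] = 3
        elif metric == "seuclidean":
            v = np.var(self._X, axis=0, ddof=1)
            self._cdist_kw["V"] = np.where(v > 1e-12, v, 1e-12)
        elif metric == "mahalanobis":
            cov = np.cov(self._X, rowvar=False)
            self._cdist_kw["VI"] = np.linalg.pinv(np.atleast_2d(cov))
        self._metric = metric
        return self

    def _neighbor_weights(self, X: np.ndarray):
        d = cdist(self._transform(np.asarray(X, dtype=float)), self._X,
                  metric=self._metric, **self._cdist_kw)
        d = np.nan_to_num(d, nan=np.nanmax(d[np.isfinite(d)], initial=1.0) + 1.0)
        k = min(self.k, self._X.shape[0])
        idx = np.argsort(d, axis=1)[:, :k]
        dk = np.take_along_axis(d, idx, axis=1)
        if self.weight == "equal":
            w = np.ones_like(dk)
        elif self.weight == "inverse":
            w = 1.0 / np.maximum(dk, 1e-12)
        else:
            w = 1.0 / np.maximum(dk, 1e-12) ** 2
        return idx, w

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        idx, w = self._neighbor_weights(X)
        labels = self._y[idx]
        proba = np.zeros((X.shape[0], self.classes_.size))
        for j, c in enumerate(self.classes_):
            proba[:, j] = np.sum(w * (labels == c), axis=1)
        return proba / np.maximum(proba.sum(axis=1, keepdims=True), 1e-12)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


def build_model(config: dict, seed: int = 0):
    """Instantiate an estimator from a tuned configuration."""
    family = config["family"]
    if family == "knn":
        return KNNVoice(k=config["k"], distance=config["distance"], weight=config["weight"])
    if family == "svm":
        svc = SVC(
            C=config["box_constraint"],
            kernel="rbf",
            gamma=1.0 / config["kernel_scale"] ** 2,
            decision_function_shape="ovr",
            random_state=seed,
        )
        if config["coding"] == "one_vs_all":
            return OneVsRestClassifier(svc)
        return svc
    if family == "rf":
        return RandomForestClassifier(
            n_estimators=100,
            min_samples_leaf=config["min_leaf"],
            max_leaf_nodes=config["max_splits"] + 1,
            criterion=RF_CRITERIA[config["split_criterion"]],
            max_features=config["n_vars_sampled"],
            random_state=seed,
        )
    raise ValueError(f"unknown family {family!r}")


def _class_scores(model, X: np.ndarray) -> np.ndarray:
    """Per-class score matrix aligned with ``model.classes_``."""
    if hasattr(model, "predict_proba"):
        try:
            return model.predict_proba(X)
        except AttributeError:
            pass
    scores = model.decision_function(X)
    if scores.ndim == 1:  # binary: expand to two columns
        return np.column_stack([-scores, scores])
    return scores


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

METRIC_NAMES = ("precision", "recall", "specificity", "f1", "auc")


def binary_metrics(tp: int, fp: int, fn: int, tn: int) -> dict[str, float]:
    """One-vs-rest confusion-matrix metrics in percent (NaN when undefined)."""

    def _ratio(num, den):
        return 100.0 * num / den if den > 0 else np.nan

    precision = _ratio(tp, tp + fp)
    recall = _ratio(tp, tp + fn)
    if np.isnan(precision) or np.isnan(recall) or precision + recall == 0:
        f1 = np.nan
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return {
        "precision": precision,
        "recall": recall,
        "specificity": _ratio(tn, tn + fp),
        "f1": f1,
    }


@dataclass
class CVReport:
    """Per-class and global cross-validation metrics, mean +/- std (%)."""

    classes: tuple[str, ...]
    per_class: dict[str, dict[str, tuple[float, float]]]
    global_accuracy: tuple[float, float]
    best_config: dict | None = None
    fold_counts: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "per_class": {
                c: {m: list(v) for m, v in d.items()} for c, d in self.per_class.items()
            },
            "global_accuracy": list(self.global_accuracy),
            "best_config": self.best_config,
            "fold_counts": self.fold_counts,
        }


def _fold_indices(plan: FoldPlan, subjects: np.ndarray):
    for fold in range(plan.k):
        val_subj = plan.validation_subjects(fold)
        val = np.isin(subjects, list(val_subj))
        if val.any() and (~val).any():
            yield fold, ~val, val


def evaluate(
    model_factory: Callable[[], object],
    X: np.ndarray,
    y: np.ndarray,
    subjects: Sequence[str],
    plan: FoldPlan,
) -> CVReport:
    """Cross-validate a model under a grouped fold plan.

    Standardization is fit on the training folds only; validation rows
    are transformed with the training statistics.  A class absent from a
    fold's validation set contributes no metrics for that fold (the
    per-class fold count is reported).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    subjects = np.asarray(subjects)
    check_no_leakage(plan, subjects)
    classes = tuple(sorted(np.unique(y)))
    per_fold: dict[str, dict[str, list[float]]] = {
        c: {m: [] for m in METRIC_NAMES} for c in classes
    }
    acc: list[float] = []
    for _, train, val in _fold_indices(plan, subjects):
        assert not (set(subjects[train]) & set(subjects[val]))
        scaler = StandardScaler().fit(X[train])
        Xtr, Xva = scaler.transform(X[train]), scaler.transform(X[val])
        model = model_factory()
        model.fit(Xtr, y[train])
        pred = model.predict(Xva)
        scores = _class_scores(model, Xva)
        model_classes = list(model.classes_)
        acc.append(100.0 * float(np.mean(pred == y[val])))
        for c in classes:
            truth = y[val] == c
            if not truth.any():
                continue
            hit = pred == c
            m = binary_metrics(
                tp=int(np.sum(hit & truth)),
                fp=int(np.sum(hit & ~truth)),
                fn=int(np.sum(~hit & truth)),
                tn=int(np.sum(~hit & ~truth)),
            )
            if c in model_classes and truth.any() and (~truth).any():
                m["auc"] = 100.0 * roc_auc_score(
                    truth, scores[:, model_classes.index(c)]
                )
            else:
                m["auc"] = np.nan
            for name in METRIC_NAMES:
                per_fold[c][name].append(m[name])

    def _agg(vals: list[float]) -> tuple[float, float]:
        arr = np.asarray(vals, dtype=float)
        arr = arr[~np.isnan(arr)]
        if arr.size == 0:
            return (np.nan, np.nan)
        return (float(arr.mean()), float(arr.std(ddof=1)) if arr.size > 1 else 0.0)

    per_class = {
        c: {m: _agg(per_fold[c][m]) for m in METRIC_NAMES} for c in classes
    }
    fold_counts = {
        c: int(np.sum(~np.isnan(per_fold[c]["recall"]))) for c in classes
    }
    return CVReport(
        classes=classes,
        per_class=per_class,
        global_accuracy=_agg(acc),
        fold_counts=fold_counts,
    )


def _cv_accuracy(
    config: dict,
    X: np.ndarray,
    y: np.ndarray,
    subjects: np.ndarray,
    plan: FoldPlan,
    seed: int,
) -> float:
    """Mean cross-validated global accuracy of one configuration."""
    accs = []
    for _, train, val in _fold_indices(plan, subjects):
        scaler = StandardScaler().fit(X[train])
        model = build_model(config, seed=seed)
        model.fit(scaler.transform(X[train]), y[train])
        pred = model.predict(scaler.transform(X[val]))
        accs.append(float(np.mean(pred == y[val])))
    return 100.0 * float(np.mean(accs)) if accs else np.nan


def tune(
    family: str,
    X: np.ndarray,
    y: np.ndarray,
    subjects: Sequence[str],
    plan: FoldPlan,
    budget: int | None = None,
    seed: int = 0,
    method: str = "surrogate",
) -> tuple[dict, list[tuple[dict, float]]]:
    """Sequential model-based hyperparameter search.

    Evaluates the cross-validated global accuracy of exactly ``budget``
    configurations (default 30 for KNN, 60 for SVM/RF).  After a random
    initial design, a random-forest surrogate ranks candidate draws by
    expected improvement; ``method="random"`` is a seeded pure
    random-search fallback with the identical objective.  Returns the
    best observed configuration and the full evaluation history.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    subjects = np.asarray(subjects)
    if np.unique(y).size < 2:
        raise ValueError("need at least two classes to tune a classifier")
    space = SearchSpace(family)
    if budget is None:
        budget = BUDGETS[family]
    rng = np.random.default_rng(seed)
    history: list[tuple[dict, float]] = []

    def _evaluate(cfg: dict) -> None:
        assert space.contains(cfg)
        history.append((cfg, _cv_accuracy(cfg, X, y, subjects, plan, seed)))

    n_init = budget if method == "random" else min(max(3, budget // 4), budget)
    for _ in range(n_init):
        _evaluate(space.sample(rng))
    while len(history) < budget:
        Z = np.array([space.encode(c) for c, _ in history])
        scores = np.array([a for _, a in history])
        surrogate = RandomForestRegressor(
            n_estimators=50, random_state=int(rng.integers(2**31 - 1))
        )
        surrogate.fit(Z, scores)
        candidates = [space.sample(rng) for _ in range(128)]
        Zc = np.array([space.encode(c) for c in candidates])
        preds = np.stack([t.predict(Zc) for t in surrogate.estimators_])
        mu, sigma = preds.mean(axis=0), preds.std(axis=0) + 1e-9
        best = scores.max()
        z = (mu - best) / sigma
        ei = (mu - best) * sps.norm.cdf(z) + sigma * sps.norm.pdf(z)
        _evaluate(candidates[int(np.argmax(ei))])
    assert len(history) == budget
    best_cfg, _ = max(history, key=lambda t: t[1])
    return best_cfg, history


def run_group_experiment(
    table: pd.DataFrame,
    group: str,
    budgets: Mapping[str, int] | None = None,
    seed: int = 0,
    method: str = "surrogate",
    families: Sequence[str] = ("knn", "svm", "rf"),
) -> dict:
    """Tune and evaluate all model families on one cohort group.

    ``table`` is the canonical feature table.  Returns
    ``{"reports": {family: CVReport}, "winner": family}`` with the winner
    chosen by mean cross-validated global accuracy.
    """
    sub = table[table["group"] == group].reset_index(drop=True)
    if sub.empty:
        raise ValueError(f"no rows for group {group!r}")
    if sub["label"].nunique() < 2:
        raise ValueError(f"group {group!r} has fewer than two classes")
    X = sub[list(FEATURE_NAMES)].to_numpy(dtype=float)
    y = sub["label"].to_numpy()
    subjects = sub["subject_id"].to_numpy()
    subject_labels = dict(zip(subjects, y))
    plan = grouped_kfold(subject_labels, k=N_FOLDS, seed=seed)
    reports: dict[str, CVReport] = {}
    for family in families:
        budget = (budgets or {}).get(family)
        best_cfg, _ = tune(
            family, X, y, subjects, plan, budget=budget, seed=seed, method=method
        )
        report = evaluate(
            lambda: build_model(best_cfg, seed=seed), X, y, subjects, plan
        )
        report.best_config = best_cfg
        reports[family] = report
    winner = max(reports, key=lambda f: reports[f].global_accuracy[0])
    return {"reports": reports, "winner": winner}
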