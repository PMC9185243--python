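"""Gait classifiers and macro-averaged evaluation.

Five classifier families are configured with fixed hyperparameters:
gradient boosting (10 stages, log-loss/deviance criterion, subsample 1.0),
k-nearest neighbours (k = 4, distance weighting, Minkowski order 1),
a multilayer perceptron (two hidden layers of 50, ReLU, Adam, up to 800
iterations), a random forest (57 trees) and a linear-kernel support vector
machine.  Multi-class results are reported with macro-averaged precision
and recall: per class i, Precision_i = TP_i/(TP_i+FP_i) and
Recall_i = TP_i/(TP_i+FN_i); the macro value is the unweighted mean over
classes.  A class never predicted (TP+FP = 0) contributes precision 0 and
is flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.model_selection import train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .errors import GaitPoseError, SchemaError
from .screening import ImportanceRanking, rank_features

ALGORITHMS = (
    "gradient_boosting",
    "k_neighbors",
    "multilayer_perceptron",
    "random_forest",
    "support_vector_machine",
)

_SHORT = {
    "gradient_boosting": "GB",
    "k_neighbors": "KN",
    "multilayer_perceptron": "MLP",
    "random_forest": "RF",
    "support_vector_machine": "SVM",
}

FEATURE_MODES = ("2d-11", "3d-8", "3d-11")


@dataclass(frozen=True)
class ClassifierSpec:
    """An algorithm name plus its (fixed) parameter overrides and seed."""

    algorithm: str
    seed: int = 0
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise GaitPoseError(
                f"unknown algorithm {self.algorithm!r}; expected one of "
                f"{ALGORITHMS}"
            )

    @property
    def short_name(self) -> str:
        return _SHORT[self.algorithm]


def build_model(spec: ClassifierSpec):
    """Instantiate the (unfitted) scikit-learn estimator for a spec."""
    a = spec.algorithm
    if a == "gradient_boosting":
        params = dict(
            n_estimators=10, loss="log_loss", subsample=1.0,
            random_state=spec.seed,
        )
    elif a == "k_neighbors":
        params = dict(n_neighbors=4, weights="distance", p=1)
    elif a == "multilayer_perceptron":
        params = dict(
            hidden_layer_sizes=(50, 50), activation="relu", solver="adam",
            max_iter=800, random_state=1,
        )
    elif a == "random_forest":
        params = dict(n_estimators=57, random_state=spec.seed)
    else:  # support_vector_machine
        # the kernel coefficient is recorded but inert for a linear kernel
        params = dict(kernel="linear", gamma=1.0, random_state=spec.seed)
    params.update(spec.params)
    cls = {
        "gradient_boosting": GradientBoostingClassifier,
        "k_neighbors": KNeighborsClassifier,
        "multilayer_perceptron": MLPClassifier,
        "random_forest": RandomForestClassifier,
        "support_vector_machine": SVC,
    }[a]
    return cls(**params)


@dataclass(frozen=True)
class EvaluationReport:
    """Confusion matrix (rows = true) with per-class and macro metrics."""

    labels: tuple
    confusion: np.ndarray
    precision: dict
    recall: dict
    macro_precision: float
    macro_recall: float
    undefined_precision: tuple = ()

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.confusion) / self.confusion.sum())

    def summary(self) -> str:
        width = max(len(str(l)) for l in self.labels)
        lines = ["Confusion matrix (rows = true class)"]
        header = " " * (width + 2) + "  ".join(
            f"{str(l):>{width}s}" for l in self.labels
        )
        lines.append(header)
        for i, l in enumerate(self.labels):
            row = "  ".join(
                f"{int(v):>{width}d}" for v in self.confusion[i]
            )
            lines.append(f"{str(l):>{width}s}  {row}")
        lines.append("")
        lines.append(f"{'class':>{width}s}  precision  recall")
        for l in self.labels:
            lines.append(
                f"{str(l):>{width}s}  {self.precision[l]:9.4f}  "
                f"{self.recall[l]:6.4f}"
            )
        lines.append(
            f"macro precision = {self.macro_precision:.4f}, "
            f"macro recall = {self.macro_recall:.4f}"
        )
        return "\n".join(lines)


def evaluate(y_true, y_pred, labels=None) -> EvaluationReport:
    """Macro-averaged precision/recall from explicit prediction counting."""
    y_true = list(y_true)
    y_pred = list(y_pred)
    if len(y_true) != len(y_pred):
        raise GaitPoseError("y_true and y_pred differ in length")
    if labels is None:
        labels = sorted(set(y_true) | set(y_pred))
    labels = tuple(labels)
    if not (set(y_true) | set(y_pred)) <= set(labels):
        raise GaitPoseError("labels do not cover all observed values")
    index = {l: i for i, l in enumerate(labels)}
    n = len(labels)
    cm = np.zeros((n, n), dtype=int)
    for t, p in zip(y_true, y_pred):
        cm[index[t], index[p]] += 1
    precision: dict = {}
    recall: dict = {}
    undefined = []
    for l in labels:
        i = index[l]
        tp = cm[i, i]
        fp = cm[:, i].sum() - tp
        fn = cm[i, :].sum() - tp
        if tp + fp == 0:
            precision[l] = 0.0
            undefined.append(l)
        else:
            precision[l] = float(tp / (tp + fp))
        recall[l] = float(tp / (tp + fn)) if tp + fn > 0 else 0.0
    return EvaluationReport(
        labels=labels,
        confusion=cm,
        precision=precision,
        recall=recall,
        macro_precision=float(np.mean([precision[l] for l in labels])),
        macro_recall=float(np.mean([recall[l] for l in labels])),
        undefined_precision=tuple(undefined),
    )


@dataclass(frozen=True)
class BenchmarkReport:
    """Per-mode, per-algorithm macro metrics plus per-class recalls."""

    results: dict  # (mode, algorithm) -> EvaluationReport
    modes: tuple
    algorithms: tuple
    ranking: ImportanceRanking | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for algo in self.algorithms:
            row: dict = {"algorithm": _SHORT[algo]}
            for mode in self.modes:
                rep = self.results[(mode, algo)]
                row[f"{mode}_recall"] = rep.macro_recall
                row[f"{mode}_precision"] = rep.macro_precision
            rows.append(row)
        return pd.DataFrame(rows)

    def per_class_recall(self, mode: str, algorithm: str) -> dict:
        return dict(self.results[(mode, algorithm)].recall)

    def summary(self) -> str:
        lines = ["Macro recall / precision by algorithm and feature mode"]
        header = f"{'algorithm':<10s}" + "".join(
            f"  {m + ' R':>9s}  {m + ' P':>9s}" for m in self.modes
        )
        lines.append(header)
        for algo in self.algorithms:
            cells = []
            for mode in self.modes:
                rep = self.results[(mode, algo)]
                cells.append(f"  {rep.macro_recall:>9.4f}  {rep.macro_precision:>9.4f}")
            lines.append(f"{_SHORT[algo]:<10s}" + "".join(cells))
        return "\n".join(lines)


def run_benchmark(
    X2d: pd.DataFrame | None,
    X3d: pd.DataFrame | None,
    y,
    specs: tuple[ClassifierSpec, ...] | None = None,
    modes: tuple[str, ...] = FEATURE_MODES,
    split_seed: int = 0,
    ranking: ImportanceRanking | None = None,
    screen_seed: int = 0,
) -> BenchmarkReport:
    """Fit every classifier per feature mode on one stratified 70/30 split.

    Modes: ``2d-11`` (all planar features), ``3d-11`` (all reconstructed
    features), ``3d-8`` (top 8 reconstructed features by boosted-tree
    importance).  The same train/test rows are used for every mode so the
    comparison isolates the feature variant.
    """
    y = np.asarray(y)
    if specs is None:
        specs = tuple(ClassifierSpec(a, seed=split_seed) for a in ALGORITHMS)
    for mode in modes:
        if mode not in FEATURE_MODES:
            raise SchemaError(f"unknown feature mode {mode!r}")
        if mode.startswith("2d") and X2d is None:
            raise SchemaError(f"mode {mode!r} requested but no 2D features given")
        if mode.startswith("3d") and X3d is None:
            raise SchemaError(f"mode {mode!r} requested but no 3D features given")

    idx_train, idx_test = train_test_split(
        np.arange(len(y)),
        test_size=0.3,
        random_state=split_seed,
        stratify=y,
    )
    if "3d-8" in modes and ranking is None:
        ranking = rank_features(X3d, y, seed=screen_seed)

    results: dict = {}
    for mode in modes:
        X = X2d if mode.startswith("2d") else X3d
        X = pd.DataFrame(X)
        if mode == "3d-8":
            X = X[ranking.top(8)]
        for spec in specs:
            model = build_model(spec)
            model.fit(X.iloc[idx_train], y[idx_train])
            pred = model.predict(X.iloc[idx_test])
            results[(mode, spec.algorithm)] = evaluate(
                y[idx_test], pred, labels=sorted(set(y))
            )
    return BenchmarkReport(
        results=results,
        modes=tuple(modes),
        algorithms=tuple(s.algorithm for s in specs),
        ranking=ranking,
    )
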