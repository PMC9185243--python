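"""Boosted-tree feature screening and the acceptance-score curve.

Features are ranked by the normalized total-gain importance of a gradient
boosted decision-tree ensemble (tree booster, learning rate 0.3, maximum
depth 6, 100 boosting rounds) fit on the full table.  The acceptance curve
then records, for every feature count k from all features down to one, the
held-out accuracy ("acceptance score") of the same ensemble retrained on
the top-k features, using a stratified 70/30 train/test split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split
from sklearn.preprocessing import LabelEncoder
from xgboost import XGBClassifier

from .errors import GaitPoseError

XGB_PARAMS = dict(
    booster="gbtree",
    learning_rate=0.3,
    max_depth=6,
    n_estimators=100,
)

TEST_FRACTION = 0.3


@dataclass(frozen=True)
class ImportanceRanking:
    """Ordered (feature, score) pairs; scores sum to 1."""

    pairs: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        scores = np.array([s for _, s in self.pairs])
        if np.any(scores < 0):
            raise ValueError("importance scores must be non-negative")
        if abs(scores.sum() - 1.0) > 1e-9:
            raise ValueError("importance scores must sum to 1")

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.pairs]

    @property
    def scores(self) -> dict[str, float]:
        return dict(self.pairs)

    def top(self, k: int) -> list[str]:
        return self.names[:k]

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class AcceptanceCurve:
    """Acceptance score (held-out accuracy) per retained feature count."""

    scores: dict[int, float]
    test_size: int

    def __post_init__(self) -> None:
        ks = sorted(self.scores)
        if ks != list(range(1, max(ks) + 1)):
            raise ValueError("curve must be defined for every k from 1 to max")
        for v in self.scores.values():
            if not 0.0 <= v <= 1.0:
                raise ValueError("acceptance scores must lie in [0, 1]")


@dataclass(frozen=True)
class SelectedFeatures:
    """Smallest feature count achieving the maximal acceptance score."""

    k: int
    features: tuple[str, ...]
    best_score: float
    tied_ks: tuple[int, ...]


def _make_booster(seed: int) -> XGBClassifier:
    return XGBClassifier(random_state=seed, verbosity=0, **XGB_PARAMS)


def _check_inputs(X: pd.DataFrame, y) -> tuple[pd.DataFrame, np.ndarray]:
    X = pd.DataFrame(X)
    y = np.asarray(y)
    if len(X) != len(y):
        raise GaitPoseError("X and y differ in length")
    if X.isna().to_numpy().any():
        raise GaitPoseError("feature table contains missing values")
    if len(np.unique(y)) < 2:
        raise GaitPoseError("need at least two classes to screen features")
    return X, y


def rank_features(X: pd.DataFrame, y, seed: int = 0) -> ImportanceRanking:
    """Rank features by normalized total-gain importance.

    Ties (including zero-importance constant features) are broken by
    feature-name order.
    """
    X, y = _check_inputs(X, y)
    codes = LabelEncoder().fit_transform(y)
    model = _make_booster(seed)
    model.fit(X, codes)
    gains = model.get_booster().get_score(importance_type="total_gain")
    raw = {name: float(gains.get(name, 0.0)) for name in X.columns}
    total = sum(raw.values())
    if total <= 0:
        scores = {name: 1.0 / len(raw) for name in raw}
    else:
        scores = {name: v / total for name, v in raw.items()}
    ordered = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    # exact renormalisation guard against float drift
    s = sum(v for _, v in ordered)
    ordered = [(n, v / s) for n, v in ordered]
    return ImportanceRanking(tuple(ordered))


def acceptance_curve(
    X: pd.DataFrame, y, ranking: ImportanceRanking, split_seed: int = 0
) -> AcceptanceCurve:
    """Held-out accuracy for each top-k feature subset, k = all .. 1."""
    X, y = _check_inputs(X, y)
    idx_train, idx_test = train_test_split(
        np.arange(len(y)),
        test_size=TEST_FRACTION,
        random_state=split_seed,
        stratify=y,
    )
    if set(np.unique(y[idx_test])) != set(np.unique(y)):
        raise GaitPoseError("test fold is missing a class (stratification error)")
    scores: dict[int, float] = {}
    for k in range(len(ranking), 0, -1):
        cols = ranking.top(k)
        model = _make_booster(split_seed)
        codes = LabelEncoder().fit_transform(y)
        model.fit(X.iloc[idx_train][cols], codes[idx_train])
        pred = model.predict(X.iloc[idx_test][cols])
        scores[k] = float(np.mean(pred == codes[idx_test]))
    return AcceptanceCurve(scores=scores, test_size=len(idx_test))


def select_features(
    curve: AcceptanceCurve, ranking: ImportanceRanking
) -> SelectedFeatures:
    """Smallest k achieving the maximal acceptance score (ties reported)."""
    best = max(curve.scores.values())
    tied = tuple(sorted(k for k, v in curve.scores.items() if v == best))
    k = tied[0]
    return SelectedFeatures(
        k=k,
        features=tuple(ranking.top(k)),
        best_score=best,
        tied_ks=tied,
    )


class FeatureScreen:
    """Screening model over a feature table: rank, curve, selection.

    ``FeatureScreen(X, y).fit()`` returns a :class:`FeatureScreenResult`
    whose ``summary()`` prints the importance ranking and the acceptance
    scores for every feature count.
    """

    def __init__(self, X: pd.DataFrame, y) -> None:
        self.X, self.y = _check_inputs(X, y)

    def fit(self, seed: int = 0, split_seed: int = 0) -> "FeatureScreenResult":
        ranking = rank_features(self.X, self.y, seed=seed)
        curve = acceptance_curve(self.X, self.y, ranking, split_seed=split_seed)
        selection = select_features(curve, ranking)
        return FeatureScreenResult(ranking, curve, selection)


@dataclass(frozen=True)
class FeatureScreenResult:
    ranking: ImportanceRanking
    curve: AcceptanceCurve
    selection: SelectedFeatures

    def to_frame(self) -> pd.DataFrame:
        ks = sorted(self.curve.scores, reverse=True)
        return pd.DataFrame(
            {"n_features": ks, "score": [self.curve.scores[k] for k in ks]}
        )

    def summary(self) -> str:
        lines = ["Feature importance (normalized total gain)"]
        for name, score in self.ranking.pairs:
            lines.append(f"  {name:<5s} {score:8.4f}")
        lines.append("")
        lines.append("Acceptance scores by number of retained features")
        lines.append("  n_features  score")
        for k in sorted(self.curve.scores, reverse=True):
            lines.append(f"  {k:>10d}  {self.curve.scores[k]:.4f}")
        tied = ", ".join(str(k) for k in self.selection.tied_ks)
        lines.append("")
        lines.append(
            f"Best score {self.selection.best_score:.4f} with "
            f"{self.selection.k} features (tied at: {tied})"
        )
        return "\n".join(lines)
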