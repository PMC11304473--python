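"""Emission-level classification from hydrologic descriptors.

Seasonal CH4 totals are discretized into ordered levels (five by
default, by equal-frequency quantiles; fixed published cut sets are
available as presets), split 80:20 with per-level stratification, and
modeled two ways: a random forest (headline out-of-bag error, Gini
importances) and a single cost-complexity-pruned classification tree
for interpretation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

#: Published five-level CH4 cut points (kg/ha). The two sets circulate in
#: the same study and disagree; both are provided, neither is endorsed.
LEVEL_CUT_PRESETS: dict[str, tuple[float, ...]] = {
    "methods": (56.6, 129.0, 207.0, 317.0),
    "tree_figure": (73.6, 162.0, 254.0, 383.0),
}


@dataclass(frozen=True)
class LevelScheme:
    """Monotone mapping from a continuous flux to levels 1..n.

    Intervals are left-open right-closed except the first:
    level = 1 + #{boundaries strictly below the value}.
    """

    boundaries: tuple[float, ...]
    method: str  # "equal_frequency" | "fixed"

    def __post_init__(self) -> None:
        b = self.boundaries
        if any(b[i] >= b[i + 1] for i in range(len(b) - 1)):
            raise ValueError("boundaries must be strictly increasing")

    @property
    def n_levels(self) -> int:
        return len(self.boundaries) + 1

    def assign(self, values) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        return 1 + np.sum(values[:, None] > np.asarray(self.boundaries)[None, :], axis=1)


def discretize(
    values,
    n_levels: int = 5,
    boundaries: Optional[Sequence[float]] = None,
) -> tuple[LevelScheme, np.ndarray]:
    """Build a level scheme and label the values.

    With explicit ``boundaries`` the scheme is fixed; otherwise cut
    points sit at the i/n-quantiles of the values (equal frequency),
    which requires at least ``n_levels`` distinct values.
    """
    values = np.asarray(values, dtype=float)
    if boundaries is not None:
        scheme = LevelScheme(tuple(float(b) for b in boundaries), "fixed")
        return scheme, scheme.assign(values)
    if len(np.unique(values)) < n_levels:
        raise ValueError(f"need >= {n_levels} distinct values for equal-frequency levels")
    qs = np.quantile(values, [i / n_levels for i in range(1, n_levels)])
    if len(np.unique(qs)) < len(qs):
        raise ValueError("tied quantiles: values too concentrated for equal-frequency levels")
    scheme = LevelScheme(tuple(float(q) for q in qs), "equal_frequency")
    return scheme, scheme.assign(values)


def stratified_split(
    X: pd.DataFrame,
    labels: np.ndarray,
    ratio: float = 0.8,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-level train/test split at ``ratio`` (positional indices).

    Within every level the training allocation is the integer nearest to
    ``ratio``·n (so 20 members at 0.8 give exactly 16/4), after a seeded
    shuffle; train and test are disjoint and exhaustive.
    """
    if not (0.0 < ratio < 1.0):
        raise ValueError("split ratio must be in (0, 1)")
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for lev in np.unique(labels):
        idx = np.flatnonzero(labels == lev)
        if len(idx) < 2:
            raise ValueError(f"level {lev} has a single member; cannot stratify")
        rng.shuffle(idx)
        n_train = int(np.clip(round(ratio * len(idx)), 1, len(idx) - 1))
        train_idx.extend(idx[:n_train])
        test_idx.extend(idx[n_train:])
    return np.sort(np.array(train_idx)), np.sort(np.array(test_idx))


@dataclass
class LevelClassifier:
    """Fitted forest + pruned tree predicting CH4 level from descriptors."""

    scheme: LevelScheme
    forest: RandomForestClassifier
    tree: DecisionTreeClassifier
    feature_names: list[str]
    oob_error: float
    gini_importance: pd.Series
    ccp_alpha: float
    test_accuracy_forest: Optional[float] = None
    test_accuracy_tree: Optional[float] = None
    test_confusion: Optional[np.ndarray] = None

    def tree_as_dict(self) -> dict:
        """The pruned tree as nested JSON-able splits."""
        t = self.tree.tree_

        def node(i: int) -> dict:
            if t.children_left[i] == -1:
                counts = t.value[i][0]
                return {"leaf": True,
                        "level": int(self.tree.classes_[int(np.argmax(counts))]),
                        "n": int(t.n_node_samples[i])}
            return {
                "leaf": False,
                "descriptor": self.feature_names[t.feature[i]],
                "threshold": float(t.threshold[i]),
                "left": node(t.children_left[i]),
                "right": node(t.children_right[i]),
            }

        return node(0)


def _prune_alpha_1se(
    X: np.ndarray, y: np.ndarray, min_leaf: int, seed: int, n_folds: int = 5
) -> float:
    """Cost-complexity alpha by cross-validation with the 1-SE rule."""
    base = DecisionTreeClassifier(min_samples_leaf=min_leaf, random_state=seed)
    alphas = np.unique(base.cost_complexity_pruning_path(X, y).ccp_alphas)
    alphas = alphas[alphas >= 0]
    if len(alphas) <= 1:
        return 0.0
    counts = np.bincount(y)
    n_folds = int(min(n_folds, counts[counts > 0].min()))
    if n_folds < 2:
        return 0.0
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    scores = np.zeros((len(alphas), n_folds))
    for f, (tr, va) in enumerate(cv.split(X, y)):
        for i, a in enumerate(alphas):
            m = DecisionTreeClassifier(
                min_samples_leaf=min_leaf, ccp_alpha=a, random_state=seed
            ).fit(X[tr], y[tr])
            scores[i, f] = m.score(X[va], y[va])
    mean = scores.mean(axis=1)
    se = scores.std(axis=1, ddof=1) / math.sqrt(n_folds)
    best = int(np.argmax(mean))
    threshold = mean[best] - se[best]
    ok = np.flatnonzero(mean >= threshold)
    return float(alphas[ok.max()])  # most pruned tree within 1 SE of the best


def fit_models(
    X_train: pd.DataFrame,
    y_train: np.ndarray,
    scheme: LevelScheme,
    seed: int = 0,
    n_trees: int = 500,
    min_leaf: int = 5,
    X_test: Optional[pd.DataFrame] = None,
    y_test: Optional[np.ndarray] = None,
) -> LevelClassifier:
    """Fit the random forest and the pruned single tree.

    The forest (``n_trees``, sqrt-p features per split) reports OOB error
    and Gini importances; the tree is grown with ``min_leaf`` and pruned
    by cross-validated cost complexity (1-SE rule). If a held-out set is
    given, both models are evaluated on it.
    """
    y_train = np.asarray(y_train)
    if len(X_train) < 30:
        raise ValueError("need at least 30 training records")
    if len(np.unique(y_train)) < 2:
        raise ValueError("degenerate training set: single class")
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        oob_score=True,
        random_state=seed,
        n_jobs=1,
    ).fit(X_train.values, y_train)
    alpha = _prune_alpha_1se(X_train.values, y_train, min_leaf, seed)
    tree = DecisionTreeClassifier(
        min_samples_leaf=min_leaf, ccp_alpha=alpha, random_state=seed
    ).fit(X_train.values, y_train)

    clf = LevelClassifier(
        scheme=scheme,
        forest=forest,
        tree=tree,
        feature_names=list(X_train.columns),
        oob_error=float(1.0 - forest.oob_score_),
        gini_importance=pd.Series(
            forest.feature_importances_, index=X_train.columns
        ).sort_values(ascending=False),
        ccp_alpha=alpha,
    )
    if X_test is not None and y_test is not None:
        y_test = np.asarray(y_test)
        pf = forest.predict(X_test.values)
        pt = tree.predict(X_test.values)
        clf.test_accuracy_forest = float(np.mean(pf == y_test))
        clf.test_accuracy_tree = float(np.mean(pt == y_test))
        clf.test_confusion = confusion_matrix(y_test, pf)
    return clf


def predict_level(model: LevelClassifier, descriptors: pd.DataFrame | pd.Series) -> pd.DataFrame:
    """Forest and tree level predictions for descriptor rows."""
    if isinstance(descriptors, pd.Series):
        descriptors = descriptors.to_frame().T
    missing = [c for c in model.feature_names if c not in descriptors.columns]
    if missing:
        raise ValueError(f"missing descriptors: {missing}")
    X = descriptors[model.feature_names].values
    return pd.DataFrame(
        {
            "forest": model.forest.predict(X).astype(int),
            "tree": model.tree.predict(X).astype(int),
        },
        index=descriptors.index,
    )
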