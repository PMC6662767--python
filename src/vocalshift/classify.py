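"""Bin-level condition classification with bagged decision trees.

An ensemble of bagged trees (Breiman-style bootstrap aggregation of
decision trees) is trained to assign each observation bin to its
recording condition from the 11 acoustic-parameter bin means.  Accuracy
is reported per class from stratified k-fold cross-validation, so every
bin is scored exactly once by a model that never saw it.  Note the
classifier treats bins as independent even though consecutive bins are
autocorrelated — a deliberate fidelity choice, not an oversight.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import BaggingClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from .features import FEATURE_COLUMNS


@dataclass
class ClassifierConfig:
    n_trees: int = 100
    max_depth: int | None = None
    cv_folds: int = 5
    seed: int = 0
    feature_set: list[str] = field(default_factory=lambda: list(FEATURE_COLUMNS))

    def __post_init__(self) -> None:
        if self.n_trees < 10:
            raise ValueError("n_trees must be >= 10")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


@dataclass
class ClassificationResult:
    per_class_accuracy: dict
    confusion: pd.DataFrame      # rows: true class, columns: predicted
    classes: list
    overall_accuracy: float


def classify_bins(bins: pd.DataFrame, label_column: str = "condition",
                  config: ClassifierConfig | None = None
                  ) -> ClassificationResult:
    """Cross-validated per-class correct-assignment rates on bin means.

    Requires at least two classes and at least ``cv_folds`` bins per
    class.  Deterministic under ``config.seed`` (fold assignment and
    bootstrap draws are both seeded).
    """
    if config is None:
        config = ClassifierConfig()
    labels = bins[label_column].to_numpy()
    classes = sorted(pd.unique(labels))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    counts = pd.Series(labels).value_counts()
    if counts.min() < config.cv_folds:
        raise ValueError("each class needs at least cv_folds bins")
    X = bins[config.feature_set].to_numpy(dtype=np.float64)
    y = labels

    skf = StratifiedKFold(n_splits=config.cv_folds, shuffle=True,
                          random_state=config.seed)
    pred = np.empty(len(y), dtype=object)
    for train_idx, test_idx in skf.split(X, y):
        clf = BaggingClassifier(
            estimator=DecisionTreeClassifier(max_depth=config.max_depth,
                                             random_state=config.seed),
            n_estimators=config.n_trees, random_state=config.seed)
        clf.fit(X[train_idx], y[train_idx])
        pred[test_idx] = clf.predict(X[test_idx])

    confusion = pd.crosstab(pd.Series(y, name="true"),
                            pd.Series(pred, name="predicted"))
    confusion = confusion.reindex(index=classes, columns=classes,
                                  fill_value=0)
    per_class = {c: float(confusion.loc[c, c] / confusion.loc[c].sum())
                 for c in classes}
    overall = float(np.mean(pred == y))
    return ClassificationResult(per_class_accuracy=per_class,
                                confusion=confusion, classes=classes,
                                overall_accuracy=overall)
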