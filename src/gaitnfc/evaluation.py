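"""Experiment harness: splits, cross-validation, accuracy, rule sweep.

Any classifier exposing ``fit(train: GaitDataset)`` and
``predict(signals: d x N ndarray) -> labels`` plugs in, so baselines
(nearest-template, scikit-learn estimators, ...) can be compared with
the neuro-fuzzy classifier through thin adapters.  Splitting and
confusion counting are delegated to scikit-learn behind this surface.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit

from .dataset import GaitDataset
from .fcm import FCMConfig
from .model import FCMNFC, FCMNFCResults
from .tsk import TrainConfig

__all__ = ["ConfusionMatrix", "split_holdout", "k_fold", "evaluate",
           "rule_sweep", "FCMNFCClassifier", "NearestTemplateClassifier"]


@dataclass
class ConfusionMatrix:
    """True-class x predicted-class counts, rows/columns in code order."""

    counts: np.ndarray
    class_order: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.class_order)
        if self.counts.shape != (k, k):
            raise ValueError("confusion matrix shape mismatch")
        if (self.counts < 0).any():
            raise ValueError("confusion counts must be >= 0")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        """Percent correct: 100 * trace / total."""
        return 100.0 * float(np.trace(self.counts)) / self.total

    def to_json(self) -> str:
        return json.dumps(
            {"class_order": list(self.class_order),
             "counts": self.counts.tolist()}
        )

    def to_text(self) -> str:
        width = max(12, max(len(c) for c in self.class_order) + 2)
        head = " " * width + "".join(
            f"{c:>{width}}" for c in self.class_order
        )
        rows = [
            f"{c:>{width}}" + "".join(
                f"{n:>{width}d}" for n in self.counts[i]
            )
            for i, c in enumerate(self.class_order)
        ]
        return "\n".join([head, *rows])


def split_holdout(
    data: GaitDataset,
    fraction: float = 0.5,
    seed: Optional[int] = None,
    stratified: bool = True,
) -> tuple[GaitDataset, GaitDataset]:
    """Random train/test split; ``fraction`` is the training share.

    Stratified by default so a balanced 160-sample set splits 20/20 per
    gait.  Train and test are disjoint and exhaustive.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    n = data.n_samples
    y = data.codes
    if stratified:
        counts = np.bincount(y)
        if (counts[counts > 0] < 2).any():
            raise ValueError(
                "every class needs >= 2 samples for a stratified split"
            )
        splitter = StratifiedShuffleSplit(
            n_splits=1, train_size=fraction, random_state=seed
        )
        train_idx, test_idx = next(splitter.split(np.zeros((n, 1)), y))
    else:
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n)
        k = int(round(fraction * n))
        train_idx, test_idx = perm[:k], perm[k:]
    return data.select(np.sort(train_idx)), data.select(np.sort(test_idx))


def k_fold(
    data: GaitDataset, k: int, seed: Optional[int] = None
) -> list[tuple[GaitDataset, GaitDataset]]:
    """Stratified k-fold partition; each sample tests exactly once."""
    if k < 2:
        raise ValueError("k must be >= 2")
    counts = list(data.counts().values())
    if min(c for c in counts if c > 0) < k:
        raise ValueError(f"k={k} exceeds the smallest class count")
    y = data.codes
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = []
    for train_idx, test_idx in splitter.split(np.zeros((data.n_samples, 1)),
                                              y):
        folds.append(
            (data.select(np.sort(train_idx)), data.select(np.sort(test_idx)))
        )
    return folds


def evaluate(
    classifier, train: GaitDataset, test: GaitDataset
) -> tuple[float, ConfusionMatrix]:
    """Fit on ``train``, predict ``test``, return (accuracy %, confusion).

    The classifier must obey the fit/predict contract; anything else
    raises a ``TypeError``.
    """
    if not (hasattr(classifier, "fit") and hasattr(classifier, "predict")):
        raise TypeError(
            "classifier must expose fit(train_dataset) and predict(signals)"
        )
    classifier.fit(train)
    pred = classifier.predict(test.signals)
    order = tuple(
        sorted(test.class_codes, key=lambda g: test.class_codes[g])
    )
    counts = _sk_confusion(test.labels, list(pred), labels=list(order))
    cm = ConfusionMatrix(counts=counts, class_order=order)
    return cm.accuracy, cm


def rule_sweep(
    data: GaitDataset,
    rule_range: Sequence[int],
    fcm_config: Optional[FCMConfig] = None,
    train_config: Optional[TrainConfig] = None,
    seed: Optional[int] = None,
) -> tuple[list[tuple[int, float]], int]:
    """Validation accuracy per rule count on one fixed split.

    Returns the (rules, accuracy %) table and the argmax rule count
    (first of ties).  This is the trial-and-error protocol for choosing
    the rule count over a range such as 2..50.
    """
    train_config = train_config or TrainConfig()
    train, test = split_holdout(data, fraction=0.5, seed=seed)
    table: list[tuple[int, float]] = []
    for r in rule_range:
        clf = FCMNFCClassifier(
            n_rules=r,
            fuzzifier=(fcm_config.m if fcm_config else 2.0),
            epochs=train_config.epochs,
            learning_rate=train_config.learning_rate,
            ridge=train_config.ridge,
            seed=seed,
        )
        acc, _ = evaluate(clf, train, test)
        table.append((int(r), float(acc)))
    best = max(table, key=lambda t: t[1])[0]
    return table, best


# ---------------------------------------------------------------------------
# classifier adapters

class FCMNFCClassifier:
    """fit/predict adapter around :class:`gaitnfc.model.FCMNFC`."""

    def __init__(self, n_rules: int = 33, fuzzifier: float = 2.0,
                 epochs: int = 50, learning_rate: float = 0.01,
                 ridge: float = 1e-8, first_order: bool = True,
                 seed: Optional[int] = None):
        self.n_rules = n_rules
        self.fuzzifier = fuzzifier
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.ridge = ridge
        self.first_order = first_order
        self.seed = seed
        self.results_: Optional[FCMNFCResults] = None

    def fit(self, train: GaitDataset) -> "FCMNFCClassifier":
        model = FCMNFC.from_dataset(
            train, n_rules=self.n_rules, fuzzifier=self.fuzzifier
        )
        self.results_ = model.fit(
            epochs=self.epochs, learning_rate=self.learning_rate,
            ridge=self.ridge, first_order=self.first_order, seed=self.seed,
        )
        return self

    def predict(self, signals: np.ndarray) -> list[str]:
        if self.results_ is None:
            raise TypeError("classifier is not fitted")
        return self.results_.predict(np.atleast_2d(signals).T)


class NearestTemplateClassifier:
    """Baseline: per-class mean signal, nearest template by Euclidean
    distance.  Used as a sanity yardstick for the synthetic data."""

    def __init__(self):
        self.templates_: Optional[dict[str, np.ndarray]] = None

    def fit(self, train: GaitDataset) -> "NearestTemplateClassifier":
        self.templates_ = {}
        for gait in train.class_codes:
            cols = [i for i, l in enumerate(train.labels) if l == gait]
            if cols:
                self.templates_[gait] = train.signals[:, cols].mean(axis=1)
        return self

    def predict(self, signals: np.ndarray) -> list[str]:
        if not self.templates_:
            raise TypeError("classifier is not fitted")
        X = np.atleast_2d(signals)
        names = list(self.templates_)
        T = np.column_stack([self.templates_[g] for g in names])
        d = ((X[:, :, None] - T[:, None, :]) ** 2).sum(axis=0)
        return [names[i] for i in np.argmin(d, axis=1)]
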