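"""Estimator-style front end: ``FCMNFC`` model and ``FCMNFCResults``.

The model object binds the data and hyperparameters; ``fit()`` runs the
full pipeline (FCM scatter partitioning -> rule initialisation -> hybrid
LSE/backprop learning) and returns a results object carrying the fitted
rule base, the training log and prediction/summary methods, in the
spirit of the statsmodels model/results split.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import tsk
from .dataset import DEFAULT_CLASS_CODES, GaitDataset
from .fcm import FCMConfig
from .tsk import RuleBase, TrainConfig

__all__ = ["FCMNFC", "FCMNFCResults"]


class FCMNFC:
    """FCM-seeded Takagi-Sugeno-Kang neuro-fuzzy gait classifier.

    Parameters
    ----------
    endog : sequence
        Per-observation gait labels (strings) or integer class codes.
    exog : ndarray, shape (nobs, k)
        Feature rows, one observation per row (wavelet-packet features
        or raw signal windows).
    n_rules : int
        Number of fuzzy rules = FCM cluster count.  The study-scale
        default is 33; the practical range for these data is 2..50.
    fuzzifier : float
        FCM fuzzifier m > 1.
    class_codes : dict, optional
        label -> code map; defaults to walk/sitting_trot/rising_trot/
        canter coded 1..4.

    Examples
    --------
    >>> from gaitnfc import synthetic, wavelet_features
    >>> data = synthetic.generate_dataset(seed=0)
    >>> feats = wavelet_features.wp_layer_features(data, layer=2)
    >>> model = FCMNFC(data.labels, feats.features.T, n_rules=8)
    >>> res = model.fit(epochs=5, seed=0)
    >>> res.predict(feats.features.T)[:1]
    ['walk']
    """

    def __init__(
        self,
        endog: Sequence,
        exog: np.ndarray,
        n_rules: int = 33,
        fuzzifier: float = 2.0,
        class_codes: Optional[dict[str, int]] = None,
    ):
        self.exog = np.atleast_2d(np.asarray(exog, dtype=float))
        self.class_codes = dict(class_codes or DEFAULT_CLASS_CODES)
        self.endog = self._encode(endog)
        if self.exog.shape[0] != self.endog.size:
            raise ValueError(
                f"{self.endog.size} labels for {self.exog.shape[0]} rows"
            )
        self.n_rules = int(n_rules)
        self.fuzzifier = float(fuzzifier)

    def _encode(self, endog: Sequence) -> np.ndarray:
        vals = list(endog)
        if vals and isinstance(vals[0], str):
            unknown = set(vals) - set(self.class_codes)
            if unknown:
                raise ValueError(f"unregistered labels: {sorted(unknown)}")
            return np.array([self.class_codes[v] for v in vals], dtype=float)
        codes = np.asarray(vals, dtype=float)
        if not set(np.unique(codes)) <= set(
            float(c) for c in self.class_codes.values()
        ):
            raise ValueError("numeric targets outside the registered codes")
        return codes

    @classmethod
    def from_dataset(cls, data: GaitDataset, **kwargs) -> "FCMNFC":
        """Build from a :class:`GaitDataset` (signals are columns)."""
        kwargs.setdefault("class_codes", dict(data.class_codes))
        return cls(data.labels, data.signals.T, **kwargs)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, label_col: str = "gait", **kwargs
    ) -> "FCMNFC":
        """Build from a DataFrame with feature columns + a label column."""
        y = df[label_col].tolist()
        X = df.drop(columns=[label_col]).to_numpy(dtype=float)
        return cls(y, X, **kwargs)

    def fit(
        self,
        epochs: int = 50,
        learning_rate: float = 0.01,
        ridge: float = 1e-8,
        first_order: bool = True,
        seed: Optional[int] = None,
        fcm_epsilon: float = 1e-5,
        fcm_max_iter: int = 200,
    ) -> "FCMNFCResults":
        """Run FCM seeding plus hybrid LSE/backprop learning."""
        fcm_config = FCMConfig(
            c=self.n_rules, m=self.fuzzifier, epsilon=fcm_epsilon,
            max_iter=fcm_max_iter, seed=seed,
        )
        train_config = TrainConfig(
            epochs=epochs, learning_rate=learning_rate, ridge=ridge,
            first_order=first_order, seed=seed,
        )
        rulebase = tsk.fit(
            self.exog.T, self.endog, fcm_config, train_config,
            class_codes=self.class_codes,
        )
        return FCMNFCResults(self, rulebase, fcm_config, train_config)


class FCMNFCResults:
    """Fitted rule base with prediction, diagnostics and serialisation."""

    def __init__(
        self,
        model: Optional[FCMNFC],
        rulebase: RuleBase,
        fcm_config: Optional[FCMConfig] = None,
        train_config: Optional[TrainConfig] = None,
    ):
        self.model = model
        self.rulebase = rulebase
        self.fcm_config = fcm_config
        self.train_config = train_config

    # ------------------------------------------------------------------
    @property
    def n_rules(self) -> int:
        return self.rulebase.n_rules

    @property
    def training_log(self) -> list[dict]:
        return self.rulebase.training_log

    @property
    def training_sse(self) -> float:
        return float(self.training_log[-1]["sse"]) if self.training_log \
            else float("nan")

    def predict_value(self, exog: np.ndarray) -> np.ndarray:
        """Raw scalar inference outputs for feature rows (nobs, k)."""
        X = np.atleast_2d(np.asarray(exog, dtype=float))
        return tsk.infer_batch(self.rulebase, X.T)

    def predict(self, exog: np.ndarray) -> list[str]:
        """Decoded gait labels for feature rows (nobs, k)."""
        X = np.atleast_2d(np.asarray(exog, dtype=float))
        return tsk.predict_class_batch(self.rulebase, X.T)

    def accuracy(self, exog: np.ndarray, labels: Sequence[str]) -> float:
        """Percent of rows whose decoded label matches."""
        pred = self.predict(exog)
        hits = sum(p == t for p, t in zip(pred, labels))
        return 100.0 * hits / len(pred)

    # ------------------------------------------------------------------
    def summary(self) -> str:
        """Plain-text fit summary table."""
        rb = self.rulebase
        lines = [
            "FCM-NFC (TSK neuro-fuzzy classifier) results",
            "=" * 52,
            f"{'rules':<28}{rb.n_rules}",
            f"{'input dimension':<28}{rb.input_dim}",
            f"{'classes':<28}"
            + ", ".join(f"{k}={v}" for k, v in rb.class_codes.items()),
        ]
        if self.train_config is not None:
            lines += [
                f"{'epochs':<28}{self.train_config.epochs}",
                f"{'learning rate (initial)':<28}"
                f"{self.train_config.learning_rate}",
                f"{'ridge':<28}{self.train_config.ridge}",
                f"{'consequent order':<28}"
                f"{'first (affine)' if self.train_config.first_order else 'zero (constant)'}",
            ]
        if self.training_log:
            first = self.training_log[0]["sse"]
            last = self.training_log[-1]["sse"]
            lines += [
                f"{'training SSE (epoch 0)':<28}{first:.6g}",
                f"{'training SSE (final)':<28}{last:.6g}",
            ]
        lines.append("=" * 52)
        return "\n".join(lines)

    def plot_training(self, ax=None):
        """Training SSE per epoch."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        log = [e for e in self.training_log if e["epoch"] != "final"]
        ax.plot([e["epoch"] for e in log], [e["sse"] for e in log],
                marker="o")
        ax.set_xlabel("epoch")
        ax.set_ylabel("training SSE")
        return ax

    # ------------------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """JSON serialisation; a reload predicts identically."""
        self.rulebase.save(path)

    @classmethod
    def load(cls, path: str | Path) -> "FCMNFCResults":
        return cls(model=None, rulebase=RuleBase.load(path))
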