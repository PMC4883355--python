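"""Takagi-Sugeno-Kang neuro-fuzzy classifier with FCM-seeded rules.

Each rule i has a Gaussian premise per input dimension j,

    A_ji(x_j) = exp(-((x_j - c_ji) / sigma_ji)^2),

a firing strength w_i = prod_j A_ji(x_j) (product t-norm), and a
first-order (affine) consequent f_i(x) = p_i . x + r_i.  Inference is
the firing-strength-weighted average f = sum_i wbar_i f_i with
wbar_i = w_i / sum_k w_k.

Rules are scatter-partitioned: premises start at fuzzy c-means cluster
centers with membership-weighted spreads.  Training is the classic
hybrid scheme: consequents by a global least-squares solve with premises
frozen, premises by full-batch gradient descent on the squared error
with consequents frozen, alternating per epoch.

Class labels are coded 1..4 (walk, sitting trot, rising trot, canter)
and regressed as a single scalar; prediction decodes the inference
output to the nearest code.

Module-level functions operate on a :class:`RuleBase` with the
d x N samples-in-columns convention; the estimator-style front end lives
in :mod:`gaitnfc.model`.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import scipy.linalg

from .dataset import DEFAULT_CLASS_CODES
from .fcm import FCMConfig, FCMResult, fcm_fit

__all__ = ["TSKRule", "RuleBase", "TrainConfig", "init_from_fcm",
           "firing_strengths", "infer", "lse_consequents",
           "bp_premise_step", "fit", "predict_class", "training_sse"]

logger = logging.getLogger(__name__)

_WIDTH_FLOOR_FRACTION = 1e-3  # of each dimension's data range
_WIDTH_FLOOR_ABS = 1e-3       # fallback when a dimension has zero range


@dataclass
class TSKRule:
    """One fuzzy if-then rule: Gaussian premise + affine consequent."""

    center: np.ndarray      # (d,) premise centers c_ji
    width: np.ndarray       # (d,) premise spreads sigma_ji, > 0
    consequent: np.ndarray  # (d+1,): [p_i, r_i], affine coefficients

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float).ravel()
        self.width = np.asarray(self.width, dtype=float).ravel()
        self.consequent = np.asarray(self.consequent, dtype=float).ravel()
        if self.width.shape != self.center.shape:
            raise ValueError("width and center dimensions differ")
        if np.any(self.width <= 0):
            raise ValueError("rule widths must be strictly positive")
        if self.consequent.size != self.center.size + 1:
            raise ValueError("consequent must have input_dim + 1 entries")


@dataclass
class RuleBase:
    """The rule set of a fitted (or initialising) classifier."""

    rules: list[TSKRule]
    input_dim: int
    class_codes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_CODES)
    )
    training_log: list[dict] = field(default_factory=list)
    width_floor: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.rules) < 1:
            raise ValueError("a rule base needs at least one rule")
        for r in self.rules:
            if r.center.size != self.input_dim:
                raise ValueError("rule dimension mismatch")
        if self.width_floor is None:
            self.width_floor = np.full(self.input_dim, _WIDTH_FLOOR_ABS)

    @property
    def n_rules(self) -> int:
        return len(self.rules)

    # convenient stacked views ------------------------------------------
    @property
    def centers(self) -> np.ndarray:
        return np.vstack([r.center for r in self.rules])  # (r, d)

    @property
    def widths(self) -> np.ndarray:
        return np.vstack([r.width for r in self.rules])  # (r, d)

    @property
    def consequents(self) -> np.ndarray:
        return np.vstack([r.consequent for r in self.rules])  # (r, d+1)

    def _set_params(self, centers=None, widths=None, consequents=None):
        for i, r in enumerate(self.rules):
            if centers is not None:
                r.center = centers[i].copy()
            if widths is not None:
                r.width = widths[i].copy()
            if consequents is not None:
                r.consequent = consequents[i].copy()

    # serialisation ------------------------------------------------------
    def to_json_dict(self) -> dict:
        return {
            "input_dim": self.input_dim,
            "class_codes": self.class_codes,
            "rules": [
                {
                    "center": r.center.tolist(),
                    "width": r.width.tolist(),
                    "consequent": r.consequent.tolist(),
                }
                for r in self.rules
            ],
            "training_log": self.training_log,
            "width_floor": np.asarray(self.width_floor).tolist(),
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json_dict(), indent=1))

    @classmethod
    def from_json_dict(cls, d: dict) -> "RuleBase":
        return cls(
            rules=[
                TSKRule(
                    center=np.array(r["center"]),
                    width=np.array(r["width"]),
                    consequent=np.array(r["consequent"]),
                )
                for r in d["rules"]
            ],
            input_dim=int(d["input_dim"]),
            class_codes={k: int(v) for k, v in d["class_codes"].items()},
            training_log=list(d.get("training_log", [])),
            width_floor=np.array(d["width_floor"]),
        )

    @classmethod
    def load(cls, path: str | Path) -> "RuleBase":
        return cls.from_json_dict(json.loads(Path(path).read_text()))


@dataclass
class TrainConfig:
    """Hybrid-learning schedule.

    epochs : full LSE + backprop alternations (0 = single LSE only).
    learning_rate : gradient step for premise centers/widths; halved
        whenever a step would increase the training SSE.
    ridge : Tikhonov regulariser for the consequent least-squares solve.
    first_order : affine consequents if True, constants if False.
    seed : randomness seed (FCM initialisation).
    """

    epochs: int = 50
    learning_rate: float = 0.01
    ridge: float = 1e-8
    first_order: bool = True
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.epochs > 0 and not self.learning_rate > 0:
            raise ValueError("learning_rate must be > 0 when training")
        if self.ridge < 0:
            raise ValueError("ridge must be >= 0")


# ---------------------------------------------------------------------------
# rule construction

def init_from_fcm(
    fcm_result: FCMResult,
    X: np.ndarray,
    class_codes: Optional[dict[str, int]] = None,
) -> RuleBase:
    """One rule per FCM cluster: each center becomes a premise prototype.

    Rule widths are the membership-weighted standard deviation of each
    dimension around the cluster center (weights u_ij^m with m = 2,
    matching the center update), floored at 1e-3 of the dimension's data
    range so coincident clusters keep positive spread.  Consequents start
    at zero; the first LSE pass sets them.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))  # (d, N)
    d, n = X.shape
    C = np.atleast_2d(fcm_result.centers)  # (c, d)
    U = np.atleast_2d(fcm_result.membership)  # (c, N)
    if C.shape[1] != d or U.shape[1] != n:
        raise ValueError("FCM result does not match the data shape")
    data_range = X.max(axis=1) - X.min(axis=1)  # (d,)
    floor = np.where(
        data_range > 0, _WIDTH_FLOOR_FRACTION * data_range, _WIDTH_FLOOR_ABS
    )
    W = U**2.0
    rules = []
    floored = 0
    for j in range(C.shape[0]):
        w = W[j]
        diff2 = (X - C[j][:, None]) ** 2  # (d, N)
        var = (diff2 * w).sum(axis=1) / w.sum()
        width = np.sqrt(var)
        below = width < floor
        floored += int(below.sum())
        width = np.where(below, floor, width)
        rules.append(
            TSKRule(center=C[j], width=width, consequent=np.zeros(d + 1))
        )
    if floored:
        logger.warning(
            "width floor applied to %d rule dimensions "
            "(zero/near-zero spread)", floored
        )
    return RuleBase(
        rules=rules,
        input_dim=d,
        class_codes=dict(class_codes or DEFAULT_CLASS_CODES),
        width_floor=floor,
    )


# ---------------------------------------------------------------------------
# inference

def _log_firing(model: RuleBase, Xc: np.ndarray) -> np.ndarray:
    """log w_i for each sample: (N, r).  Xc is (N, d)."""
    C = model.centers  # (r, d)
    S = model.widths   # (r, d)
    z = (Xc[:, None, :] - C[None, :, :]) / S[None, :, :]
    return -(z**2).sum(axis=2)


def _firing_batch(model: RuleBase, Xc: np.ndarray):
    """Scaled firing strengths and normalised strengths, (N, r) each.

    The returned w is exp(log w - max log w) per sample; ratios (and
    hence wbar and all gradient terms) are unchanged by the scaling,
    which prevents underflow of the product of many Gaussian factors.
    """
    logw = _log_firing(model, Xc)
    shift = logw.max(axis=1, keepdims=True)
    w = np.exp(logw - shift)
    tot = w.sum(axis=1, keepdims=True)
    bad = ~np.isfinite(tot.ravel()) | (tot.ravel() <= 0.0)
    if bad.any():
        logger.warning(
            "all firing strengths vanished for %d sample(s); "
            "using uniform rule weights", int(bad.sum())
        )
        w[bad] = 1.0
        tot = w.sum(axis=1, keepdims=True)
    return w, w / tot


def firing_strengths(
    model: RuleBase, x: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Rule activations for one input: (w, w_norm), each length r.

    w_i is the product over dimensions of the Gaussian memberships
    (so w_i = 1 exactly at a rule's center); w_norm sums to 1.  If every
    w_i underflows to zero the normalised weights fall back to uniform.
    """
    x = np.asarray(x, dtype=float).ravel()
    logw = _log_firing(model, x[None, :])[0]
    w = np.exp(logw)
    tot = w.sum()
    if not np.isfinite(tot) or tot <= 0.0:
        logger.warning("all firing strengths vanished; uniform fallback")
        w_norm = np.full(model.n_rules, 1.0 / model.n_rules)
    else:
        w_norm = w / tot
    return w, w_norm


def _consequent_values(model: RuleBase, Xc: np.ndarray) -> np.ndarray:
    """f_i(x) for all samples and rules: (N, r)."""
    P = model.consequents  # (r, d+1)
    return Xc @ P[:, :-1].T + P[:, -1]


def infer_batch(model: RuleBase, X: np.ndarray) -> np.ndarray:
    """Weighted-average inference for all columns of a d x N matrix."""
    Xc = np.atleast_2d(np.asarray(X, dtype=float)).T  # (N, d)
    _, wbar = _firing_batch(model, Xc)
    return (wbar * _consequent_values(model, Xc)).sum(axis=1)


def infer(model: RuleBase, x: np.ndarray) -> float:
    """Crisp inference output f(x) = sum_i wbar_i f_i(x) for one input."""
    x = np.asarray(x, dtype=float).ravel()
    return float(infer_batch(model, x[:, None])[0])


def predict_class(model: RuleBase, x: np.ndarray) -> str:
    """Decode the inference output to a gait label.

    Nearest registered class code wins; exact midpoints go to the lower
    code; outputs beyond the code range clip to the extreme codes.
    """
    f = infer(model, x)
    codes = sorted(model.class_codes.values())
    dists = [abs(f - c) for c in codes]
    best = codes[int(np.argmin(dists))]  # argmin takes the first = lower tie
    inv = {v: k for k, v in model.class_codes.items()}
    return inv[best]


def predict_class_batch(model: RuleBase, X: np.ndarray) -> list[str]:
    """Vector of gait labels for a d x N input matrix."""
    f = infer_batch(model, X)
    codes = np.array(sorted(model.class_codes.values()))
    idx = np.argmin(np.abs(f[:, None] - codes[None, :]), axis=1)
    inv = {v: k for k, v in model.class_codes.items()}
    return [inv[int(codes[i])] for i in idx]


def training_sse(model: RuleBase, X: np.ndarray, y: np.ndarray) -> float:
    """Sum of squared errors of the inference output against targets."""
    return float(np.sum((infer_batch(model, X) - np.asarray(y, float)) ** 2))


# ---------------------------------------------------------------------------
# hybrid learning

def lse_consequents(
    model: RuleBase,
    X: np.ndarray,
    y: np.ndarray,
    ridge: float = 1e-8,
    first_order: bool = True,
) -> RuleBase:
    """Global least-squares solve for all consequent coefficients.

    With premises frozen the inference output is linear in the stacked
    consequents: the design row for sample x is
    ``[wbar_1 * (x, 1), ..., wbar_r * (x, 1)]``.  A ridge term (or the
    minimum-norm pseudoinverse solution when ridge = 0) handles the
    rank-deficient case, which is the rule rather than the exception
    when r * (d + 1) exceeds N.  Training SSE never increases.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))  # (d, N)
    y = np.asarray(y, dtype=float).ravel()
    Xc = X.T  # (N, d)
    n, d = Xc.shape
    r = model.n_rules
    _, wbar = _firing_batch(model, Xc)  # (N, r)
    if first_order:
        basis = np.concatenate([Xc, np.ones((n, 1))], axis=1)  # (N, d+1)
    else:
        basis = np.ones((n, 1))
    k = basis.shape[1]
    # design (N, r*k): rule-major blocks
    Phi = (wbar[:, :, None] * basis[:, None, :]).reshape(n, r * k)
    p = r * k
    if n < p:
        # dual (kernel) form: with many more unknowns than samples the
        # ridge/minimum-norm solution is theta = Phi' (Phi Phi' + l I)^-1 y,
        # an N x N solve instead of an SVD of the p-column design
        G = Phi @ Phi.T
        if ridge > 0:
            alpha = scipy.linalg.solve(
                G + ridge * np.eye(n), y, assume_a="pos"
            )
        else:
            logger.warning(
                "rank-deficient consequent design; minimum-norm solution"
            )
            alpha, *_ = scipy.linalg.lstsq(G, y)
        theta = Phi.T @ alpha
    else:
        if ridge > 0:
            A = np.vstack([Phi, np.sqrt(ridge) * np.eye(p)])
            b = np.concatenate([y, np.zeros(p)])
        else:
            A, b = Phi, y
            if np.linalg.matrix_rank(Phi) < p:
                logger.warning(
                    "rank-deficient consequent design; minimum-norm solution"
                )
        theta, *_ = scipy.linalg.lstsq(A, b)
    theta = theta.reshape(r, k)
    consequents = np.zeros((r, d + 1))
    if first_order:
        consequents[:] = theta
    else:
        consequents[:, -1] = theta[:, 0]
    model._set_params(consequents=consequents)
    return model


def bp_premise_step(
    model: RuleBase,
    X: np.ndarray,
    y: np.ndarray,
    learning_rate: float,
) -> RuleBase:
    """One full-batch gradient-descent step on the premise parameters.

    Analytic gradients of E = sum_n (f(x_n) - y_n)^2 with respect to
    every center c_ji and width sigma_ji, propagated through the
    normalised weighted average.  Widths are re-floored at their
    positive minimum after the step.  A non-finite gradient skips the
    step.
    """
    grad_C, grad_S = premise_gradients(model, X, y)
    if not (np.all(np.isfinite(grad_C)) and np.all(np.isfinite(grad_S))):
        logger.error("non-finite premise gradient; step skipped")
        return model
    C = model.centers - learning_rate * grad_C
    S = model.widths - learning_rate * grad_S
    S = np.maximum(S, np.asarray(model.width_floor)[None, :])
    model._set_params(centers=C, widths=S)
    return model


def premise_gradients(
    model: RuleBase, X: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """dE/dc_ji and dE/dsigma_ji, each (r, d)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    Xc = X.T  # (N, d)
    C = model.centers
    S = model.widths
    w, wbar = _firing_batch(model, Xc)  # (N, r), scaled w
    fi = _consequent_values(model, Xc)  # (N, r)
    f = (wbar * fi).sum(axis=1)  # (N,)
    err = f - y
    # dE/d(log w_i) = 2 err (f_i - f) wbar_i   (scale-invariant in w)
    g = 2.0 * err[:, None] * (fi - f[:, None]) * wbar  # (N, r)
    diff = Xc[:, None, :] - C[None, :, :]  # (N, r, d)
    grad_C = np.einsum("nr,nrd->rd", g, 2.0 * diff / S[None, :, :] ** 2)
    grad_S = np.einsum("nr,nrd->rd", g, 2.0 * diff**2 / S[None, :, :] ** 3)
    return grad_C, grad_S


def fit(
    X: np.ndarray,
    y: np.ndarray,
    fcm_config: FCMConfig,
    train_config: TrainConfig = TrainConfig(),
    class_codes: Optional[dict[str, int]] = None,
) -> RuleBase:
    """Full hybrid-learning pipeline on d x N data with coded targets.

    FCM scatter partitioning seeds the rules, then each epoch runs a
    global LSE for consequents followed by one backprop step on the
    premises; a final LSE re-optimises the consequents for the adapted
    premises.  The learning rate halves whenever a premise step would
    raise the training SSE (the step is retried; after 10 halvings it is
    skipped for that epoch).  Deterministic for fixed seeds.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    codes = dict(class_codes or DEFAULT_CLASS_CODES)
    if len(np.unique(y)) < 2:
        warnings.warn(
            "targets contain a single class; the model fits a constant",
            stacklevel=2,
        )
    fcm_result = fcm_fit(X, fcm_config)
    model = init_from_fcm(fcm_result, X, class_codes=codes)
    lse_consequents(model, X, y, ridge=train_config.ridge,
                    first_order=train_config.first_order)
    sse = training_sse(model, X, y)
    model.training_log.append({"epoch": 0, "sse": sse,
                               "lr": train_config.learning_rate})
    lr = train_config.learning_rate
    for epoch in range(1, train_config.epochs + 1):
        stepped = False
        for _ in range(10):
            C0, S0 = model.centers, model.widths
            bp_premise_step(model, X, y, learning_rate=lr)
            lse_consequents(model, X, y, ridge=train_config.ridge,
                            first_order=train_config.first_order)
            new_sse = training_sse(model, X, y)
            if new_sse <= sse + 1e-12:
                sse = new_sse
                stepped = True
                break
            model._set_params(centers=C0, widths=S0)
            lse_consequents(model, X, y, ridge=train_config.ridge,
                            first_order=train_config.first_order)
            lr *= 0.5
        if not stepped:
            logger.info("epoch %d: no descent step found; premises frozen",
                        epoch)
            sse = training_sse(model, X, y)
        model.training_log.append({"epoch": epoch, "sse": sse, "lr": lr})
    lse_consequents(model, X, y, ridge=train_config.ridge,
                    first_order=train_config.first_order)
    model.training_log.append(
        {"epoch": "final", "sse": training_sse(model, X, y), "lr": lr}
    )
    return model
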