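"""Fuzzy c-means clustering.

Each point belongs to every cluster with a membership grade in [0, 1],
the grades summing to one per point.  Fitting alternates two closed-form
updates that minimise the fuzzy objective

    J_m = sum_i sum_j u_ij^m ||x_i - c_j||^2,    m > 1,

with the centers as membership-weighted means and the memberships as
inverse-distance ratios raised to 2/(m-1).  Iteration stops when the
largest membership change falls below a threshold.  The fuzzifier m
controls softness: m -> 1 approaches hard k-means.

Here FCM supplies scatter partitioning for the neuro-fuzzy classifier:
each center becomes the premise prototype of one fuzzy rule, so the rule
count equals the cluster count and never grows exponentially with the
input dimension as grid partitioning does.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial.distance import cdist

__all__ = ["FCMConfig", "FCMResult", "init_membership", "fcm_objective",
           "fcm_fit"]


@dataclass
class FCMConfig:
    """Fitting configuration.

    Parameters
    ----------
    c : int
        Number of clusters (= number of fuzzy rules downstream).
    m : float
        Fuzzifier, > 1.  Default 2, the universal choice.
    epsilon : float
        Termination threshold on the max absolute membership change,
        in (0, 1).
    max_iter : int
        Iteration cap.
    seed : int or None
        Seed for the random membership initialisation.
    """

    c: int
    m: float = 2.0
    epsilon: float = 1e-5
    max_iter: int = 200
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.c < 1:
            raise ValueError("cluster count c must be >= 1")
        if not self.m > 1:
            raise ValueError("fuzzifier m must be > 1")
        if not 0 < self.epsilon < 1:
            raise ValueError("epsilon must be in (0, 1)")


@dataclass
class FCMResult:
    """Fitted centers, memberships and the objective trace.

    Attributes
    ----------
    centers : ndarray, shape (c, d)
    membership : ndarray, shape (c, N)
        Column-stochastic: each point's memberships sum to 1.
    objective_trace : list of float
        J_m after each center/membership update; non-increasing.
    iterations : int
    """

    centers: np.ndarray
    membership: np.ndarray
    objective_trace: list[float] = field(default_factory=list)
    iterations: int = 0

    def to_json_dict(self) -> dict:
        return {
            "centers": self.centers.tolist(),
            "membership": self.membership.tolist(),
            "objective_trace": list(self.objective_trace),
            "iterations": self.iterations,
        }


def init_membership(
    n_points: int, c: int, seed: Optional[int] = None
) -> np.ndarray:
    """Random membership matrix (c x n_points), each column summing to 1.

    Entries are uniform random then normalised per point; reproducible
    for a fixed seed.  With a single cluster every membership is 1.
    """
    if c < 1:
        raise ValueError("c must be >= 1")
    if c > n_points:
        raise ValueError(f"c={c} clusters exceed n_points={n_points}")
    rng = np.random.default_rng(seed)
    U = rng.random((c, n_points))
    return U / U.sum(axis=0, keepdims=True)


def fcm_objective(
    X: np.ndarray, U: np.ndarray, C: np.ndarray, m: float
) -> float:
    """Fuzzy objective J_m = sum_ij u_ij^m ||x_i - c_j||^2.

    ``X`` is d x N (samples in columns), ``U`` is c x N, ``C`` is c x d.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    U = np.atleast_2d(np.asarray(U, dtype=float))
    C = np.atleast_2d(np.asarray(C, dtype=float))
    if X.shape[1] != U.shape[1] or U.shape[0] != C.shape[0] \
            or C.shape[1] != X.shape[0]:
        raise ValueError(
            f"inconsistent shapes X{X.shape}, U{U.shape}, C{C.shape}"
        )
    d2 = cdist(C, X.T, metric="sqeuclidean")  # (c, N)
    return float(np.sum(U**m * d2))


def _update_centers(X: np.ndarray, U: np.ndarray, m: float) -> np.ndarray:
    W = U**m  # (c, N)
    return (W @ X.T) / W.sum(axis=1, keepdims=True)


def _update_membership(X: np.ndarray, C: np.ndarray, m: float) -> np.ndarray:
    d2 = cdist(C, X.T, metric="sqeuclidean")  # (c, N)
    zero = d2 <= 0.0
    # log-domain ratio keeps small fuzzifiers (large 1/(m-1)) from
    # overflowing before normalisation
    with np.errstate(divide="ignore", invalid="ignore"):
        log_inv = (-1.0 / (m - 1.0)) * np.log(d2)
        log_inv -= log_inv.max(axis=0, keepdims=True)
    inv = np.exp(log_inv)
    U = inv / inv.sum(axis=0, keepdims=True)
    # point coincident with a center: full membership to the first such
    coincident = zero.any(axis=0)
    if coincident.any():
        for i in np.nonzero(coincident)[0]:
            U[:, i] = 0.0
            U[np.argmax(zero[:, i]), i] = 1.0
    return U


def fcm_fit(X: np.ndarray, config: FCMConfig) -> FCMResult:
    """Alternating-optimisation FCM fit.

    ``X`` is d x N with samples in columns.  Starting from a random
    membership matrix, centers and memberships are updated in turn until
    ``max_ij |u_ij^(k+1) - u_ij^(k)| < epsilon`` or the iteration cap.

    With ``c=1`` the single center is exactly the arithmetic mean of the
    points and all memberships are 1.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if not np.all(np.isfinite(X)):
        raise ValueError("data contains non-finite values")
    n = X.shape[1]
    if n < config.c:
        raise ValueError(f"c={config.c} clusters exceed N={n} points")
    U = init_membership(n, config.c, seed=config.seed)
    trace: list[float] = []
    iterations = 0
    for k in range(config.max_iter):
        C = _update_centers(X, U, config.m)
        U_new = _update_membership(X, C, config.m)
        trace.append(fcm_objective(X, U_new, C, config.m))
        delta = float(np.max(np.abs(U_new - U)))
        U = U_new
        iterations = k + 1
        if delta < config.epsilon:
            break
    C = _update_centers(X, U, config.m)
    return FCMResult(
        centers=C, membership=U, objective_trace=trace, iterations=iterations
    )
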