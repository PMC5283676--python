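"""Ordering-conditional Gaussian likelihood and its closed-form maximizer.

Given a causal ordering o, the log-likelihood of the interventional Gaussian
model decomposes over target nodes j: each node contributes Gaussian
residual terms over the experiments K_j in which it was not intervened.
Profiling out the mean reduces the weight fit to one least-squares problem
per target node (regression of the centered target column on the centered
columns of its ordering-predecessors over K_j); the joint system over all
p(p-1)/2 weights is block-diagonal across targets, so the per-node solves are
mathematically identical to the joint solve.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .dag_model import ExperimentSet, _as_order
from .exceptions import DegenerateNodeError, ModelError, NumericalError, ParameterError

__all__ = [
    "CenteredData",
    "MLEResult",
    "OrderingLikelihood",
    "center_measurements",
    "fit_weights",
    "fit_means",
    "fit_variances",
    "log_likelihood",
    "max_log_likelihood",
    "total_effects",
]

_LOG_2PI = float(np.log(2.0 * np.pi))

#: Default floor applied to fitted standard deviations so the likelihood stays
#: finite on (near-)noiseless data.
SIGMA_FLOOR = 1e-8

#: Default ridge added to a singular predecessor Gram block before giving up.
RIDGE = 1e-10


@dataclass(frozen=True)
class CenteredData:
    """Measurements centered over the experiments without an intervention on node j."""

    Y: np.ndarray  # (N_j, p) rows y^{k,j}
    K: np.ndarray  # indices of the contributing experiments
    node: int


@dataclass(frozen=True)
class MLEResult:
    """Closed-form MLE under a fixed ordering, expressed in original node labels."""

    W_hat: np.ndarray
    m_hat: np.ndarray
    sigma_hat: np.ndarray
    ell_max: float
    ordering: np.ndarray


def center_measurements(data: ExperimentSet, j: int) -> CenteredData:
    """Center all columns over K_j, the experiments with no intervention on j."""
    K = data.K(j)
    if K.size == 0:
        raise DegenerateNodeError(f"node {j} is intervened in every experiment")
    Xk = data.X[K]
    return CenteredData(Y=Xk - Xk.mean(axis=0), K=K, node=j)


def _solve_block(G: np.ndarray, P: np.ndarray, j: int, ridge: float) -> np.ndarray:
    """Solve the predecessor normal equations G[P,P] w = G[P,j] with ridge fallback."""
    A = G[np.ix_(P, P)]
    b = G[P, j]
    try:
        return np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        pass
    try:
        return np.linalg.solve(A + ridge * np.eye(len(P)), b)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - pathological
        raise NumericalError(f"singular predecessor system for node {j}") from exc


class OrderingLikelihood:
    """Per-dataset engine for repeated ordering-conditional MLE evaluations.

    Precomputes, once per dataset, the per-target-node centered Gram matrices
    and column means over K_j; every subsequent ordering costs p small linear
    solves. Used by the Metropolis samplers, the exhaustive enumerator and the
    benchmark, where thousands of orderings are scored against one dataset.
    """

    def __init__(
        self,
        data: ExperimentSet,
        *,
        sigma_floor: float = SIGMA_FLOOR,
        ridge: float = RIDGE,
        require_min_nj: int = 2,
    ) -> None:
        self.data = data
        self.p = data.p
        self.sigma_floor = float(sigma_floor)
        self.ridge = float(ridge)
        self._n = np.zeros(self.p, dtype=np.intp)
        self._mu = np.zeros((self.p, self.p))
        self._G = np.zeros((self.p, self.p, self.p))
        for j in range(self.p):
            K = data.K(j)
            if K.size < require_min_nj:
                raise DegenerateNodeError(
                    f"node {j} retains only {K.size} non-intervened experiments"
                )
            Xk = data.X[K]
            mu = Xk.mean(axis=0)
            Xc = Xk - mu
            self._n[j] = K.size
            self._mu[j] = mu
            self._G[j] = Xc.T @ Xc

    def _node_terms(self, order: np.ndarray):
        """Yield (position, node, predecessors, weights, rss) along the ordering."""
        for b, j in enumerate(order):
            P = order[:b]
            G = self._G[j]
            if b == 0:
                w = np.empty(0)
                rss = G[j, j]
            else:
                w = _solve_block(G, P, j, self.ridge)
                rss = G[j, j] - G[j, P] @ w
            yield b, j, P, w, max(float(rss), 0.0)

    def ell_max(self, order: Sequence[int]) -> float:
        """Maximized log-likelihood of the model under the given ordering."""
        order = _as_order(order, self.p)
        ell = 0.0
        for _, j, _, _, rss in self._node_terms(order):
            n = self._n[j]
            sigma = max(np.sqrt(rss / n), self.sigma_floor)
            ell += -0.5 * n * _LOG_2PI - n * np.log(sigma) - rss / (2.0 * sigma * sigma)
        return float(ell)

    def fit(self, order: Sequence[int]) -> MLEResult:
        """Full closed-form MLE (weights, means, sds, maximized log-likelihood)."""
        order = _as_order(order, self.p)
        W = np.zeros((self.p, self.p))
        m = np.zeros(self.p)
        sig = np.zeros(self.p)
        ell = 0.0
        for _, j, P, w, rss in self._node_terms(order):
            W[P, j] = w
            n = self._n[j]
            m[j] = self._mu[j, j] - self._mu[j] @ W[:, j]
            sigma = max(np.sqrt(rss / n), self.sigma_floor)
            sig[j] = sigma
            ell += -0.5 * n * _LOG_2PI - n * np.log(sigma) - rss / (2.0 * sigma * sigma)
        return MLEResult(W_hat=W, m_hat=m, sigma_hat=sig, ell_max=float(ell), ordering=order)


def fit_weights(data: ExperimentSet, ordering: Sequence[int], *, ridge: float = RIDGE) -> np.ndarray:
    """Weight MLE under a fixed ordering, in original node labels.

    For the target at ordering position b, regresses the centered target
    column on the centered columns of the positions before b, over K_j.
    """
    order = _as_order(ordering, data.p)
    W = np.zeros((data.p, data.p))
    for b, j in enumerate(order):
        if b == 0:
            continue
        cd = center_measurements(data, j)
        P = order[:b]
        G = cd.Y.T @ cd.Y
        W[P, j] = _solve_block(G, P, j, ridge)
    return W


def fit_means(data: ExperimentSet, ordering: Sequence[int], W_hat: np.ndarray) -> np.ndarray:
    """Mean MLE: K_j-average of the weight-adjusted target column."""
    _as_order(ordering, data.p)
    m = np.zeros(data.p)
    for j in range(data.p):
        K = data.K(j)
        if K.size == 0:
            raise DegenerateNodeError(f"node {j} is intervened in every experiment")
        Xk = data.X[K]
        m[j] = np.mean(Xk[:, j] - Xk @ W_hat[:, j])
    return m


def fit_variances(
    data: ExperimentSet,
    ordering: Sequence[int],
    W_hat: np.ndarray,
    *,
    sigma_floor: float = SIGMA_FLOOR,
) -> np.ndarray:
    """Standard-deviation MLE: root mean squared centered residual over K_j, floored."""
    _as_order(ordering, data.p)
    sig = np.zeros(data.p)
    for j in range(data.p):
        cd = center_measurements(data, j)
        resid = cd.Y[:, j] - cd.Y @ W_hat[:, j]
        sig[j] = max(np.sqrt(np.mean(resid**2)), sigma_floor)
    return sig


def log_likelihood(
    data: ExperimentSet, m: np.ndarray, sigma: np.ndarray, W: np.ndarray
) -> float:
    """Log-likelihood of the interventional Gaussian model at given parameters.

    Node j contributes only over K_j: experiments with an intervention on j
    carry no information about node j's parameters.
    """
    m = np.asarray(m, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    W = np.asarray(W, dtype=float)
    ell = 0.0
    for j in range(data.p):
        K = data.K(j)
        n = K.size
        if n == 0:
            continue
        if sigma[j] <= 0:
            raise ParameterError(f"sigma[{j}] must be positive (node has {n} experiments)")
        Xk = data.X[K]
        resid = Xk[:, j] - Xk @ W[:, j] - m[j]
        ell += (
            -0.5 * n * _LOG_2PI
            - n * np.log(sigma[j])
            - 0.5 * np.sum(resid**2) / sigma[j] ** 2
        )
    return float(ell)


def max_log_likelihood(
    data: ExperimentSet,
    ordering: Sequence[int],
    *,
    sigma_floor: float = SIGMA_FLOOR,
    ridge: float = RIDGE,
) -> MLEResult:
    """Closed-form maximum-likelihood fit under a fixed causal ordering."""
    engine = OrderingLikelihood(data, sigma_floor=sigma_floor, ridge=ridge)
    return engine.fit(ordering)


def total_effects(W: np.ndarray, *, tol: float = 1e-9) -> np.ndarray:
    """Total (direct plus mediated) causal effects L = (I - W)^{-1}.

    Requires W nilpotent (some permutation is strictly upper triangular), in
    which case the inverse equals the finite path sum I + W + ... + W^{p-1}.
    """
    W = np.asarray(W, dtype=float)
    p = W.shape[0]
    if W.shape != (p, p):
        raise ModelError("W must be square")
    scale = max(np.abs(W).max(), 1.0)
    if np.abs(np.linalg.matrix_power(W, p)).max() > tol * scale**p:
        raise ModelError("W is not nilpotent: the weight matrix contains a cycle")
    return np.linalg.inv(np.eye(p) - W)
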