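"""Linear Gaussian DAG model, random ensemble generator, and intervention machinery.

The generative model places a Gaussian variable on every node j of a DAG:

    X_j = m_j + sum_{i in parents(j)} w_{i,j} X_i + eps_j,   eps_j ~ N(0, sigma_j^2)

where nodes are visited in a causal (topological) order. An *intervention*
clamps a node to a fixed value (0 for a knock-out); the clamped value still
feeds the node's descendants when an experiment is simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .exceptions import ModelError, ParameterError

__all__ = [
    "CausalDAG",
    "ExperimentSet",
    "Interventions",
    "generate_random_dag",
    "assign_systematic_interventions",
    "simulate_experiments",
]

#: One intervention set per experiment: node index -> clamp value.
Interventions = Sequence[Mapping[int, float]]


def _as_order(order: Sequence[int], p: int) -> np.ndarray:
    o = np.asarray(order, dtype=np.intp)
    if o.shape != (p,) or not np.array_equal(np.sort(o), np.arange(p)):
        raise ParameterError(f"ordering must be a permutation of 0..{p - 1}, got {order!r}")
    return o


@dataclass(frozen=True)
class CausalDAG:
    """A linear Gaussian DAG: weights ``W``, baseline means ``m``, baseline sds ``sigma``.

    ``W[i, j]`` is the direct causal effect of node ``i`` on node ``j``.
    ``gen_order`` is a permutation under which ``W`` is strictly upper
    triangular (the causal order used to generate data).
    """

    W: np.ndarray
    m: np.ndarray
    sigma: np.ndarray
    gen_order: np.ndarray
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=float)
        m = np.asarray(self.m, dtype=float)
        sigma = np.asarray(self.sigma, dtype=float)
        p = W.shape[0]
        if W.shape != (p, p):
            raise ModelError(f"W must be square, got shape {W.shape}")
        if m.shape != (p,) or sigma.shape != (p,):
            raise ModelError("m and sigma must be length-p vectors")
        if np.any(sigma < 0):
            raise ModelError("sigma entries must be non-negative")
        order = _as_order(self.gen_order, p)
        Wp = W[np.ix_(order, order)]
        if np.any(np.tril(Wp) != 0.0):
            raise ModelError("W permuted by gen_order is not strictly upper triangular")
        labels = tuple(self.labels) if self.labels else tuple(f"n{i}" for i in range(p))
        if len(labels) != p:
            raise ModelError("label count must match node count")
        object.__setattr__(self, "W", W)
        object.__setattr__(self, "m", m)
        object.__setattr__(self, "sigma", sigma)
        object.__setattr__(self, "gen_order", order)
        object.__setattr__(self, "labels", labels)

    @property
    def p(self) -> int:
        return self.W.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(self.W))


@dataclass(frozen=True)
class ExperimentSet:
    """N experiments over p nodes: measurement matrix ``X`` plus intervention sets.

    ``interventions[k]`` maps intervened node indices to their clamp values for
    experiment ``k``. Derived per node j: ``K(j)`` — the experiments with no
    intervention on j — and ``N_j = |K(j)|``.
    """

    X: np.ndarray
    interventions: tuple[Mapping[int, float], ...]

    def __post_init__(self) -> None:
        X = np.atleast_2d(np.asarray(self.X, dtype=float))
        interventions = tuple(dict(J) for J in self.interventions)
        if len(interventions) != X.shape[0]:
            raise ParameterError(
                f"{len(interventions)} intervention sets for {X.shape[0]} experiments"
            )
        mask = np.zeros(X.shape, dtype=bool)
        for k, J in enumerate(interventions):
            for j, v in J.items():
                if not 0 <= j < X.shape[1]:
                    raise ParameterError(f"intervention on unknown node {j} in experiment {k}")
                if X[k, j] != v:
                    raise ParameterError(
                        f"experiment {k}: X[{k},{j}]={X[k, j]} does not equal clamp value {v}"
                    )
                mask[k, j] = True
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "interventions", interventions)
        object.__setattr__(self, "_mask", mask)

    @property
    def N(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def intervened_mask(self) -> np.ndarray:
        """Boolean (N, p) matrix: True where the node was clamped."""
        return self._mask  # type: ignore[attr-defined]

    def K(self, j: int) -> np.ndarray:
        """Indices of experiments with no intervention on node ``j``."""
        return np.flatnonzero(~self.intervened_mask[:, j])

    @property
    def N_j(self) -> np.ndarray:
        """Per-node counts of non-intervened experiments."""
        return (~self.intervened_mask).sum(axis=0)

    def subset(self, nodes: Sequence[int], exclude_external_interventions: bool = False) -> "ExperimentSet":
        """Restrict to the given node columns (in the given order).

        With ``exclude_external_interventions`` only experiments whose
        intervention set is contained in ``nodes`` are retained; otherwise all
        experiments are kept and interventions on dropped nodes are discarded
        from the annotation (their influence on the retained columns remains
        in the data, which is the point of the flag).
        """
        nodes = list(nodes)
        if len(set(nodes)) != len(nodes):
            raise ParameterError("subset nodes must be distinct")
        pos = {j: a for a, j in enumerate(nodes)}
        keep = []
        new_interv = []
        node_set = set(nodes)
        for k, J in enumerate(self.interventions):
            if exclude_external_interventions and not set(J) <= node_set:
                continue
            keep.append(k)
            new_interv.append({pos[j]: v for j, v in J.items() if j in node_set})
        return ExperimentSet(self.X[np.ix_(keep, nodes)], tuple(new_interv))


def generate_random_dag(
    p: int,
    q: float,
    *,
    weight_lo: float = 0.4,
    weight_hi: float = 1.0,
    m_value: float = 0.5,
    sigma_lo: float = 0.01,
    sigma_hi: float = 0.1,
    rng: np.random.Generator,
    labels: Sequence[str] = (),
) -> CausalDAG:
    """Draw one DAG from the random ensemble.

    Every pair i < j (in the identity generating order) independently receives
    an edge with probability ``q``; edge weights are uniform in magnitude on
    ``[weight_lo, weight_hi]`` with a random sign, so nonzero weights are well
    separated from zero. Baseline means are constant ``m_value``; baseline
    standard deviations are uniform on ``[sigma_lo, sigma_hi]``.
    """
    if p < 2:
        raise ParameterError("p must be at least 2")
    if not 0.0 <= q <= 1.0:
        raise ParameterError(f"edge probability q={q} outside [0, 1]")
    if not 0.0 < weight_lo <= weight_hi:
        raise ParameterError("require 0 < weight_lo <= weight_hi")
    if not 0.0 <= sigma_lo <= sigma_hi:
        raise ParameterError("require 0 <= sigma_lo <= sigma_hi")
    iu = np.triu_indices(p, 1)
    n_pairs = iu[0].size
    present = rng.random(n_pairs) < q
    magnitude = rng.uniform(weight_lo, weight_hi, n_pairs)
    sign = rng.integers(0, 2, n_pairs) * 2 - 1
    W = np.zeros((p, p))
    W[iu] = np.where(present, sign * magnitude, 0.0)
    m = np.full(p, float(m_value))
    sigma = rng.uniform(sigma_lo, sigma_hi, p)
    return CausalDAG(W=W, m=m, sigma=sigma, gen_order=np.arange(p), labels=tuple(labels))


def assign_systematic_interventions(
    p: int, N: int, r: int, clamp: float = 0.0
) -> list[dict[int, float]]:
    """Single-node interventions for the first ``r`` of ``N`` experiments, round-robin.

    Experiment k (0-based, k < r) intervenes on node ``k mod p``, so every node
    is intervened either floor(r/p) or ceil(r/p) times and the counts sum to
    r. The remaining experiments are observational.
    """
    if not 0 <= r <= N:
        raise ParameterError(f"need 0 <= r <= N, got r={r}, N={N}")
    out: list[dict[int, float]] = [{k % p: float(clamp)} for k in range(r)]
    out.extend({} for _ in range(N - r))
    return out


def simulate_experiments(
    dag: CausalDAG, N: int, interventions: Interventions, rng: np.random.Generator
) -> ExperimentSet:
    """Simulate ``N`` experiments from the model, honouring interventions.

    Nodes are visited in ``gen_order``; an intervened node is set to its clamp
    value instead of being sampled, and the clamped value feeds its
    descendants.
    """
    if len(interventions) != N:
        raise ParameterError(f"{len(interventions)} intervention sets for N={N} experiments")
    p = dag.p
    X = np.zeros((N, p))
    clamp_val = np.zeros((N, p))
    clamp_mask = np.zeros((N, p), dtype=bool)
    for k, J in enumerate(interventions):
        for j, v in J.items():
            clamp_mask[k, j] = True
            clamp_val[k, j] = v
    for j in dag.gen_order:
        col = dag.m[j] + X @ dag.W[:, j]
        if dag.sigma[j] > 0:
            col = col + rng.normal(0.0, dag.sigma[j], size=N)
        X[:, j] = np.where(clamp_mask[:, j], clamp_val[:, j], col)
    return ExperimentSet(X=X, interventions=tuple(dict(J) for J in interventions))
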