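"""Pair and triplet Babington-Smith preference tables and ordering scores.

A pair preference pi[i, j] is the probability that node i precedes node j,
estimated by comparing the maximized likelihoods of the two complete two-node
subgraph models (i -> j) and (j -> i) on the data restricted to those
columns. Triplet preferences rho[i, j, k] generalize this to the six
orderings of a three-node complete subgraph. The Babington-Smith score of a
full ordering is the sum of the log preferences of all its internal pairs
(or triples); it serves as a cheap surrogate for the full ordering-conditional
maximum likelihood during Metropolis sampling.

All preference arithmetic is done in log-space; probabilities are clamped to
[1e-300, 1 - 1e-16] before taking logs, since subgraph log-likelihoods at
realistic noise levels reach magnitudes that overflow literal exponentials.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations, permutations
from typing import Sequence

import numpy as np
from scipy.special import expit, log_softmax

from .dag_model import ExperimentSet, _as_order
from .exceptions import DegenerateNodeError, ParameterError
from .likelihood import _LOG_2PI, RIDGE, SIGMA_FLOOR, max_log_likelihood

__all__ = [
    "PairPreferences",
    "TripletPreferences",
    "subgraph_max_loglik",
    "pair_preferences",
    "triplet_preferences",
    "pair_bs_loglik",
    "triplet_bs_loglik",
    "pair_swap_delta",
    "triplet_swap_delta",
]

_P_LO = 1e-300
_P_HI = 1.0 - 1e-16


@dataclass(frozen=True)
class PairPreferences:
    """p x p table pi[i, j] = probability that i precedes j; diagonal unused (NaN)."""

    pi: np.ndarray

    def __post_init__(self) -> None:
        pi = np.asarray(self.pi, dtype=float)
        object.__setattr__(self, "pi", pi)
        with np.errstate(divide="ignore", invalid="ignore"):
            object.__setattr__(self, "_log_pi", np.log(pi))

    @property
    def p(self) -> int:
        return self.pi.shape[0]

    @property
    def log_pi(self) -> np.ndarray:
        return self._log_pi  # type: ignore[attr-defined]


@dataclass(frozen=True)
class TripletPreferences:
    """Dense table rho[i, j, k] = probability that the triple appears in order i, j, k.

    Entries with repeated indices are NaN; for every unordered triple the six
    permutation entries sum to one.
    """

    rho: np.ndarray

    def __post_init__(self) -> None:
        rho = np.asarray(self.rho, dtype=float)
        object.__setattr__(self, "rho", rho)
        with np.errstate(divide="ignore", invalid="ignore"):
            object.__setattr__(self, "_log_rho", np.log(rho))

    @property
    def p(self) -> int:
        return self.rho.shape[0]

    @property
    def log_rho(self) -> np.ndarray:
        return self._log_rho  # type: ignore[attr-defined]


# ---------------------------------------------------------------------------
# Subgraph likelihood machinery
# ---------------------------------------------------------------------------


def subgraph_max_loglik(
    data: ExperimentSet,
    node_sequence: Sequence[int],
    exclude_external_interventions: bool = True,
) -> float:
    """Maximized log-likelihood of the complete DAG on 2 or 3 nodes in the given order.

    With ``exclude_external_interventions`` (the default), experiments that
    intervene on nodes outside the sequence are dropped before fitting.
    """
    seq = list(node_sequence)
    if len(seq) not in (2, 3) or len(set(seq)) != len(seq):
        raise ParameterError(f"node sequence must be 2 or 3 distinct nodes, got {seq!r}")
    sub = data.subset(seq, exclude_external_interventions)
    if np.any(sub.N_j < 2):
        raise DegenerateNodeError(
            f"subgraph {tuple(seq)}: a node retains fewer than 2 experiments"
        )
    return max_log_likelihood(sub, np.arange(len(seq))).ell_max


class _GroupedMoments:
    """Per-dataset sufficient statistics grouped by intervention pattern.

    Experiments sharing the same intervention *node set* are pooled into one
    group carrying its size, column sums and cross-moment matrix. Restricted
    subgraph fits then reduce to summing a handful of group blocks, which
    makes building all O(p^3) triplet preferences tractable.
    """

    def __init__(self, data: ExperimentSet) -> None:
        self.p = data.p
        buckets: dict[frozenset, list[int]] = {}
        for k, J in enumerate(data.interventions):
            buckets.setdefault(frozenset(J), []).append(k)
        self.groups: list[tuple[frozenset, int, np.ndarray, np.ndarray]] = []
        for nodes, rows in buckets.items():
            Xg = data.X[rows]
            self.groups.append((nodes, len(rows), Xg.sum(axis=0), Xg.T @ Xg))

    def target_stats(self, cols: Sequence[int], target_pos: int, exclude: bool):
        """Centered moment matrix over K_target restricted to ``cols``.

        Returns (n, C) where C holds centered second-moment *sums* (not
        divided by n) among ``cols``.
        """
        cols = list(cols)
        node_set = frozenset(cols)
        target = cols[target_pos]
        n = 0
        S = np.zeros(len(cols))
        Q = np.zeros((len(cols), len(cols)))
        ix = np.ix_(cols, cols)
        for nodes, ng, Sg, Qg in self.groups:
            if target in nodes:
                continue
            if exclude and not nodes <= node_set:
                continue
            n += ng
            S += Sg[cols]
            Q += Qg[ix]
        if n < 2:
            raise DegenerateNodeError(
                f"subgraph {tuple(cols)}: node {target} retains {n} experiments"
            )
        return n, Q - np.outer(S, S) / n


def _contrib(C: np.ndarray, n: int, t: int, parents: Sequence[int], sigma_floor: float) -> float:
    """Profile log-likelihood contribution of one target with the given local parents."""
    parents = list(parents)
    if not parents:
        rss = C[t, t]
    elif len(parents) == 1:
        a = parents[0]
        denom = C[a, a] if C[a, a] > 0 else C[a, a] + RIDGE
        w = C[a, t] / denom
        rss = C[t, t] - w * C[a, t]
    else:
        A = C[np.ix_(parents, parents)]
        b = C[parents, t]
        try:
            w = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            w = np.linalg.solve(A + RIDGE * np.eye(len(parents)), b)
        rss = C[t, t] - b @ w
    rss = max(float(rss), 0.0)
    sigma = max(np.sqrt(rss / n), sigma_floor)
    return -0.5 * n * _LOG_2PI - n * np.log(sigma) - rss / (2.0 * sigma * sigma)


def pair_preferences(
    data: ExperimentSet,
    exclude_external_interventions: bool = True,
    *,
    sigma_floor: float = SIGMA_FLOOR,
) -> PairPreferences:
    """Estimate all pair preferences from two-node subgraph likelihoods."""
    gm = _GroupedMoments(data)
    p = data.p
    pi = np.full((p, p), np.nan)
    for i, j in combinations(range(p), 2):
        cols = (i, j)
        n_i, C_i = gm.target_stats(cols, 0, exclude_external_interventions)
        n_j, C_j = gm.target_stats(cols, 1, exclude_external_interventions)
        # ell(i -> j) = f(i | {}) + f(j | {i}); ell(j -> i) = f(j | {}) + f(i | {j})
        ell_ij = _contrib(C_i, n_i, 0, (), sigma_floor) + _contrib(C_j, n_j, 1, (0,), sigma_floor)
        ell_ji = _contrib(C_j, n_j, 1, (), sigma_floor) + _contrib(C_i, n_i, 0, (1,), sigma_floor)
        p_ij = float(np.clip(expit(ell_ij - ell_ji), _P_LO, _P_HI))
        pi[i, j] = p_ij
        pi[j, i] = 1.0 - p_ij
    return PairPreferences(pi=pi)


def triplet_preferences(
    data: ExperimentSet,
    exclude_external_interventions: bool = True,
    *,
    sigma_floor: float = SIGMA_FLOOR,
) -> TripletPreferences:
    """Estimate all triplet preferences from three-node complete-subgraph likelihoods.

    For each unordered triple the six ordered subgraph log-likelihoods are
    soft-max normalized in log-space to yield probabilities summing to one.
    """
    gm = _GroupedMoments(data)
    p = data.p
    rho = np.full((p, p, p), np.nan)
    perms = list(permutations(range(3)))
    for triple in combinations(range(p), 3):
        stats = [gm.target_stats(triple, t, exclude_external_interventions) for t in range(3)]
        # f[t][S] = contribution of local target t with local parent set S
        f = []
        for t in range(3):
            n, C = stats[t]
            others = [u for u in range(3) if u != t]
            f.append(
                {
                    (): _contrib(C, n, t, (), sigma_floor),
                    (others[0],): _contrib(C, n, t, (others[0],), sigma_floor),
                    (others[1],): _contrib(C, n, t, (others[1],), sigma_floor),
                    tuple(others): _contrib(C, n, t, others, sigma_floor),
                }
            )
        ells = np.array(
            [
                f[o1][()] + f[o2][(o1,)] + f[o3][tuple(sorted((o1, o2)))]
                for o1, o2, o3 in perms
            ]
        )
        probs = np.clip(np.exp(log_softmax(ells)), _P_LO, _P_HI)
        for (o1, o2, o3), pr in zip(perms, probs):
            rho[triple[o1], triple[o2], triple[o3]] = pr
    return TripletPreferences(rho=rho)


# ---------------------------------------------------------------------------
# Babington-Smith ordering scores and swap deltas
# ---------------------------------------------------------------------------


@lru_cache(maxsize=32)
def _pair_positions(p: int):
    return np.triu_indices(p, 1)


@lru_cache(maxsize=32)
def _triple_positions(p: int):
    idx = np.array(list(combinations(range(p), 3)), dtype=np.intp)
    return idx[:, 0], idx[:, 1], idx[:, 2]


def pair_bs_loglik(prefs: PairPreferences, o: Sequence[int]) -> float:
    """Unnormalized pair Babington-Smith log-likelihood of an ordering."""
    o = _as_order(o, prefs.p)
    a, b = _pair_positions(prefs.p)
    return float(prefs.log_pi[o[a], o[b]].sum())


def triplet_bs_loglik(prefs: TripletPreferences, o: Sequence[int]) -> float:
    """Unnormalized triplet Babington-Smith log-likelihood of an ordering."""
    o = _as_order(o, prefs.p)
    a, b, c = _triple_positions(prefs.p)
    return float(prefs.log_rho[o[a], o[b], o[c]].sum())


def pair_swap_delta(prefs: PairPreferences, o: Sequence[int], a: int, b: int) -> float:
    """Change in the pair BS log-likelihood when positions a < b are swapped.

    Only pairs involving the swapped positions change: the (a, b) pair itself
    plus, for every intermediate position c, the (a, c) and (c, b) pairs.
    O(p) work.
    """
    if not 0 <= a < b:
        raise ParameterError(f"need positions 0 <= a < b, got a={a}, b={b}")
    o = _as_order(o, prefs.p)
    L = prefs.log_pi
    u, v = o[a], o[b]
    delta = L[v, u] - L[u, v]
    mid = o[a + 1 : b]
    if mid.size:
        delta += float(
            (L[v, mid] + L[mid, u] - L[u, mid] - L[mid, v]).sum()
        )
    return float(delta)


def _affected_triples(p: int, a: int, b: int):
    """Position triples (sorted) containing position a or position b."""
    others = np.array([x for x in range(p) if x != a and x != b], dtype=np.intp)
    rows = [np.sort(np.stack([np.full(others.size, a), np.full(others.size, b), others], 1), 1)]
    if others.size >= 2:
        s, t = np.triu_indices(others.size, 1)
        pair = np.stack([others[s], others[t]], axis=1)
        for x in (a, b):
            rows.append(np.sort(np.column_stack([np.full(len(pair), x), pair]), axis=1))
    return np.concatenate(rows, axis=0)


def triplet_swap_delta(prefs: TripletPreferences, o: Sequence[int], a: int, b: int) -> float:
    """Change in the triplet BS log-likelihood when positions a < b are swapped.

    Re-evaluates log rho for every position triple containing a or b (the only
    triples whose internal node assignment can change); O(p^2) work.
    """
    if not 0 <= a < b:
        raise ParameterError(f"need positions 0 <= a < b, got a={a}, b={b}")
    o = _as_order(o, prefs.p)
    tri = _affected_triples(prefs.p, a, b)
    o2 = o.copy()
    o2[a], o2[b] = o[b], o[a]
    R = prefs.log_rho
    old = R[o[tri[:, 0]], o[tri[:, 1]], o[tri[:, 2]]].sum()
    new = R[o2[tri[:, 0]], o2[tri[:, 1]], o2[tri[:, 2]]].sum()
    return float(new - old)
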