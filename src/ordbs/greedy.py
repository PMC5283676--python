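"""Greedy construction of a high-preference causal ordering.

Starts from the best pair (or triple) in the preference table and repeatedly
inserts one remaining node at the (node, gap) choice that maximizes the
partial Babington-Smith log-likelihood restricted to the nodes placed so
far. Pairs mode touches O(p^3) table entries in total, triplets mode O(p^4).
Ties are broken by the lowest (node index, position), making the
construction deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ParameterError
from .preferences import PairPreferences, TripletPreferences

__all__ = ["GreedyResult", "greedy_order"]


@dataclass(frozen=True)
class GreedyResult:
    """Greedy ordering, its final partial BS log-likelihood, and table-lookup count."""

    ordering: np.ndarray
    score: float
    n_lookups: int


def _init_pair(log_pi: np.ndarray) -> tuple[list[int], float]:
    masked = np.where(np.isnan(log_pi), -np.inf, log_pi)
    i, j = np.unravel_index(np.argmax(masked), masked.shape)  # row-major: lowest (i, j) wins ties
    return [int(i), int(j)], float(masked[i, j])


def _init_triplet(log_rho: np.ndarray) -> tuple[list[int], float]:
    masked = np.where(np.isnan(log_rho), -np.inf, log_rho)
    i, j, k = np.unravel_index(np.argmax(masked), masked.shape)
    return [int(i), int(j), int(k)], float(masked[i, j, k])


def _pair_insertion_gains(log_pi: np.ndarray, placed: list[int], v: int) -> np.ndarray:
    """Gain of the partial pair score for inserting node v at each of the L+1 gaps."""
    q = np.asarray(placed, dtype=np.intp)
    before = log_pi[q, v]  # placed node precedes v
    after = log_pi[v, q]  # v precedes placed node
    # gain(g) = sum(before[:g]) + sum(after[g:])
    cum_before = np.concatenate([[0.0], np.cumsum(before)])
    cum_after = np.concatenate([np.cumsum(after[::-1])[::-1], [0.0]])
    return cum_before + cum_after


def _triplet_insertion_gains(log_rho: np.ndarray, placed: list[int], v: int) -> np.ndarray:
    """Gain of the partial triplet score for inserting node v at each gap.

    For gap g, the new triples are (q_s, q_t, v) for s < t < g, (q_s, v, q_t)
    for s < g <= t, and (v, q_s, q_t) for g <= s < t; each family is summed
    with cumulative prefix/suffix sums over the placed-pair triangle.
    """
    q = np.asarray(placed, dtype=np.intp)
    L = q.size
    s, t = np.triu_indices(L, 1)
    A = np.zeros((L, L))
    B = np.zeros((L, L))
    C = np.zeros((L, L))
    A[s, t] = log_rho[q[s], q[t], v]
    B[s, t] = log_rho[q[s], v, q[t]]
    C[s, t] = log_rho[v, q[s], q[t]]
    gains = np.zeros(L + 1)
    # both placed nodes before the gap: sum_{s<t<g} A
    col_a = A.sum(axis=0)  # col_a[t] = sum_{s<t} A[s, t]
    gains += np.concatenate([[0.0], np.cumsum(col_a)])
    # straddling: sum_{s<g<=t} B, via suffix sums over t of the s-prefix-summed table
    PB = np.cumsum(B, axis=0)
    QB = np.cumsum(PB[:, ::-1], axis=1)[:, ::-1]
    for g in range(1, L):
        gains[g] += QB[g - 1, g]
    # both after: sum_{g<=s<t} C
    col_c = C.sum(axis=1)  # col_c[s] = sum_{t>s} C[s, t]
    gains += np.concatenate([np.cumsum(col_c[::-1])[::-1], [0.0]])
    return gains


def greedy_order(
    prefs: PairPreferences | TripletPreferences, *, return_details: bool = False
):
    """Greedy high-preference ordering from a pair or triplet table.

    Returns the ordering as an index array, or a :class:`GreedyResult` with
    the final partial score and the number of preference-table entries
    touched when ``return_details`` is set.
    """
    p = prefs.p
    lookups = 0
    if isinstance(prefs, PairPreferences):
        if p < 2:
            raise ParameterError("pair-based greedy needs p >= 2")
        placed, score = _init_pair(prefs.log_pi)
        lookups += p * p
        gains_fn = lambda v: _pair_insertion_gains(prefs.log_pi, placed, v)
        per_candidate = lambda L: 2 * L
    elif isinstance(prefs, TripletPreferences):
        if p < 3:
            raise ParameterError("triplet-based greedy needs p >= 3")
        placed, score = _init_triplet(prefs.log_rho)
        lookups += p * p * p
        gains_fn = lambda v: _triplet_insertion_gains(prefs.log_rho, placed, v)
        per_candidate = lambda L: 3 * (L * (L - 1)) // 2
    else:
        raise ParameterError(f"unsupported preference table type {type(prefs)!r}")

    remaining = sorted(set(range(p)) - set(placed))
    while remaining:
        best = None  # (gain, node, gap)
        for v in remaining:
            gains = gains_fn(v)
            lookups += per_candidate(len(placed))
            g = int(np.argmax(gains))  # argmax returns the lowest position on ties
            if best is None or gains[g] > best[0]:
                best = (float(gains[g]), v, g)
        gain, v, g = best
        placed.insert(g, v)
        remaining.remove(v)
        score += gain
    order = np.array(placed, dtype=np.intp)
    if return_details:
        return GreedyResult(ordering=order, score=score, n_lookups=lookups)
    return order
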