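from itertools import combinations, permutations

import numpy as np
import pytest
from scipy.special import expit

from conftest import make_ensemble_data, make_iid_data
from ordbs.dag_model import ExperimentSet
from ordbs.exceptions import DegenerateNodeError, ParameterError
from ordbs.preferences import (
    PairPreferences,
    TripletPreferences,
    pair_bs_loglik,
    pair_preferences,
    pair_swap_delta,
    subgraph_max_loglik,
    triplet_bs_loglik,
    triplet_preferences,
    triplet_swap_delta,
)


def random_pair_prefs(p, seed):
    rng = np.random.default_rng(seed)
    pi = np.full((p, p), np.nan)
    for i, j in combinations(range(p), 2):
        x = rng.uniform(0.05, 0.95)
        pi[i, j], pi[j, i] = x, 1 - x
    return PairPreferences(pi=pi)


def random_triplet_prefs(p, seed):
    rng = np.random.default_rng(seed)
    rho = np.full((p, p, p), np.nan)
    for tri in combinations(range(p), 3):
        probs = rng.dirichlet(np.ones(6))
        for perm, pr in zip(permutations(range(3)), probs):
            rho[tri[perm[0]], tri[perm[1]], tri[perm[2]]] = pr
    return TripletPreferences(rho=rho)


class TestSubgraphLikelihood:
    def test_matches_full_mle_on_column_subset(self):
        # the 2-/3-node subgraph fit is the general MLE on restricted data
        from ordbs.likelihood import max_log_likelihood

        _, data = make_ensemble_data(6, 0.8, 60, 18, seed=1)
        for seq in [(0, 3), (4, 1), (2, 0, 5)]:
            sub = data.subset(seq, exclude_external_interventions=True)
            ref = max_log_likelihood(sub, np.arange(len(seq))).ell_max
            assert subgraph_max_loglik(data, seq) == pytest.approx(ref, abs=1e-10)

    def test_chain_triplet_ordering_dominates(self, chain3):
        _, data = chain3
        ells = {perm: subgraph_max_loglik(data, perm) for perm in permutations((0, 1, 2))}
        assert max(ells, key=ells.get) == (0, 1, 2)

    def test_degenerate_subgraph_identified(self):
        # every experiment intervenes outside the pair: exclusion leaves nothing
        X = np.zeros((4, 3))
        data = ExperimentSet(X=X, interventions=({2: 0.0},) * 4)
        with pytest.raises(DegenerateNodeError):
            subgraph_max_loglik(data, (0, 1))

    def test_invalid_sequences_rejected(self):
        _, data = make_ensemble_data(4, 1.0, 40, 0, seed=2)
        with pytest.raises(ParameterError):
            subgraph_max_loglik(data, (0, 0))
        with pytest.raises(ParameterError):
            subgraph_max_loglik(data, (0, 1, 2, 3))


class TestPreferenceTables:
    def test_pair_table_normalization_and_oracle(self):
        _, data = make_ensemble_data(6, 0.7, 60, 18, seed=3)
        prefs = pair_preferences(data)
        for i, j in combinations(range(6), 2):
            assert prefs.pi[i, j] + prefs.pi[j, i] == pytest.approx(1.0, abs=1e-12)
            ref = expit(subgraph_max_loglik(data, (i, j)) - subgraph_max_loglik(data, (j, i)))
            assert prefs.pi[i, j] == pytest.approx(ref, abs=1e-9)

    def test_triplet_table_normalization_and_oracle(self):
        _, data = make_ensemble_data(5, 0.7, 50, 15, seed=4)
        prefs = triplet_preferences(data)
        for tri in combinations(range(5), 3):
            entries = [
                prefs.rho[tri[a], tri[b], tri[c]] for a, b, c in permutations(range(3))
            ]
            assert sum(entries) == pytest.approx(1.0, abs=1e-12)
            ells = np.array(
                [subgraph_max_loglik(data, [tri[a] for a in perm])
                 for perm in permutations(range(3))]
            )
            ref = np.exp(ells - ells.max())
            ref /= ref.sum()
            assert np.allclose(entries, ref, atol=1e-9)

    def test_independent_columns_give_indifferent_preferences(self):
        data = make_iid_data(4, 500, seed=5)
        pp = pair_preferences(data)
        tp = triplet_preferences(data)
        for i, j in combinations(range(4), 2):
            assert abs(pp.pi[i, j] - 0.5) < 0.1
        for tri in combinations(range(4), 3):
            for perm in permutations(range(3)):
                assert abs(tp.rho[tri[perm[0]], tri[perm[1]], tri[perm[2]]] - 1 / 6) < 0.1

    def test_chain_fixture_preferences_are_decisive(self, chain3):
        _, data = chain3
        pp = pair_preferences(data)
        assert pp.pi[0, 1] > 0.99
        tp = triplet_preferences(data)
        six = {perm: tp.rho[perm[0], perm[1], perm[2]] for perm in permutations(range(3))}
        assert max(six, key=six.get) == (0, 1, 2)
        # a peaked triplet table implies the matching pair dominance
        assert pp.pi[0, 1] > pp.pi[1, 0] and pp.pi[1, 2] > pp.pi[2, 1]


class TestBsScores:
    def test_pair_score_trivia(self):
        prefs = random_pair_prefs(2, 0)
        assert pair_bs_loglik(prefs, [0, 1]) == pytest.approx(np.log(prefs.pi[0, 1]))
        flat = PairPreferences(pi=np.where(np.eye(5, dtype=bool), np.nan, 0.5))
        for seed in range(3):
            o = np.random.default_rng(seed).permutation(5)
            assert pair_bs_loglik(flat, o) == pytest.approx(10 * np.log(0.5))

    def test_pair_score_matches_brute_force_product(self):
        prefs = random_pair_prefs(6, 1)
        rng = np.random.default_rng(2)
        for _ in range(10):
            o = rng.permutation(6)
            brute = np.prod([prefs.pi[o[a], o[b]] for a in range(6) for b in range(a + 1, 6)])
            assert pair_bs_loglik(prefs, o) == pytest.approx(np.log(brute), abs=1e-10)

    def test_triplet_score_trivia_and_brute_force(self):
        prefs = random_triplet_prefs(3, 3)
        o = np.array([2, 0, 1])
        assert triplet_bs_loglik(prefs, o) == pytest.approx(np.log(prefs.rho[2, 0, 1]))
        uniform = TripletPreferences(rho=np.full((5, 5, 5), 1 / 6))
        assert triplet_bs_loglik(uniform, np.arange(5)) == pytest.approx(10 * np.log(1 / 6))
        prefs6 = random_triplet_prefs(6, 4)
        rng = np.random.default_rng(5)
        for _ in range(10):
            o = rng.permutation(6)
            brute = np.prod(
                [prefs6.rho[o[a], o[b], o[c]] for a, b, c in combinations(range(6), 3)]
            )
            assert triplet_bs_loglik(prefs6, o) == pytest.approx(np.log(brute), abs=1e-10)


class TestSwapDeltas:
    def test_adjacent_pair_swap_reduces_to_single_ratio(self):
        prefs = random_pair_prefs(5, 6)
        o = np.arange(5)
        d = pair_swap_delta(prefs, o, 2, 3)
        assert d == pytest.approx(np.log(prefs.pi[3, 2] / prefs.pi[2, 3]))

    def test_indifferent_tables_give_zero_delta(self):
        flat = PairPreferences(pi=np.where(np.eye(6, dtype=bool), np.nan, 0.5))
        uniform = TripletPreferences(rho=np.full((6, 6, 6), 1 / 6))
        o = np.random.default_rng(0).permutation(6)
        assert pair_swap_delta(flat, o, 1, 4) == pytest.approx(0.0)
        assert triplet_swap_delta(uniform, o, 1, 4) == pytest.approx(0.0)

    @pytest.mark.parametrize("kind,p", [("pair", 12), ("triplet", 10)])
    def test_delta_matches_from_scratch_difference(self, kind, p):
        if kind == "pair":
            prefs = random_pair_prefs(p, 7)
            delta_fn, score_fn = pair_swap_delta, pair_bs_loglik
        else:
            prefs = random_triplet_prefs(p, 8)
            delta_fn, score_fn = triplet_swap_delta, triplet_bs_loglik
        rng = np.random.default_rng(9)
        o = rng.permutation(p)
        for _ in range(200):
            a, b = sorted(rng.choice(p, 2, replace=False))
            o2 = o.copy()
            o2[a], o2[b] = o[b], o[a]
            ref = score_fn(prefs, o2) - score_fn(prefs, o)
            assert delta_fn(prefs, o, int(a), int(b)) == pytest.approx(ref, abs=1e-10)
            o = o2  # walk so many distinct configurations are exercised

    def test_accumulated_deltas_match_endpoint_scores(self):
        prefs = random_triplet_prefs(8, 10)
        rng = np.random.default_rng(11)
        o = rng.permutation(8)
        start = triplet_bs_loglik(prefs, o)
        acc = 0.0
        for _ in range(60):
            a, b = sorted(rng.choice(8, 2, replace=False))
            acc += triplet_swap_delta(prefs, o, int(a), int(b))
            o[a], o[b] = o[b], o[a]
        assert start + acc == pytest.approx(triplet_bs_loglik(prefs, o), abs=1e-8)

    def test_unordered_positions_rejected(self):
        prefs = random_pair_prefs(5, 12)
        with pytest.raises(ParameterError):
            pair_swap_delta(prefs, np.arange(5), 3, 1)
        with pytest.raises(ParameterError):
            triplet_swap_delta(random_triplet_prefs(5, 13), np.arange(5), 2, 2)
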