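"""Finite-population macro-model: Fermi selection, fixation, profile chain."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from evorank import (EvoParams, ReducibleChainError, build_profile_chain,
                     build_single_population_chain, fermi_probability,
                     fixation_probability, fixation_probability_oracle,
                     make_canonical_game, random_game, sparsity,
                     stationary_distribution)
from evorank.macro import (BirthDeathState, chain_to_dot, chain_to_tsv,
                           fitness, fitness_polymorphic, step_probabilities)
from conftest import random_game_corpus


def params(m=50, alpha=0.1, **kw):
    return EvoParams(m=m, alpha=alpha, **kw)


class TestFitness:
    def test_monomorphic_fitness_is_payoff(self, canonical_games):
        bos = canonical_games["battle_of_sexes"]
        assert fitness(bos, 0, 0, opponents=(0,)) == 3
        assert fitness(bos, 1, 1, opponents=(1,)) == 3
        assert fitness(bos, 1, 0, opponents=(1,)) == 0

    def test_polymorphic_reduces_to_monomorphic(self):
        g = random_game(3, [3, 3, 3], (-2, 2), seed=4)
        m = 10
        for k in range(3):
            counts = []
            opp = []
            for c in range(3):
                if c == k:
                    continue
                vec = [0, 0, 0]
                vec[1] = m
                counts.append(vec)
                opp.append(1)
            poly = fitness_polymorphic(g, k, 2, counts, m)
            assert poly == pytest.approx(fitness(g, k, 2, opp), rel=1e-14)

    def test_polymorphic_mixes_opponents(self):
        g = random_game(2, [2, 2], (0, 1), seed=9)
        # half the opponent population on each strategy -> average payoff
        got = fitness_polymorphic(g, 0, 0, [[5, 5]], 10)
        want = 0.5 * (g.payoffs[0][0, 0] + g.payoffs[0][0, 1])
        assert got == pytest.approx(want)

    def test_polymorphic_counts_must_sum_to_m(self):
        g = random_game(2, [2, 2], (0, 1), seed=9)
        with pytest.raises(ValueError):
            fitness_polymorphic(g, 0, 0, [[5, 4]], 10)


class TestFermi:
    def test_neutral_alpha_gives_half(self):
        assert fermi_probability(0.0, 3.0, -5.0) == 0.5

    def test_log3_gives_quarter(self):
        # alpha*(f_tau - f_sigma) = ln 3  ->  1/(1+3)
        assert fermi_probability(1.0, 0.0, math.log(3)) == pytest.approx(0.25)

    def test_strong_selection_limits(self):
        assert fermi_probability(100.0, 10.0, 0.0) == pytest.approx(1.0)
        assert fermi_probability(100.0, 0.0, 10.0) == pytest.approx(0.0, abs=1e-300)

    @given(x=st.floats(min_value=-800, max_value=800))
    @settings(deadline=None, derandomize=True)
    def test_no_overflow_and_complementarity(self, x):
        p = fermi_probability(1.0, 0.0, x)
        q = fermi_probability(1.0, x, 0.0)
        assert 0.0 <= p <= 1.0
        assert p + q == pytest.approx(1.0)


class TestStepProbabilities:
    def test_absorbing_boundaries(self):
        p = params()
        assert step_probabilities(BirthDeathState(0, 50), p, 1.0, 0.0) == (0, 0)
        assert step_probabilities(BirthDeathState(50, 0), p, 1.0, 0.0) == (0, 0)

    def test_m2_neutral_quarter(self):
        dec, inc = step_probabilities(BirthDeathState(1, 1), params(m=2), 1.0, 1.0)
        assert dec == pytest.approx(0.25)
        assert inc == pytest.approx(0.25)

    def test_alpha_zero_balances(self):
        p = params(alpha=0.0)
        for pt in range(1, 50):
            dec, inc = step_probabilities(
                BirthDeathState(pt, 50 - pt), p, 2.0, -1.0)
            assert dec == pytest.approx(inc)


class TestFixation:
    def test_neutral_branch(self):
        assert fixation_probability(params(m=50), 1.0, 1.0) == pytest.approx(0.02)
        assert fixation_probability(params(m=50, alpha=0.0), 5.0, -5.0) \
            == pytest.approx(0.02)

    def test_m2_log2_two_thirds(self):
        # at m=2 the closed form reduces to the Fermi term: 1/(1+e^{-alpha u})
        p = params(m=2, alpha=1.0)
        assert fixation_probability(p, math.log(2), 0.0) == pytest.approx(2 / 3)

    def test_oracle_m2_log2(self):
        p = params(m=2, alpha=1.0)
        assert fixation_probability_oracle(p, math.log(2), 0.0) \
            == pytest.approx(2 / 3, abs=1e-12)

    def test_oracle_neutral_drift(self):
        p = params(m=50, alpha=1.0)
        assert fixation_probability_oracle(p, 1.0, 1.0) \
            == pytest.approx(0.02, abs=1e-10)

    @pytest.mark.parametrize("m", [2, 10, 50])
    @pytest.mark.parametrize("au", [-5.0, -2.0, -0.5, -0.01, 0.01, 0.5, 2.0, 5.0])
    def test_closed_form_matches_absorption_oracle(self, m, au):
        p = params(m=m, alpha=1.0)
        rho = fixation_probability(p, au, 0.0)
        oracle = fixation_probability_oracle(p, au, 0.0)
        assert rho == pytest.approx(oracle, rel=1e-8)

    def test_monotone_in_fitness_difference(self):
        p = params(m=20, alpha=1.5)
        us = np.linspace(-6, 6, 61)
        rhos = [fixation_probability(p, u, 0.0) for u in us]
        assert all(b >= a for a, b in zip(rhos, rhos[1:]))

    def test_extreme_selection_stable(self):
        p = params(m=50, alpha=100.0)
        assert fixation_probability(p, 50.0, 0.0) == pytest.approx(1.0)
        assert fixation_probability(p, 0.0, 50.0) == 0.0
        # log-domain branch agrees with direct evaluation where both work
        p2 = params(m=4, alpha=1.0)
        for u in [-10.0, -8.0]:
            direct = math.expm1(-u) / math.expm1(-4 * u)
            assert fixation_probability(p2, u, 0.0) == pytest.approx(direct,
                                                                     rel=1e-12)


class TestProfileChain:
    def test_rps_neutral_chain_entries(self, canonical_games):
        # single population, alpha=0: eta=1/2 and rho=1/m everywhere
        m = 50
        chain = build_single_population_chain(
            canonical_games["rps"], params(m=m, alpha=0.0))
        C = chain.matrix.toarray()
        off = C[~np.eye(3, dtype=bool)]
        assert np.allclose(off, 1 / (2 * m))
        assert np.allclose(np.diag(C), 1 - 1 / m)

    def test_bos_row_structure(self, canonical_games):
        chain = build_profile_chain(canonical_games["battle_of_sexes"], params())
        C = chain.matrix
        assert C.shape == (4, 4)
        for i in range(4):
            row = C.getrow(i).toarray().ravel()
            assert np.count_nonzero(np.delete(row, i)) == 2

    def test_row_stochastic_and_sparsity_bound_on_random_games(self):
        for game in random_game_corpus(100, seed=23):
            if sum(n - 1 for n in game.shape) == 0:
                continue
            chain = build_profile_chain(game, params(alpha=0.5, m=20))
            C = chain.matrix
            rows = np.asarray(C.sum(axis=1)).ravel()
            np.testing.assert_allclose(rows, 1.0, atol=1e-12)
            assert C.data.min() >= 0 and C.data.max() <= 1 + 1e-12
            bound = 1 + sum(n - 1 for n in game.shape)
            assert max(np.diff(C.indptr)) <= bound
            assert chain.eta == pytest.approx(
                1 / sum(n - 1 for n in game.shape))

    def test_singleton_game_rejected(self):
        g = random_game(2, [1, 1], (0, 1), seed=0)
        with pytest.raises(ValueError, match="eta"):
            build_profile_chain(g, params())

    def test_single_population_requires_symmetry(self, canonical_games):
        with pytest.raises(ValueError, match="symmetric"):
            build_single_population_chain(
                canonical_games["battle_of_sexes"], params())


class TestStationaryDistribution:
    @pytest.mark.parametrize("alpha", [0.01, 0.1, 1.0, 10.0])
    def test_rps_uniform_any_alpha(self, canonical_games, alpha):
        chain = build_single_population_chain(
            canonical_games["rps"], params(m=50, alpha=alpha))
        dist = stationary_distribution(chain)
        np.testing.assert_allclose(dist.mass, 1 / 3, atol=1e-6)

    @pytest.mark.parametrize("name", ["rps", "biased_rps", "battle_of_sexes",
                                      "matching_pennies", "coordination"])
    @pytest.mark.parametrize("alpha", [0.01, 0.1, 1.0, 10.0])
    def test_residuals_on_canonical_games(self, canonical_games, name, alpha):
        game = canonical_games[name]
        chain = build_profile_chain(game, params(alpha=alpha))
        try:
            dist = stationary_distribution(chain)
        except ReducibleChainError:
            # at the strongest intensity the leak probabilities of the
            # coordination-type chains underflow; the explicit error (never
            # a silent wrong answer) is the contracted behavior
            assert alpha == 10.0
            return
        assert dist.residual <= 1e-10
        assert dist.mass.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(dist.mass >= 0)

    def test_neutral_alpha_uniform_for_arbitrary_games(self):
        for game in random_game_corpus(20, seed=31):
            if sum(n - 1 for n in game.shape) == 0:
                continue
            chain = build_profile_chain(game, params(alpha=0.0, m=10))
            dist = stationary_distribution(chain)
            np.testing.assert_allclose(dist.mass, 1 / game.num_profiles,
                                       atol=1e-10)

    def test_doubly_stochastic_two_state(self):
        import scipy.sparse as sp
        from evorank.macro import ProfileChain
        C = sp.csr_matrix(np.array([[0.5, 0.5], [0.5, 0.5]]))
        chain = ProfileChain(((0,), (1,)), ("a", "b"), C, 1.0, params())
        dist = stationary_distribution(chain)
        np.testing.assert_allclose(dist.mass, 0.5, atol=1e-14)

    def test_bos_large_alpha_coordination_mass(self, canonical_games):
        chain = build_profile_chain(
            canonical_games["battle_of_sexes"], params(alpha=2.0))
        dist = stationary_distribution(chain)
        by_label = dict(zip(chain.labels, dist.mass))
        assert by_label["(O,O)"] == pytest.approx(0.5, abs=1e-3)
        assert by_label["(M,M)"] == pytest.approx(0.5, abs=1e-3)
        assert by_label["(O,M)"] <= 1e-3 and by_label["(M,O)"] <= 1e-3

    def test_extreme_alpha_raises_not_silent(self, canonical_games):
        chain = build_profile_chain(
            canonical_games["battle_of_sexes"], params(alpha=1e4))
        with pytest.raises(ReducibleChainError, match="alpha"):
            stationary_distribution(chain)

    def test_constant_game_single_population_uniform(self):
        from evorank import NormalFormGame
        g = NormalFormGame(2, [["a", "b", "c"]] * 2,
                           [np.ones((3, 3)), np.ones((3, 3))])
        chain = build_single_population_chain(g, params(alpha=3.0))
        dist = stationary_distribution(chain)
        np.testing.assert_allclose(dist.mass, 1 / 3, atol=1e-12)
        # two identical-payoff strategies: both off-diagonals are 1/m (eta=1)
        g2 = NormalFormGame(2, [["a", "b"]] * 2,
                            [np.ones((2, 2)), np.ones((2, 2))])
        chain2 = build_single_population_chain(g2, params(m=50, alpha=1.0))
        C = chain2.matrix.toarray()
        assert C[0, 1] == pytest.approx(1 / 50)
        assert C[1, 0] == pytest.approx(1 / 50)


class TestSparsity:
    def test_six_player_four_strategy_value(self):
        g = random_game(6, [4] * 6, (0, 1), seed=0)
        assert sparsity(g) >= 0.9953
        assert sparsity(g) == pytest.approx(1 - (1 + 18) / 4096)

    def test_one_population_dense(self):
        g = random_game(1, [3], (0, 1), seed=0)
        assert sparsity(g) == pytest.approx(0.0)

    def test_two_by_two(self):
        g = random_game(2, [2, 2], (0, 1), seed=0)
        assert sparsity(g) == pytest.approx(0.25)

    def test_matches_built_matrix_nnz(self):
        g = random_game(3, [3, 2, 4], (-1, 1), seed=5)
        chain = build_profile_chain(g, params(alpha=0.3, m=10))
        achieved = 1 - chain.matrix.nnz / g.num_profiles**2
        # closed form is a lower bound on achieved sparsity (zero diag slack)
        assert achieved >= sparsity(g) - 1e-12


class TestExports:
    def test_dot_and_tsv_exports(self, canonical_games):
        chain = build_single_population_chain(canonical_games["rps"], params())
        dist = stationary_distribution(chain)
        dot = chain_to_dot(chain, dist)
        assert dot.startswith("digraph") and "->" in dot
        tsv = chain_to_tsv(chain)
        assert tsv.splitlines()[0] == "source\ttarget\tprobability"
        assert len(tsv.splitlines()) == 1 + chain.matrix.nnz
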