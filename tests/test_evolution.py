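import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tomcg import (
    PairwisePayoffMatrix,
    ToMStrategy,
    composition_fitness,
    embedded_chain,
    fermi_prob,
    fixation_probability,
    gradient_of_selection,
    is_evolutionarily_robust,
    marginals,
    payoff_matrix,
    strategy_space,
)


def toy_matrix(values):
    """2x2 payoff matrix between labelled dummy strategies A=(1,0), B=(2,0)."""
    return PairwisePayoffMatrix(
        strategies=(ToMStrategy(1, 0), ToMStrategy(2, 0)),
        pay=np.asarray(values, dtype=float),
    )


def brute_force_fixation(pay, Z, beta):
    """Absorbing-chain linear solve for the invader's fixation probability.

    Independent oracle for the closed form: solves the (Z+1)-state
    birth-death chain for absorption at Z starting from one invader.
    """
    i = np.arange(1, Z)
    fA = ((i - 1) * pay[0, 0] + (Z - i) * pay[0, 1]) / (Z - 1)
    fB = (i * pay[1, 0] + (Z - 1 - i) * pay[1, 1]) / (Z - 1)
    up = ((Z - i) / Z) * (i / (Z - 1)) / (1 + np.exp(-beta * (fA - fB)))
    dn = (i / Z) * ((Z - i) / (Z - 1)) / (1 + np.exp(beta * (fA - fB)))
    # h(i) = P(absorb at Z | state i);  h(0)=0, h(Z)=1
    A = np.zeros((Z - 1, Z - 1))
    b = np.zeros(Z - 1)
    for row, ii in enumerate(i):
        A[row, row] = up[row] + dn[row]
        if row > 0:
            A[row, row - 1] = -dn[row]
        if row < Z - 2:
            A[row, row + 1] = -up[row]
        if ii == Z - 1:
            b[row] = up[row]
    return float(np.linalg.solve(A, b)[0])


class TestFermi:
    def test_neutral_selection_gives_half(self):
        assert fermi_prob(0.0, 1.23, -9.0) == 0.5

    def test_equal_fitness_gives_half(self):
        assert fermi_prob(3.0, 0.7, 0.7) == 0.5

    def test_saturates_for_large_advantage(self):
        assert fermi_prob(10.0, 5.0, 0.0) == pytest.approx(1.0)

    def test_overflow_safe(self):
        assert fermi_prob(1e4, -1e3, 1e3) == pytest.approx(0.0, abs=1e-300)
        assert fermi_prob(1e4, 1e3, -1e3) == 1.0

    def test_negative_beta_rejected(self):
        with pytest.raises(ValueError):
            fermi_prob(-1.0, 0.0, 0.0)


class TestCompositionFitness:
    def test_lone_mutant_meets_only_residents(self):
        pay = toy_matrix([[1.0, 2.0], [3.0, 4.0]])
        fA, fB = composition_fitness((1, 0), (2, 0), 1, 10, pay)
        assert fA == pytest.approx(2.0)

    def test_lone_resident_mirrored(self):
        pay = toy_matrix([[1.0, 2.0], [3.0, 4.0]])
        _, fB = composition_fitness((1, 0), (2, 0), 9, 10, pay)
        assert fB == pytest.approx(3.0)

    def test_neutral_payoffs_equalize(self):
        pay = toy_matrix([[1.0, 1.0], [1.0, 1.0]])
        fA, fB = composition_fitness((1, 0), (2, 0), 4, 10, pay)
        assert fA == fB == 1.0

    def test_out_of_range_composition(self):
        pay = toy_matrix([[1.0, 1.0], [1.0, 1.0]])
        with pytest.raises(ValueError):
            composition_fitness((1, 0), (2, 0), 10, 10, pay)


class TestFixation:
    def test_neutral_drift_fixes_at_one_over_Z(self):
        pay = toy_matrix([[0.3, 1.9], [0.8, 0.1]])
        for Z in (2, 10, 500):
            rho = fixation_probability((1, 0), (2, 0), Z, 0.0, pay)
            assert rho == pytest.approx(1.0 / Z, rel=1e-12)

    def test_two_individuals_reduce_to_single_fermi_step(self):
        pay = toy_matrix([[0.0, 1.4], [0.6, 0.0]])
        rho = fixation_probability((1, 0), (2, 0), 2, 0.7, pay)
        assert rho == pytest.approx(fermi_prob(0.7, 1.4, 0.6))

    @given(
        vals=st.lists(st.floats(0.0, 5.0), min_size=4, max_size=4),
        Z=st.integers(2, 12),
        beta=st.sampled_from([0.0, 0.5, 2.0]),
    )
    @settings(max_examples=80, deadline=None)
    def test_closed_form_matches_birth_death_linear_solve(self, vals, Z, beta):
        pay = toy_matrix(np.array(vals).reshape(2, 2))
        rho = fixation_probability((1, 0), (2, 0), Z, beta, pay)
        assert rho == pytest.approx(brute_force_fixation(pay.pay, Z, beta), rel=1e-9)

    def test_large_beta_Z_is_overflow_safe(self):
        pay = toy_matrix([[0.0, 0.0], [5.0, 5.0]])  # hopeless invader
        rho = fixation_probability((1, 0), (2, 0), 500, 10.0, pay)
        assert rho == 0.0


class TestEmbeddedChain:
    def test_two_neutral_strategies_split_evenly(self):
        pay = toy_matrix([[1.0, 1.0], [1.0, 1.0]])
        chain = embedded_chain(pay.strategies, 50, 1.0, pay)
        assert chain.sigma == pytest.approx([0.5, 0.5])

    def test_neutral_selection_is_uniform_over_any_set(self, icg4):
        strategies = strategy_space(icg4)
        pay = payoff_matrix(strategies, icg4, "inertia", 0.19)
        chain = embedded_chain(strategies, 500, 0.0, pay)
        assert chain.sigma == pytest.approx(np.full(25, 1 / 25), abs=1e-12)

    def test_rows_sum_to_one_and_sigma_is_stationary(self, icg4):
        strategies = strategy_space(icg4)
        pay = payoff_matrix(strategies, icg4, "inertia", 0.19)
        chain = embedded_chain(strategies, 100, 0.31, pay)
        assert chain.gamma.sum(axis=1) == pytest.approx(np.ones(25), abs=1e-12)
        assert np.abs(chain.sigma @ chain.gamma - chain.sigma).max() < 1e-10
        assert chain.sigma.sum() == pytest.approx(1.0)

    def test_inhibited_k_transitions_renormalize(self, icg4):
        strategies = strategy_space(icg4)
        pay = payoff_matrix(strategies, icg4, "inertia", 0.19)
        chain = embedded_chain(strategies, 100, 0.31, pay, k_transition_weight=0.1)
        assert chain.gamma.sum(axis=1) == pytest.approx(np.ones(25), abs=1e-12)
        base = embedded_chain(strategies, 100, 0.31, pay)
        i10, i11 = [pay.index(s) for s in ((1, 0), (1, 1))]
        assert chain.gamma[i10, i11] == pytest.approx(0.1 * base.gamma[i10, i11])


class TestMarginals:
    def test_concentrated_sigma_yields_point_marginals(self, icg4):
        # (1,0) invades (2,0) but not vice versa, so sigma piles up on it
        strategies = [ToMStrategy(1, 0), ToMStrategy(2, 0)]
        pay = payoff_matrix(strategies, icg4, "inertia", 0.0)
        chain = embedded_chain(strategies, 50, 5.0, pay)
        summ = marginals(chain, icg4, "inertia", 0.0)
        assert summ.t_marginal[1] > 0.99
        assert summ.avg_k == 0.0

    def test_no_mismatch_without_theory_of_mind(self, icg4):
        strategies = [ToMStrategy(t, 0) for t in range(1, 6)]
        pay = payoff_matrix(strategies, icg4, "inertia", 0.19)
        chain = embedded_chain(strategies, 50, 0.31, pay)
        summ = marginals(chain, icg4, "inertia", 0.19)
        assert summ.belief_mismatch_by_k == {0: pytest.approx(0.0, abs=1e-12)}

    def test_uniform_sigma_averages_available_k(self, icg4):
        strategies = strategy_space(icg4)
        pay = payoff_matrix(strategies, icg4, "inertia", 0.19)
        chain = embedded_chain(strategies, 500, 0.0, pay)
        summ = marginals(chain, icg4, "inertia", 0.19)
        assert summ.avg_k == pytest.approx(2.0)  # mean of k in 0..4


class TestGradient:
    def test_neutral_selection_has_zero_gradient(self, icg4):
        pay = payoff_matrix([(1, 0), (5, 3)], icg4, "inertia", 0.19)
        prof = gradient_of_selection((5, 3), (1, 0), 100, 0.0, pay)
        assert (prof.G == 0).all()

    def test_dominant_strategy_has_positive_gradient(self):
        pay = toy_matrix([[2.0, 2.0], [1.0, 1.0]])
        prof = gradient_of_selection((1, 0), (2, 0), 50, 1.0, pay)
        assert (prof.G > 0).all()
        assert prof.repellers == ()

    def test_gradient_bounded_by_sampling_prefactor(self, icg4):
        pay = payoff_matrix([(1, 0), (5, 3)], icg4, "inertia", 0.19)
        prof = gradient_of_selection((5, 3), (1, 0), 200, 2.0, pay)
        i = prof.counts
        assert (np.abs(prof.G) <= i * (200 - i) / 200**2 + 1e-15).all()

    def test_zero_at_fitness_equality(self):
        pay = toy_matrix([[1.0, 1.0], [1.0, 1.0]])
        prof = gradient_of_selection((1, 0), (2, 0), 50, 3.0, pay)
        assert (prof.G == 0).all()

    def test_coordination_pair_has_interior_repeller_at_high_error(self, icg4):
        # at eps = 0.19 the (1,0)/(5,3) pair is a coordination game whose
        # repeller sits below Z/2: the ToM strategy holds the larger basin
        pay = payoff_matrix([(1, 0), (5, 3)], icg4, "inertia", 0.19)
        prof = gradient_of_selection((5, 3), (1, 0), 500, 0.31, pay)
        assert prof.has_interior_repeller()
        assert max(prof.repellers) < 250


class TestRobustness:
    def test_no_strategy_robust_under_neutral_drift(self, icg4):
        strategies = [(1, 0), (3, 1), (5, 3)]
        pay = payoff_matrix(strategies, icg4, "inertia", 0.19)
        robust, table = is_evolutionarily_robust((1, 0), strategies, 100, 0.0, pay)
        assert not robust
        assert all(rho == pytest.approx(0.01) for rho in table.values())

    def test_strictly_dominant_strategy_is_robust(self):
        pay = toy_matrix([[2.0, 2.0], [1.0, 1.0]])
        robust, table = is_evolutionarily_robust(
            (1, 0), pay.strategies, 50, 5.0, pay)
        assert robust
        assert table[ToMStrategy(2, 0)] < 1 / 50

    def test_report_invariant_to_strategy_ordering(self, icg4):
        strategies = strategy_space(icg4)
        pay = payoff_matrix(strategies, icg4, "inertia", 0.19)
        rev = list(reversed(strategies))
        pay_rev = payoff_matrix(rev, icg4, "inertia", 0.19)
        r1, t1 = is_evolutionarily_robust((5, 3), strategies, 100, 2.0, pay)
        r2, t2 = is_evolutionarily_robust((5, 3), rev, 100, 2.0, pay_rev)
        assert r1 == r2
        for m, rho in t1.items():
            assert t2[m] == pytest.approx(rho, rel=1e-12)
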