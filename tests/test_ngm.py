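"""Disease-free equilibrium, transition matrices, R0 and the invasion number."""

import numpy as np
import pytest
import scipy.linalg

import agesirs as ag
from agesirs import model, ngm

from conftest import random_outer_instance


class TestDiseaseFreeEquilibrium:
    def test_single_stage_gets_whole_population(self):
        pop = ag.PopulationStructure([0.0], [0.01], 0.02)
        dfe = ngm.disease_free_equilibrium(pop)
        assert dfe.S_hat[0] == pytest.approx(1.0)

    def test_two_stage_hand_example(self):
        # a1 = delta2 = 0.05 makes alpha2 = 1, so the stages split evenly
        pop = ag.PopulationStructure([0.05, 0.0], [0.01, 0.05], 0.0)
        dfe = ngm.disease_free_equilibrium(pop)
        np.testing.assert_allclose(dfe.alpha, [1.0, 1.0])
        np.testing.assert_allclose(dfe.S_hat, [0.5, 0.5])

    def test_matches_linear_system_oracle(self):
        # oracle: solve the I=R=0 stage balance directly as a linear system
        rng = np.random.default_rng(5)
        pop, _, _ = random_outer_instance(rng, 4)
        a, delta = pop.aging_rates, pop.background_mortality
        n = pop.n
        A = np.zeros((n, n))
        for i in range(1, n):
            A[i, i - 1] = a[i - 1]
            A[i, i] = -(a[i] + delta[i])
        A[0, :] = 1.0  # replace stage-1 balance (redundant) with normalisation
        b = np.zeros(n)
        b[0] = 1.0
        oracle = scipy.linalg.solve(A, b)
        np.testing.assert_allclose(ngm.disease_free_equilibrium(pop).S_hat, oracle,
                                   rtol=1e-12)

    def test_is_fixed_point_of_the_dynamics(self, three_stage):
        sc = three_stage
        dfe = ngm.disease_free_equilibrium(sc.population)
        state = ag.SystemState(dfe.S_hat, np.zeros(sc.n), np.zeros(sc.n))
        deriv = ag.single_strain_rhs(state, sc.population, sc.strain, sc.transmission)
        assert np.max(np.abs(deriv.S)) < 1e-14

    def test_zero_denominator_rejected(self):
        pop = ag.PopulationStructure([0.05, 0.0], [0.01, 0.0], 0.0)
        with pytest.raises(ValueError, match="delta_n"):
            ngm.disease_free_equilibrium(pop)


class TestTransitionMatrix:
    def test_scalar_case(self):
        pop = ag.PopulationStructure([0.0], [0.01], 0.0)
        strain = ag.StrainTraits([0.19], [0.0])
        assert ngm.transition_matrix(pop, strain)[0, 0] == pytest.approx(-0.2)
        assert ngm.transition_matrix_inverse(pop, strain)[0, 0] == pytest.approx(-5.0)

    def test_two_stage_hand_inversion(self):
        # a1=1, mu1=2, mu2=4 -> -Sigma^{-1} = [[1/2, 0], [1/8, 1/4]]
        pop = ag.PopulationStructure([1.0, 0.0], [0.5, 1.0], 0.0)
        strain = ag.StrainTraits([0.5, 3.0], [0.0, 0.0])
        np.testing.assert_allclose(
            -ngm.transition_matrix_inverse(pop, strain),
            [[0.5, 0.0], [0.125, 0.25]], rtol=1e-14)

    def test_closed_form_inverse_matches_numeric(self):
        rng = np.random.default_rng(11)
        pop, strain, _ = random_outer_instance(rng, 5)
        Sigma = ngm.transition_matrix(pop, strain)
        inv = ngm.transition_matrix_inverse(pop, strain)
        np.testing.assert_allclose(Sigma @ inv, np.eye(5), atol=1e-12)
        np.testing.assert_allclose(inv, np.linalg.inv(Sigma), atol=1e-12)


class TestR0:
    def test_scalar_closed_form(self, single_stage):
        sc = single_stage
        expected = 0.4 / (0.1 + 0.01)
        assert ngm.r0(sc.population, sc.strain, sc.transmission, "trace") == \
            pytest.approx(expected, rel=1e-12)
        assert ngm.r0(sc.population, sc.strain, sc.transmission, "eigen") == \
            pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_trace_equals_dominant_eigenvalue_for_rank_one(self, seed):
        rng = np.random.default_rng(seed)
        pop, strain, trans = random_outer_instance(rng, 3)
        rt = ngm.r0(pop, strain, trans, "trace")
        re = ngm.r0(pop, strain, trans, "eigen")
        assert rt == pytest.approx(re, rel=1e-10)

    def test_zero_transmission_gives_zero(self):
        pop = ag.PopulationStructure([0.0], [0.01], 0.0)
        strain = ag.StrainTraits([0.1], [0.0])
        trans = ag.TransmissionStructure("outer_product", [1.0], [0.0])
        assert ngm.r0(pop, strain, trans) == 0.0

    def test_trace_refused_for_general_full_rank_contacts(self):
        rng = np.random.default_rng(3)
        pop, strain, _ = random_outer_instance(rng, 3)
        trans = ag.TransmissionStructure("general", contact_matrix=rng.uniform(0.1, 1, (3, 3)))
        with pytest.raises(ValueError, match="rank 1"):
            ngm.r0(pop, strain, trans, "trace")
        # and the trace genuinely differs from the spectral radius there
        dfe = ngm.disease_free_equilibrium(pop)
        tr = ngm.reproduction_number_trace(dfe.S_hat, pop, strain, trans)
        ev = ngm.r0(pop, strain, trans, "eigen")
        assert abs(tr - ev) > 1e-6


class TestInvasionNumber:
    @pytest.mark.parametrize("template,kwargs", [
        ("single_stage", {}),
        ("slow_aging_n", {"n": 2}),
        ("three_stage_human", {}),
        ("slow_aging_n", {"n": 5}),
    ])
    def test_self_invasion_is_neutral(self, template, kwargs):
        sc = ag.generate_scenario(template, **kwargs)
        eq = ag.endemic_equilibrium(sc.population, sc.strain, sc.transmission)
        assert not eq.subcritical
        q0 = ngm.invasion_number(eq.state.S, sc.population, sc.strain, sc.transmission)
        assert q0 == pytest.approx(1.0, abs=1e-4)

    def test_doubling_transmission_doubles_q0(self, single_stage, single_stage_eq):
        sc = single_stage
        q0 = ngm.invasion_number(single_stage_eq.state.S, sc.population, sc.strain,
                                 sc.transmission.scaled(2.0))
        assert q0 == pytest.approx(2.0, abs=1e-10)

    def test_scalar_q0_closed_form_and_ess_unimodality(self, single_stage, single_stage_eq):
        # scalar oracle: Q0(g) = beta(g) S* / (g + d + delta), maximal at gamma*
        sc = single_stage
        S_star = single_stage_eq.state.S[0]
        gamma_star = ag.ess_power_law_closed_form(0.5, 0.01)

        def q0_oracle(g):
            return sc.tradeoff.beta(g) * S_star / (g + 0.01)

        for g in (gamma_star / 2, 2 * gamma_star, 0.05, 0.2):
            mut = sc.strain.with_recovery([g])
            q0 = ngm.invasion_number(single_stage_eq.state.S, sc.population, mut,
                                     sc.transmission)
            assert q0 == pytest.approx(q0_oracle(g), rel=1e-12)
        q_star = q0_oracle(gamma_star)
        assert q0_oracle(gamma_star / 2) < q_star
        assert q0_oracle(2 * gamma_star) < q_star

    def test_q0_sign_agrees_with_two_strain_dynamics(self, single_stage, single_stage_eq):
        # Q0 > 1 mutants grow from a tiny seed, Q0 < 1 mutants decay
        sc = single_stage
        eq = single_stage_eq
        for scale, grows in ((0.5, True), (4.0, False)):
            mut = sc.strain.with_recovery(sc.strain.recovery * scale)
            q0 = ngm.invasion_number(eq.state.S, sc.population, mut, sc.transmission)
            assert (q0 > 1) == grows
            seed = 1e-6
            init = ag.SystemState(eq.state.S, eq.state.I * (1 - seed), eq.state.R,
                                  eq.state.I * seed, [0.0])
            traj = ag.integrate(init, sc.population, sc.strain, sc.transmission,
                                horizon=400.0, mutant=mut, n_eval=5)
            pooled = traj.y[3]
            assert (pooled[-1] > pooled[0]) == grows


class TestQ0Gradient:
    def test_vanishes_at_scalar_ess(self, single_stage):
        sc = single_stage
        gamma_star = ag.ess_power_law_closed_form(0.5, 0.01)
        resident = sc.strain.with_recovery([gamma_star])
        grad = ngm.q0_gradient(resident, sc.population, sc.transmission)
        assert abs(grad[0]) < 1e-6

    def test_positive_below_the_ess(self, single_stage):
        # acuter mutants invade a too-chronic resident
        sc = single_stage
        gamma_star = ag.ess_power_law_closed_form(0.5, 0.01)
        resident = sc.strain.with_recovery([gamma_star / 2])
        grad = ngm.q0_gradient(resident, sc.population, sc.transmission)
        assert grad[0] > 0

    def test_contact_rate_cancels_from_the_gradient(self, single_stage):
        sc = single_stage
        gamma_star = ag.ess_power_law_closed_form(0.5, 0.01)
        resident = sc.strain.with_recovery([gamma_star])
        for factor in (10.0, 1000.0):
            grad = ngm.q0_gradient(resident, sc.population, sc.transmission.scaled(factor))
            assert abs(grad[0]) < 1e-6

    def test_slow_aging_bound_for_three_stages(self, three_stage):
        # cross-stage coupling neglected by the per-stage ESS condition is small:
        # the gradient at gamma* is < 5% of its magnitude at gamma*/2
        sc = three_stage
        d = sc.strain.disease_mortality
        m = sc.population.aging_rates + d + sc.population.background_mortality
        gamma_star = ag.ess_power_law_closed_form(0.5, m)
        assert np.all((gamma_star + d) >= 50 * sc.population.aging_rates)
        star = ag.StrainTraits(gamma_star, d, sc.tradeoff)
        half = ag.StrainTraits(gamma_star / 2, d, sc.tradeoff)
        g_star = ngm.q0_gradient(star, sc.population, sc.transmission)
        g_half = ngm.q0_gradient(half, sc.population, sc.transmission)
        assert np.max(np.abs(g_star)) < 0.05 * np.max(np.abs(g_half))


class TestNGMBundle:
    def test_bundle_consistency(self, three_stage):
        sc = three_stage
        dfe = ngm.disease_free_equilibrium(sc.population)
        bundle = ngm.ngm_bundle(dfe.S_hat, sc.population, sc.strain, sc.transmission,
                                method="eigen")
        np.testing.assert_allclose(bundle.Sigma @ bundle.Sigma_inv, np.eye(sc.n),
                                   atol=1e-12)
        assert np.all(bundle.K >= 0)
        assert bundle.value == pytest.approx(np.trace(bundle.K), rel=1e-10)
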