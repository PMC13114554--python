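import numpy as np
import pytest
from scipy.stats import chisquare

import qdyad as q


@pytest.fixture(scope="module")
def single_model(canonical_operator):
    return q.CollapseModel(canonical_operator, omega=1.0)


@pytest.fixture(scope="module")
def multi_model(dyad_qshapes, dyad_labels):
    ops = q.build_multi_operator_set(dyad_qshapes, dyad_labels)
    return q.CollapseModel(ops, omega=1.0)


@pytest.fixture(scope="module")
def superposed_rho():
    # (|0,0> + |1,0>)/sqrt(2), the post-SWAP state of the |0,+> preparation
    psi = q.apply_swap(q.prepare_product(("0", "+")))
    return q.DensityOp.from_pure(psi)


class TestLindbladRHS:
    def test_diagonal_states_are_stationary(self, single_model):
        rho = q.DensityOp(np.diag([0.4, 0.3, 0.2, 0.1]))
        assert np.allclose(q.lindblad_rhs(single_model, rho), 0.0)

    def test_maximally_mixed_is_stationary(self, multi_model):
        rho = q.DensityOp(np.eye(4) / 4)
        assert np.allclose(q.lindblad_rhs(multi_model, rho), 0.0)

    def test_entrywise_double_commutator(self, single_model, superposed_rho):
        # entry (i,k) decays at rate (omega/2) * (a_i - a_k)^2
        rhs = q.lindblad_rhs(single_model, superposed_rho)
        gaps = single_model.gap_matrix()
        expected = -0.5 * gaps * superposed_rho.matrix
        assert np.allclose(rhs, expected)

    def test_rhs_is_traceless_and_hermitian(self, multi_model, superposed_rho):
        H = np.diag([0.0, 1.0, 2.0, 3.0]) + 0.1 * (np.eye(4)[[1, 0, 3, 2]])
        model = q.CollapseModel(multi_model.operators, omega=2.0, hamiltonian=H)
        rhs = q.lindblad_rhs(model, superposed_rho)
        assert abs(np.trace(rhs)) < 1e-12
        assert np.allclose(rhs, rhs.conj().T)

    def test_shape_mismatch_errors(self, single_model):
        with pytest.raises(ValueError):
            q.lindblad_rhs(single_model, np.eye(3) / 3)


class TestMasterEquation:
    def test_time_zero_returns_the_input(self, single_model, superposed_rho):
        out = q.evolve_master(single_model, superposed_rho, 0.0)
        assert np.allclose(out.matrix, superposed_rho.matrix)

    def test_closed_form_matches_numerical_integration(
        self, single_model, superposed_rho
    ):
        closed = q.evolve_master(single_model, superposed_rho, 1.3)
        numeric_model = q.CollapseModel(
            single_model.operators, omega=1.0, hamiltonian=np.zeros((4, 4))
        )
        numeric = q.evolve_master(numeric_model, superposed_rho, 1.3)
        assert np.max(np.abs(closed.matrix - numeric.matrix)) < 1e-6

    def test_canonical_operator_coherence_decay(self, single_model, superposed_rho):
        # gap between |0,0> (lambda=2) and |1,0> (lambda=4) is 2: rate 2
        t = 0.7
        out = q.evolve_master(single_model, superposed_rho, t)
        assert abs(out.matrix[0, 2]) == pytest.approx(0.5 * np.exp(-2 * t), rel=1e-12)

    def test_multi_operator_rates_are_qshape_distances(self, multi_model):
        rho = q.DensityOp(np.full((4, 4), 0.25))
        t = 0.9
        out = q.evolve_master(multi_model, rho, t)
        # far pair (0,1)-(1,0): squared distance 4; near pair (0,0)-(0,1): 2
        assert abs(out.matrix[1, 2]) == pytest.approx(0.25 * np.exp(-2.0 * t))
        assert abs(out.matrix[0, 1]) == pytest.approx(0.25 * np.exp(-1.0 * t))

    def test_trace_hermiticity_positivity_preserved(self, multi_model, superposed_rho):
        for t in (0.1, 0.5, 2.0):
            out = q.evolve_master(multi_model, superposed_rho, t)
            assert np.trace(out.matrix).real == pytest.approx(1.0, abs=1e-9)
            assert np.allclose(out.matrix, out.matrix.conj().T)
            assert np.linalg.eigvalsh(out.matrix).min() >= -1e-7

    def test_populations_frozen_without_hamiltonian(self, single_model, superposed_rho):
        out = q.evolve_master(single_model, superposed_rho, 3.0)
        assert np.allclose(out.populations(), superposed_rho.populations())

    def test_offdiagonals_nonincreasing(self, single_model, superposed_rho):
        mags = [
            abs(q.evolve_master(single_model, superposed_rho, t).matrix[0, 2])
            for t in np.linspace(0, 2, 9)
        ]
        assert all(b <= a + 1e-12 for a, b in zip(mags, mags[1:]))

    def test_negative_time_rejected(self, single_model, superposed_rho):
        with pytest.raises(ValueError):
            q.evolve_master(single_model, superposed_rho, -1.0)


class TestFitDecayRate:
    @pytest.mark.parametrize("omega", [1.0, 2.0])
    def test_fitted_rate_matches_gap_formula(
        self, canonical_operator, superposed_rho, omega
    ):
        model = q.CollapseModel(canonical_operator, omega=omega)
        times = np.linspace(0.0, 1.0, 30)
        rhos = [q.evolve_master(model, superposed_rho, t) for t in times]
        rate = q.fit_decay_rate(times, rhos, (0, 2))
        expected = 0.5 * omega * model.gap_matrix()[0, 2]
        assert rate == pytest.approx(expected, rel=0.01)

    def test_zero_gap_pair_has_zero_rate(self, dyad_qshapes, dyad_labels):
        ops = q.build_multi_operator_set([dyad_qshapes[0]] * 4, dyad_labels)
        model = q.CollapseModel(ops, omega=1.0)
        rho = q.DensityOp(np.full((4, 4), 0.25))
        times = np.linspace(0.0, 1.0, 10)
        rhos = [q.evolve_master(model, rho, t) for t in times]
        assert q.fit_decay_rate(times, rhos, (0, 1)) == 0.0

    def test_vanishing_coherence_rejected(self, single_model):
        rho = q.DensityOp(np.diag([0.5, 0.5, 0.0, 0.0]))
        with pytest.raises(ValueError):
            q.fit_decay_rate([0.0, 1.0], [rho, rho], (0, 2))


class TestStochasticUnraveling:
    def test_collapse_eigenstate_is_stationary(self, single_model):
        psi0 = np.array([0.0, 1.0, 0.0, 0.0], dtype=complex)
        traj = q.simulate_sde(single_model, psi0, t=0.05, seed=3)
        assert np.allclose(np.abs(traj.states[-1]), np.abs(psi0), atol=1e-9)

    def test_trajectory_reproducible_from_seed(self, single_model):
        psi0 = q.apply_swap(q.prepare_product(("0", "+")))
        a = q.simulate_sde(single_model, psi0, t=0.02, seed=11)
        b = q.simulate_sde(single_model, psi0, t=0.02, seed=11)
        assert np.array_equal(a.states, b.states)

    def test_states_stay_normalized(self, single_model):
        psi0 = q.apply_swap(q.prepare_product(("0", "+")))
        traj = q.simulate_sde(single_model, psi0, t=0.05, seed=5)
        norms = np.linalg.norm(traj.states, axis=1)
        assert np.allclose(norms, 1.0, atol=1e-6)

    def test_oversized_step_rejected(self, single_model):
        psi0 = q.apply_swap(q.prepare_product(("0", "+")))
        with pytest.raises(ValueError):
            q.simulate_sde(single_model, psi0, t=1.0, dt=0.5, seed=0)

    def test_ensemble_matches_master_equation(self, single_model):
        # moderate ensemble for the routine suite; the acceptance test
        # exercises the full 2000-trajectory protocol
        psi0 = q.apply_swap(q.prepare_product(("0", "+")))
        rho0 = q.DensityOp.from_pure(psi0)
        res = q.simulate_ensemble(single_model, psi0, t=1.0, ntraj=400, seed=17)
        bound = 3 * 0.5 / np.sqrt(res["ntraj"])  # |psi_i psi_k*| <= 1/2
        for t, avg in zip(res["times"], res["avg_rho"]):
            exact = q.evolve_master(single_model, rho0, t).matrix
            assert np.max(np.abs(avg - exact)) < bound

    def test_outcomes_follow_born_weights(self, single_model):
        psi0 = q.apply_swap(q.prepare_product(("0", "+")))
        res = q.simulate_ensemble(single_model, psi0, t=4.0, ntraj=400, seed=23)
        hist = res["histogram"]
        assert hist[1] == 0 and hist[3] == 0  # unpopulated basis states
        stat = chisquare(hist[[0, 2]], [res["ntraj"] / 2] * 2)
        assert stat.pvalue > 0.01
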