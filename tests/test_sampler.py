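"""Sampler engine: integrator correctness, kernels, adaptation."""

import numpy as np
import pytest

from hmcscatter.likelihood import CallableTarget
from hmcscatter.sampler import (
    Chain,
    DualAveraging,
    MassMatrix,
    PhaseState,
    SamplerConfig,
    adapt_mass_matrix,
    hmc_draw,
    kinetic_energy,
    leapfrog_step,
    nuts_draw,
    reflect_at_constraint,
    run_chain,
    rw_proposal_scale,
    sample_momentum,
)

from conftest import gaussian_target


class TestMassMatrix:
    def test_rejects_nonpositive_diagonal(self):
        with pytest.raises(ValueError):
            MassMatrix(np.array([1.0, -2.0]))

    def test_rejects_indefinite_full(self):
        with pytest.raises(ValueError):
            MassMatrix(np.array([[1.0, 2.0], [2.0, 1.0]]))

    def test_full_form_solve_matches_dense_inverse(self, rng):
        A = rng.standard_normal((3, 3))
        cov = A @ A.T + 3 * np.eye(3)
        m = MassMatrix(cov)
        p = rng.standard_normal(3)
        np.testing.assert_allclose(m.solve(p), np.linalg.solve(cov, p),
                                   rtol=1e-12)


class TestMomentumAndKinetic:
    def test_identity_momentum_is_standard_normal(self, rng):
        m = MassMatrix.identity(2)
        draws = np.array([sample_momentum(m, rng) for _ in range(100_000)])
        # sample variance within 3 s.e. of 1 (s.e. ~ sqrt(2/n))
        se = np.sqrt(2.0 / draws.shape[0])
        assert np.all(np.abs(draws.var(axis=0) - 1.0) < 3 * se)
        assert np.all(np.abs(draws.mean(axis=0)) < 4 / np.sqrt(draws.shape[0]))

    def test_diagonal_mass_sets_momentum_variance(self, rng):
        m = MassMatrix(np.array([4.0]))
        draws = np.array([sample_momentum(m, rng)[0] for _ in range(100_000)])
        se = 4.0 * np.sqrt(2.0 / draws.size)
        assert abs(draws.var() - 4.0) < 3 * se

    def test_zero_dimension_gives_empty_vector(self, rng):
        assert sample_momentum(MassMatrix.identity(0), rng).size == 0

    @pytest.mark.parametrize(
        "p, mass, expected",
        [
            (np.zeros(3), np.ones(3), 0.0),
            (np.array([3.0]), np.ones(1), 4.5),
            # hand-solved: 0.5 * p' M^-1 p = 0.5 * 2 * (1/4) * 2 = 0.5
            (np.array([2.0]), np.array([4.0]), 0.5),
        ],
    )
    def test_kinetic_energy_values(self, p, mass, expected):
        assert kinetic_energy(p, MassMatrix(mass)) == pytest.approx(expected)

    def test_kinetic_energy_shape_mismatch(self):
        with pytest.raises(ValueError):
            kinetic_energy(np.ones(3), MassMatrix.identity(2))


def _harmonic():
    return CallableTarget(U=lambda z: 0.5 * float(z @ z), grad=lambda z: z)


def _state(x, p, target, mass):
    u, g = target.value_and_grad(x)
    return PhaseState(np.asarray(x, float), np.asarray(p, float), u,
                      mass.kinetic(np.asarray(p, float)), g)


class TestLeapfrog:
    def test_single_step_matches_symbolic_expansion(self):
        # 1-D harmonic: x' = x(1 - eps^2/2) + eps p ; p' = p(1-eps^2/2) - eps(1-eps^2/4) x
        eps = 0.1
        target = _harmonic()
        mass = MassMatrix.identity(1)
        s = leapfrog_step(_state([1.0], [0.0], target, mass), eps, target, mass)
        assert s.position[0] == pytest.approx(1 - eps**2 / 2, abs=1e-15)
        assert s.momentum[0] == pytest.approx(-eps * (1 - eps**2 / 4), abs=1e-15)

    def test_time_reversibility_to_roundoff(self, rng):
        target = gaussian_target([[1.0, 0.7], [0.7, 2.0]])
        mass = MassMatrix(np.array([1.0, 0.5]))
        x0 = rng.standard_normal(2)
        s = _state(x0, rng.standard_normal(2), target, mass)
        for _ in range(25):
            s = leapfrog_step(s, 0.05, target, mass)
        s = PhaseState(s.position, -s.momentum, s.potential, s.kinetic, s.grad)
        for _ in range(25):
            s = leapfrog_step(s, 0.05, target, mass)
        np.testing.assert_allclose(s.position, x0, atol=1e-10)

    def test_zero_step_size_is_identity(self):
        target = _harmonic()
        mass = MassMatrix.identity(1)
        s0 = _state([1.3], [0.4], target, mass)
        s = leapfrog_step(s0, 0.0, target, mass)
        assert s.position[0] == s0.position[0]
        assert s.momentum[0] == s0.momentum[0]

    def test_nonfinite_gradient_flags_divergence(self):
        bad = CallableTarget(U=lambda z: float("nan"),
                             grad=lambda z: np.full_like(z, np.nan))
        mass = MassMatrix.identity(1)
        s = PhaseState(np.array([0.0]), np.array([1.0]), 0.0, 0.5,
                       np.array([np.nan]))
        out = leapfrog_step(s, 0.1, bad, mass)
        assert not np.isfinite(out.hamiltonian)

    def test_energy_error_scales_second_order(self):
        # max |Delta H| over a fixed trajectory drops ~4x when eps halves
        target = _harmonic()
        mass = MassMatrix.identity(1)

        def max_dh(eps, n_steps):
            s = _state([1.0], [1.0], target, mass)
            h0 = s.hamiltonian
            worst = 0.0
            for _ in range(n_steps):
                s = leapfrog_step(s, eps, target, mass)
                worst = max(worst, abs(s.hamiltonian - h0))
            return worst

        ratio = max_dh(0.2, 50) / max_dh(0.1, 100)
        assert 3.0 < ratio < 5.0


class TestHMCDraw:
    def test_zero_energy_error_always_accepts(self, rng):
        # constant potential: leapfrog conserves H exactly -> accept prob 1
        flat = CallableTarget(U=lambda z: 0.0, grad=lambda z: np.zeros_like(z))
        cfg = SamplerConfig(step_size=0.3, n_leapfrog=5, n_iterations=10,
                            n_burn_in=0)
        accepted = [hmc_draw(np.zeros(2), cfg, flat, MassMatrix.identity(2),
                             rng)[1] for _ in range(50)]
        assert all(accepted)

    def test_standard_normal_moments(self, rng):
        target = _harmonic()
        cfg = SamplerConfig(step_size=0.5, n_leapfrog=8, n_iterations=10,
                            n_burn_in=0)
        mass = MassMatrix.identity(1)
        x = np.array([0.0])
        draws = np.empty(20_000)
        for t in range(draws.size):
            x, _, _, _ = hmc_draw(x, cfg, target, mass, rng)
            draws[t] = x[0]
        # HMC draws are nearly independent here; allow 4 nominal s.e.
        assert abs(draws.mean()) < 4 / np.sqrt(draws.size)
        assert abs(draws.var() - 1.0) < 4 * np.sqrt(2.0 / draws.size)

    def test_correlated_gaussian_covariance(self, rng):
        cov = np.array([[1.0, 0.9], [0.9, 1.0]])
        target = gaussian_target(cov)
        cfg = SamplerConfig(step_size=0.15, n_leapfrog=12, n_iterations=10,
                            n_burn_in=0)
        mass = MassMatrix.identity(2)
        x = np.zeros(2)
        draws = np.empty((20_000, 2))
        for t in range(draws.shape[0]):
            x, _, _, _ = hmc_draw(x, cfg, target, mass, rng)
            draws[t] = x
        emp = np.cov(draws.T)
        # correlated components mix slower; 6 nominal s.e. margin
        assert np.all(np.abs(emp - cov) < 6 * np.sqrt(2.0 / 20_000) * 4)


class TestNUTS:
    def test_standard_normal_moments(self, rng):
        target = _harmonic()
        mass = MassMatrix.identity(1)
        x = np.array([0.0])
        draws = np.empty(20_000)
        for t in range(draws.size):
            x, _ = nuts_draw(x, 0.5, target, mass, 8, rng)
            draws[t] = x[0]
        assert abs(draws.mean()) < 4 / np.sqrt(draws.size)
        assert abs(draws.var() - 1.0) < 4 * np.sqrt(2.0 / draws.size)

    def test_pathological_step_size_stays_finite(self, rng):
        target = _harmonic()
        mass = MassMatrix.identity(1)
        x = np.array([0.5])
        n_div = 0
        for _ in range(100):
            x, info = nuts_draw(x, 10.0, target, mass, 8, rng)
            n_div += info["divergent"]
            assert np.all(np.isfinite(x))
        assert n_div > 0  # flags raised, chain still healthy

    def test_same_seed_reproduces_draw_sequence(self):
        target = gaussian_target([[1.0, 0.5], [0.5, 1.5]])
        mass = MassMatrix.identity(2)

        def seq(seed):
            rng = np.random.default_rng(seed)
            x = np.zeros(2)
            out = []
            for _ in range(30):
                x, _ = nuts_draw(x, 0.4, target, mass, 8, rng)
                out.append(x.copy())
            return np.array(out)

        np.testing.assert_array_equal(seq(7), seq(7))


class TestDualAveraging:
    def test_persistent_acceptance_raises_step(self):
        da = DualAveraging(0.1, target_accept=0.8)
        eps = [da.update(1.0) for _ in range(50)]
        assert np.all(np.diff(eps) > 0)

    def test_persistent_rejection_lowers_step(self):
        da = DualAveraging(0.1, target_accept=0.8)
        eps = [da.update(0.0) for _ in range(50)]
        assert np.all(np.diff(eps) < 0)

    def test_adapted_acceptance_near_target(self):
        # anharmonic target (a pure Gaussian has leapfrog resonances that
        # make acceptance non-monotonic in the step size)
        target = CallableTarget(
            U=lambda z: 0.5 * float(z @ z) + 0.25 * float(np.sum(z**4)),
            grad=lambda z: z + z**3)
        cfg = SamplerConfig(step_size=1.5, n_leapfrog=5, n_iterations=3000,
                            n_burn_in=1000, seed=11, target_accept=0.8,
                            adaptation="dual_averaging")
        chain = run_chain(np.zeros(2), cfg, target, kernel="hmc")
        assert abs(chain.acceptance_rate - 0.8) < 0.1


class TestMassAdaptation:
    def test_degenerate_draws_floored(self):
        draws = np.ones((50, 2))
        mass = adapt_mass_matrix(draws, "inverse_variance_diag")
        assert np.all(np.isfinite(mass.diag)) and np.all(mass.diag > 0)

    def test_inverse_variance_matches_sample_oracle(self, rng):
        draws = rng.normal(0.0, [1.0, 10.0], size=(20_000, 2))
        mass = adapt_mass_matrix(draws, "inverse_variance_diag")
        expected = 1.0 / draws.var(axis=0)
        np.testing.assert_allclose(mass.diag, expected, rtol=1e-12)
        np.testing.assert_allclose(mass.diag, [1.0, 0.01], rtol=0.1)

    def test_gradient_scaling_bins_to_two_levels(self, rng):
        # 6 high-gradient coordinates vs 4 low ones -> diagonal {400, 1}
        scale = np.array([400.0] * 6 + [1.0] * 4)
        draws = rng.standard_normal((40, 10))
        mass = adapt_mass_matrix(draws, "gradient_scaled_diag",
                                 grad_probe=lambda z: scale * np.sign(z))
        assert set(np.unique(mass.diag)) == {1.0, 400.0}

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError):
            adapt_mass_matrix(np.ones((5, 2)), "inverse_variance_diag")


class TestRunChain:
    def test_no_burn_in_means_no_adaptation(self):
        target = gaussian_target(np.eye(1))
        cfg = SamplerConfig(step_size=0.3, n_iterations=100, n_burn_in=0,
                            seed=2, adaptation="dual_averaging")
        chain = run_chain(np.zeros(1), cfg, target, kernel="hmc")
        assert np.all(chain.step_size_trace == 0.3)

    def test_same_seed_bit_identical(self):
        target = gaussian_target([[1.0, 0.3], [0.3, 1.0]])
        cfg = SamplerConfig(step_size=0.4, n_iterations=200, n_burn_in=50,
                            seed=5)
        a = run_chain(np.zeros(2), cfg, target, kernel="nuts")
        b = run_chain(np.zeros(2), cfg, target, kernel="nuts")
        np.testing.assert_array_equal(a.draws, b.draws)
        np.testing.assert_array_equal(a.accepted, b.accepted)

    def test_random_walk_metropolis_textbook_behavior(self):
        target = gaussian_target(np.eye(1))
        cfg = SamplerConfig(n_iterations=20_000, n_burn_in=1000, seed=9)
        chain = run_chain(np.zeros(1), cfg, target, kernel="random_walk",
                          rw_scale=2.4)
        post = chain.posterior()[:, 0]
        # optimal-scaling acceptance for 1-D Gaussian is ~0.44
        assert 0.25 < chain.acceptance_rate < 0.6
        assert abs(post.mean()) < 0.1
        assert abs(post.var() - 1.0) < 0.15

    def test_rejected_draw_repeats_previous_state(self):
        target = gaussian_target(np.eye(2))
        cfg = SamplerConfig(step_size=1.9, n_leapfrog=10, n_iterations=400,
                            n_burn_in=0, seed=3, adaptation="none")
        chain = run_chain(np.zeros(2), cfg, target, kernel="hmc")
        rejected = np.where(~chain.accepted[1:])[0] + 1
        assert rejected.size > 0
        for t in rejected:
            np.testing.assert_array_equal(chain.draws[t], chain.draws[t - 1])

    def test_chain_length_consistency_enforced(self):
        with pytest.raises(ValueError):
            Chain(np.zeros((5, 1)), np.zeros(4, bool), np.zeros(5),
                  np.zeros(5), np.zeros(5), np.zeros(5, bool), 1)


class TestConstraintReflection:
    def test_axis_mirror(self):
        s = PhaseState(np.zeros(2), np.array([1.0, 2.0]), 0.0, 2.5)
        out = reflect_at_constraint(s, np.array([1.0, 0.0]))
        np.testing.assert_allclose(out.momentum, [-1.0, 2.0])
        assert out.kinetic == s.kinetic

    def test_householder_oracle_diagonal_normal(self):
        s = PhaseState(np.zeros(2), np.array([1.0, 0.0]), 0.0, 0.5)
        n = np.array([1.0, 1.0]) / np.sqrt(2.0)
        out = reflect_at_constraint(s, n)
        np.testing.assert_allclose(out.momentum, [0.0, -1.0], atol=1e-15)

    def test_parallel_momentum_unchanged(self):
        s = PhaseState(np.zeros(2), np.array([0.0, 3.0]), 0.0, 4.5)
        out = reflect_at_constraint(s, np.array([1.0, 0.0]))
        np.testing.assert_allclose(out.momentum, s.momentum)

    def test_kinetic_energy_preserved(self, rng):
        for _ in range(10):
            p = rng.standard_normal(4)
            n = rng.standard_normal(4)
            s = PhaseState(np.zeros(4), p, 0.0, 0.5 * p @ p)
            out = reflect_at_constraint(s, n)
            assert 0.5 * out.momentum @ out.momentum == pytest.approx(s.kinetic)

    def test_zero_normal_rejected(self):
        s = PhaseState(np.zeros(2), np.ones(2), 0.0, 1.0)
        with pytest.raises(ValueError):
            reflect_at_constraint(s, np.zeros(2))


def test_rw_proposal_scale_uses_optimal_scaling(rng):
    draws = rng.normal(0.0, [2.0, 0.5], size=(50_000, 2))
    scale = rw_proposal_scale(draws)
    np.testing.assert_allclose(scale, [2.0, 0.5] * np.array(2.4 / np.sqrt(2)),
                               rtol=0.05)


class TestReflectionProperties:
    """Property tests: the constraint bounce is an isometric involution."""

    from hypothesis import given, settings, strategies as st

    vec = st.lists(st.floats(-10, 10), min_size=3, max_size=3).map(np.array)

    @given(p=vec, n=vec)
    @settings(max_examples=60, derandomize=True)
    def test_involution_and_energy(self, p, n):
        if float(n @ n) < 1e-6:
            return
        s = PhaseState(np.zeros(3), p, 0.0, 0.5 * float(p @ p))
        once = reflect_at_constraint(s, n)
        twice = reflect_at_constraint(once, n)
        np.testing.assert_allclose(twice.momentum, p, atol=1e-9)
        assert 0.5 * float(once.momentum @ once.momentum) == pytest.approx(
            s.kinetic, abs=1e-9)
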