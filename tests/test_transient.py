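import numpy as np
import pytest

from _oracles import (damping_ratio_eig, kreiss_grid_oracle, maxamp_brute,
                      power_iteration_lambda, random_primitive,
                      simulate_lifetime_offspring)
from coralipm import transient
from coralipm.transient import (asymptotic_growth, compute_all, damping_ratio,
                                generation_time, kreiss_bounds,
                                max_amplification, transient_envelope)

PERIODIC = np.array([[0.0, 2.0], [0.5, 0.0]])  # eigenvalues +1, -1
AMPLIFIER = np.array([[0.1, 2.0], [0.4, 0.3]])


class TestAsymptoticGrowth:
    def test_diagonal(self):
        with pytest.warns(UserWarning, match="reducible"):
            assert asymptotic_growth(np.diag([0.5, 0.2])) == pytest.approx(0.5)

    def test_periodic_matrix(self):
        assert asymptotic_growth(PERIODIC) == pytest.approx(1.0)

    def test_matches_power_iteration_on_200x200(self):
        K = random_primitive(np.random.default_rng(1), 200)
        assert asymptotic_growth(K) == pytest.approx(
            power_iteration_lambda(K), abs=1e-10)

    def test_scaling_covariance(self):
        K = random_primitive(np.random.default_rng(2), 20)
        lam = asymptotic_growth(K)
        assert asymptotic_growth(3.5 * K) == pytest.approx(3.5 * lam)
        assert damping_ratio(3.5 * K) == pytest.approx(damping_ratio(K))


class TestDampingRatio:
    def test_diagonal_closed_form(self):
        assert damping_ratio(np.diag([0.8, 0.4])) == pytest.approx(2.0)

    def test_imprimitive_ratio_one(self):
        assert damping_ratio(PERIODIC) == pytest.approx(1.0)
        m = compute_all(PERIODIC, np.zeros((2, 2)))
        assert m.flags.get("imprimitive")

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            K = random_primitive(rng, 50)
            assert damping_ratio(K) == pytest.approx(damping_ratio_eig(K),
                                                     abs=1e-10)


class TestGenerationTime:
    def test_scalar_closed_form(self):
        R0, T = generation_time([[0.5]], [[0.6]])
        assert R0 == pytest.approx(1.2)
        assert T == pytest.approx(np.log(1.2) / np.log(1.1))

    def test_no_reproduction_flagged(self):
        R0, T = generation_time([[0.5]], [[0.0]])
        assert R0 == 0.0 and np.isnan(T)

    def test_supercritical_transient_part_rejected(self):
        with pytest.raises(ValueError, match="spectral radius"):
            generation_time([[1.01]], [[0.1]])

    def test_sign_consistency_R0_lambda(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            P = random_primitive(rng, 8, target_radius=rng.uniform(0.3, 0.9))
            F = random_primitive(rng, 8) * rng.uniform(0.001, 0.1)
            R0, _ = generation_time(P, F)
            lam = asymptotic_growth(P + F)
            assert np.sign(R0 - 1) == np.sign(lam - 1)

    def test_R0_matches_lifetime_offspring_simulation(self, fitted_rates):
        import dataclasses
        from coralipm.kernel import build_kernel
        from coralipm.vital_rates import PolyLogistic
        rates = dataclasses.replace(
            fitted_rates,
            fragmentation=PolyLogistic(np.array([-60.0, 0.0, 0.0]), None, 2))
        k = build_kernel(rates, 80)
        R0, _ = generation_time(k.P, k.F)
        c0 = k.F[:, 0] / k.F[:, 0].sum()  # F is rank one: outer(c0, fvec)
        fvec = k.F.sum(axis=0)
        mc = simulate_lifetime_offspring(k.P, c0, fvec, 400_000,
                                         np.random.default_rng(9))
        assert mc == pytest.approx(R0, rel=0.02)


class TestMaxAmplification:
    def test_scalar_kernel_no_amplification(self):
        assert max_amplification(np.array([[0.7]])) == pytest.approx(1.0)

    def test_normalized_diagonal_never_amplifies(self):
        with pytest.warns(UserWarning):
            assert max_amplification(np.diag([0.8, 0.4])) == pytest.approx(1.0)

    def test_matches_brute_force_enumeration(self):
        assert max_amplification(AMPLIFIER) == pytest.approx(
            maxamp_brute(AMPLIFIER, 1000), abs=1e-10)

    def test_periodic_matrix_never_settles(self):
        with pytest.raises(RuntimeError, match="settle"):
            max_amplification(PERIODIC, t_cap=500)


class TestKreissBounds:
    def test_scalar_kernel_unit_bounds(self):
        ku, kl = kreiss_bounds(np.array([[0.7]]))
        assert ku == 1.0 and kl == 1.0
        assert transient_envelope(np.array([[0.7]])) == 0.0

    def test_reducible_diagonal_lower_limit_zero(self):
        with pytest.warns(UserWarning, match="reducible"):
            ku, kl, diag = kreiss_bounds(np.diag([0.8, 0.4]), full=True)
        assert ku == pytest.approx(1.0, abs=1e-6)
        assert kl < 1e-5 and diag["lower_boundary"]

    def test_matches_dense_grid_oracle_2x2(self):
        ku, kl = kreiss_bounds(AMPLIFIER)
        oku, okl = kreiss_grid_oracle(AMPLIFIER)
        assert ku == pytest.approx(oku, abs=1e-6)
        assert kl == pytest.approx(okl, abs=1e-6)

    def test_matches_oracle_on_random_matrices(self):
        rng = np.random.default_rng(7)
        for n in (3, 10, 25):
            K = random_primitive(rng, n)
            ku, kl = kreiss_bounds(K)
            oku, okl = kreiss_grid_oracle(K, n_points=20_000)
            assert ku == pytest.approx(oku, abs=1e-6)
            assert kl == pytest.approx(okl, abs=1e-6)


class TestComputeAll:
    def test_scalar_kernel_consistent_bundle(self):
        m = compute_all([[0.5]], [[0.6]])
        assert m.lam == pytest.approx(1.1)
        assert m.R0 == pytest.approx(1.2)
        assert m.generation_time == pytest.approx(np.log(1.2) / np.log(1.1))
        assert m.max_amplification == pytest.approx(1.0)
        assert m.kreiss_upper == 1.0 and m.kreiss_lower == 1.0
        assert m.transient_envelope == 0.0

    def test_invariant_chain_on_random_kernels(self):
        rng = np.random.default_rng(11)
        for _ in range(40):
            n = int(rng.integers(2, 12))
            P = random_primitive(rng, n, target_radius=rng.uniform(0.2, 0.9))
            F = random_primitive(rng, n) * rng.uniform(0.01, 0.5)
            m = compute_all(P, F)
            assert m.damping_ratio >= 1.0 - 1e-12
            assert m.kreiss_lower <= 1.0 + 1e-9 <= m.kreiss_upper + 1e-9
            assert m.kreiss_upper <= m.max_amplification + 1e-6
            assert m.transient_envelope >= -1e-12
            assert np.sign(m.R0 - 1) == np.sign(m.lam - 1)

    def test_reducible_matrix_flagged_not_crashed(self):
        P = np.diag([0.8, 0.4])
        F = np.zeros((2, 2))
        m = compute_all(P, F)
        assert not m.irreducible and not m.primitive
        assert m.flags  # at least one metric flagged

    def test_weedy_envelope_exceeds_stress_tolerant(self, strategy_kernels):
        te_weedy = transient_envelope(strategy_kernels["weedy"].K)
        te_stress = transient_envelope(strategy_kernels["stress_tolerant"].K)
        assert te_weedy > te_stress
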