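import numpy as np
import pytest

from bznmf.model import (
    Factorization,
    SignalMatrix,
    TimeGrid,
    kl_objective,
    lse_objective,
)
from bznmf.simulate import SimulationConfig, simulate_matrix
from bznmf.updates import (
    FitConfig,
    fit,
    fit_coeffs,
    fit_free_nmf_lse,
    kl_tau_gradient,
    lse_tau_gradient,
    update_coeffs_kl,
    update_coeffs_lse,
    update_taus_kl,
    update_taus_lse,
)
from conftest import exact_instance, random_instance

COEFF_UPDATES = {"lse": update_coeffs_lse, "kl": update_coeffs_kl}
TAU_UPDATES = {"lse": update_taus_lse, "kl": update_taus_kl}
GRADIENTS = {"lse": lse_tau_gradient, "kl": kl_tau_gradient}
OBJECTIVES = {"lse": lse_objective, "kl": kl_objective}


@pytest.mark.parametrize("kind", ["lse", "kl"])
class TestFixedPoints:
    def test_coeff_update_fixed_at_exact_fit(self, rng, kind):
        I, f = exact_instance(rng)
        np.testing.assert_allclose(
            COEFF_UPDATES[kind](I, f), f.coeffs, rtol=1e-9
        )

    def test_tau_update_fixed_at_exact_fit(self, rng, kind):
        I, f = exact_instance(rng)
        np.testing.assert_allclose(TAU_UPDATES[kind](I, f), f.taus, rtol=1e-9)

    def test_zero_coefficients_stay_zero(self, rng, kind):
        I, f = random_instance(rng)
        coeffs = f.coeffs.copy()
        coeffs[1, :] = 0.0
        coeffs[0, 2] = 0.0
        f = Factorization(f.taus, coeffs, f.grid)
        h_new = COEFF_UPDATES[kind](I, f)
        assert np.all(h_new[1, :] == 0.0)
        assert h_new[0, 2] == 0.0

    def test_nonnegativity_preserved(self, rng, kind):
        I, f = random_instance(rng)
        for _ in range(30):
            taus = TAU_UPDATES[kind](I, f, 1e-6, 1e6)
            f = Factorization(taus, f.coeffs, f.grid)
            f = Factorization(taus, COEFF_UPDATES[kind](I, f), f.grid)
        assert np.all(f.coeffs >= 0)
        assert np.all(f.taus > 0)


class TestLseCoeffHandValue:
    def test_near_scalar_instance(self):
        # M=2 with the second time far out so it contributes ~nothing:
        # w ~ (0.5, 0), I = (1, 0) -> h' = h * (w.I)/(w.w h) = 1*0.5/0.25 = 2
        tau = 10.0 / np.log(2.0)  # exp(-10/tau) = 0.5
        g = TimeGrid(np.array([10.0, 1e4]))
        f = Factorization(np.array([tau]), np.array([[1.0]]), g)
        I = SignalMatrix(np.array([[1.0], [0.0]]), g)
        h_new = update_coeffs_lse(I, f)
        assert h_new[0, 0] == pytest.approx(2.0, rel=1e-10)


@pytest.mark.parametrize("kind", ["lse", "kl"])
class TestGradients:
    def test_analytic_matches_central_difference(self, rng, kind):
        objective = OBJECTIVES[kind]
        for _ in range(5):
            I, f = random_instance(rng)
            grad = GRADIENTS[kind](I, f)
            fd = np.zeros_like(grad)
            for r in range(f.rank):
                h = 1e-6 * f.taus[r]
                tp, tm = f.taus.copy(), f.taus.copy()
                tp[r] += h
                tm[r] -= h
                fd[r] = (
                    objective(I, Factorization(tp, f.coeffs, f.grid))
                    - objective(I, Factorization(tm, f.coeffs, f.grid))
                ) / (2 * h)
            np.testing.assert_allclose(grad, fd, rtol=1e-4, atol=1e-12)

    def test_update_moves_against_gradient(self, rng, kind):
        for _ in range(10):
            I, f = random_instance(rng)
            grad = GRADIENTS[kind](I, f)
            taus_new = TAU_UPDATES[kind](I, f, 1e-9, 1e9)
            moved = np.abs(taus_new - f.taus) > 1e-12 * f.taus
            signs_ok = np.sign(taus_new - f.taus) == -np.sign(grad)
            assert np.all(signs_ok | ~moved)


@pytest.mark.parametrize("kind", ["lse", "kl"])
def test_objective_monotone_under_alternating_updates(kind):
    """Alternating multiplicative updates never increase the objective
    (empirically, to 1e-9 relative slack) on random instances."""
    objective = OBJECTIVES[kind]
    worst = 0.0
    for seed in range(100):
        rng = np.random.default_rng(seed)
        I, f = random_instance(rng, m=6, n=4, r=2)
        d = objective(I, f)
        for _ in range(25):
            taus = TAU_UPDATES[kind](I, f, 1e-9, 1e9)
            f = Factorization(taus, f.coeffs, f.grid)
            f = Factorization(taus, COEFF_UPDATES[kind](I, f), f.grid)
            d_new = objective(I, f)
            worst = max(worst, (d_new - d) / (1.0 + abs(d)))
            d = d_new
    assert worst <= 1e-9


class TestFit:
    def test_rank1_noise_free_exact_recovery(self):
        cfg = SimulationConfig(
            sim_rank=1, dims=60, n_sequences=10, noise_half_width=0.0,
            taus_true=np.array([100.0]), ratios_true=np.array([1.0]), seed=0,
        )
        I, truth, _ = simulate_matrix(cfg)
        res = fit(I, 1, FitConfig(seed=1))
        assert res.factorization.taus[0] == pytest.approx(100.0, rel=1e-3)
        assert res.objective_value < 1e-8

    def test_rank2_noise_free_recovery_within_1pct(self):
        cfg = SimulationConfig(sim_rank=2, dims=75, noise_half_width=0.0,
                               n_sequences=20, seed=0)
        I, truth, _ = simulate_matrix(cfg)
        res = fit(I, 2, FitConfig(seed=1))
        np.testing.assert_allclose(
            res.factorization.taus, [10.0, 100.0], rtol=1e-2
        )

    def test_rank3_noise_free_recovery_and_ratios(self):
        cfg = SimulationConfig(sim_rank=3, dims=145, noise_half_width=0.0,
                               n_sequences=20, seed=0)
        I, truth, _ = simulate_matrix(cfg)
        res = fit(I, 3, FitConfig(seed=1))
        np.testing.assert_allclose(
            res.factorization.taus, [10.0, 100.0, 1000.0], rtol=1e-2
        )
        ratios = res.factorization.coeffs / res.factorization.coeffs.sum(axis=0)
        np.testing.assert_allclose(ratios, 1.0 / 3.0, rtol=1e-2)

    def test_result_is_canonical_and_trace_consistent(self, rng):
        I, _ = random_instance(rng, m=12, n=6, r=3, t_hi=200.0)
        res = fit(I, 3, FitConfig(seed=2, max_iterations=200))
        f = res.factorization
        assert f.is_canonical
        assert res.objective_value == res.objective_trace[-1]
        d = res.objective_trace
        assert np.all(d[1:] <= d[:-1] + 1e-9 * (1 + d[:-1]))

    def test_all_zero_matrix_rejected(self):
        g = TimeGrid(np.array([1.0, 2.0, 3.0]))
        I = SignalMatrix(np.zeros((3, 2)), g)
        with pytest.raises(ValueError):
            fit(I, 1, FitConfig())

    def test_same_seed_reproducible(self, rng):
        I, _ = random_instance(rng, m=10, n=4, r=2, t_hi=100.0)
        r1 = fit(I, 2, FitConfig(seed=7, max_iterations=300))
        r2 = fit(I, 2, FitConfig(seed=7, max_iterations=300))
        np.testing.assert_array_equal(
            r1.factorization.taus, r2.factorization.taus
        )

    def test_fit_coeffs_holds_taus_fixed(self, rng):
        I, f = exact_instance(rng, m=10, n=6, r=2)
        fitted = fit_coeffs(I, f.taus, FitConfig(seed=3, max_iterations=2000))
        assert np.array_equal(fitted.taus, f.taus)
        assert lse_objective(I, fitted) < 1e-6


class TestFreeNMF:
    def test_converges_to_exact_product(self, rng):
        I, f = exact_instance(rng)
        res = fit_free_nmf_lse(I, 2, FitConfig(seed=1, max_iterations=2000))
        # free NMF can represent the exact rank-2 product
        assert res.objective_value < 1e-3 * res.objective_trace[0]

    def test_objective_non_increasing(self, rng):
        I, _ = random_instance(rng, m=10, n=6, r=2)
        res = fit_free_nmf_lse(I, 3, FitConfig(seed=1, max_iterations=100))
        d = res.objective_trace
        assert np.all(d[1:] <= d[:-1] + 1e-9 * (1 + d[:-1]))

    def test_basis_unconstrained_not_exponential(self):
        # on noisy two-component data the learned free basis columns need not
        # be monotone decays; just check non-negativity of the factors
        cfg = SimulationConfig(sim_rank=2, dims=40, n_sequences=10, seed=4)
        I, _, _ = simulate_matrix(cfg)
        res = fit_free_nmf_lse(I, 2, FitConfig(seed=1, max_iterations=300))
        assert np.all(res.basis >= 0)
        assert np.all(res.coeffs >= 0)
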