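"""Slab-diffusion simulator: series solution, PDE oracle, seeded noise."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from skinperm import (
    DEFAULT_SCHEDULE_H,
    CellGeometry,
    MembraneParams,
    NoiseModel,
    ValidationError,
    analyze_franz_run,
    cumulative_amounts,
    membrane_flux_series,
    simulate_franz_run,
    simulate_retention,
)


def pde_cumulative(params, cd, area, times, n_nodes=100):
    """Finite-difference slab diffusion oracle, independent of the series.

    Method-of-lines on n_nodes interior points with fixed boundary
    concentrations K*Cd (donor face) and 0 (receptor face); the state is
    augmented with the cumulative amount through the receptor face.
    """
    d, ell, k = params.diffusivity, params.thickness, params.partition
    h = ell / (n_nodes + 1)
    c0 = k * cd

    def rhs(_t, y):
        c = y[:-1]
        dc = np.empty_like(c)
        dc[0] = d * (c0 - 2 * c[0] + c[1]) / h**2
        dc[1:-1] = d * (c[:-2] - 2 * c[1:-1] + c[2:]) / h**2
        dc[-1] = d * (c[-2] - 2 * c[-1] + 0.0) / h**2
        # outward flux at the receptor face (C=0 there), one-sided 2nd order
        flux = -d * (3 * 0.0 - 4 * c[-1] + c[-2]) / (2 * h)
        return np.concatenate([dc, [area * flux]])

    y0 = np.zeros(n_nodes + 1)
    sol = solve_ivp(
        rhs, (0.0, max(times)), y0, t_eval=times, method="BDF",
        rtol=1e-8, atol=1e-12,
    )
    return sol.y[-1]


class TestSeriesSolution:
    def test_zero_donor_concentration(self, membrane):
        q = membrane_flux_series(membrane, 0.0, 0.6, DEFAULT_SCHEDULE_H)
        assert np.all(q == 0.0)

    def test_asymptotic_steady_state_slope(self, membrane):
        """dQ/dt approaches area * kp * Cd far beyond the lag time."""
        cd, area = 1000.0, 0.6
        t = np.array([50 * membrane.lag_time, 50 * membrane.lag_time + 1.0])
        q = membrane_flux_series(membrane, cd, area, t)
        slope = (q[1] - q[0]) / (t[1] - t[0])
        assert slope == pytest.approx(area * membrane.kp * cd, rel=1e-3)

    def test_series_matches_finite_difference_oracle(self, membrane):
        cd, area = 1000.0, 0.6
        q_series = membrane_flux_series(membrane, cd, area, DEFAULT_SCHEDULE_H)
        q_pde = pde_cumulative(membrane, cd, area, DEFAULT_SCHEDULE_H)
        rel = np.abs(q_series - q_pde) / np.abs(q_series)
        assert np.all(rel < 1e-3)

    def test_non_negative_and_non_decreasing(self):
        params = MembraneParams(diffusivity=0.002, thickness=0.08, partition=3.0)
        t = np.linspace(0.01, 30, 200)
        q = membrane_flux_series(params, 500.0, 0.6, t)
        assert np.all(q >= 0)
        assert np.all(np.diff(q) >= 0)

    def test_lag_only_delays_never_exceeds_envelope(self, membrane):
        """Q(t) stays below the through-origin steady-state envelope."""
        cd, area = 1000.0, 0.6
        t = np.linspace(0.01, 24, 100)
        q = membrane_flux_series(membrane, cd, area, t)
        envelope = area * membrane.kp * cd * t
        assert np.all(q < envelope)


@pytest.mark.filterwarnings("ignore:cumulative transfer")
class TestSimulateFranzRun:
    def test_zero_noise_reconstruction_is_exact(self, membrane, geometry):
        run, truth = simulate_franz_run(membrane, geometry, 2500.0)
        _, q, _ = cumulative_amounts(run)
        np.testing.assert_allclose(q, truth.q_true, rtol=0, atol=1e-9)

    @pytest.mark.filterwarnings("ignore::UserWarning")
    @pytest.mark.parametrize("kp_true", [1e-3, 1e-2, 1e-1])
    def test_noise_free_kp_recovery_within_5_percent(self, kp_true, geometry):
        params = MembraneParams.from_permeability(kp_true, lag_time=0.1)
        cd = 1000.0
        run, truth = simulate_franz_run(params, geometry, cd)
        res = analyze_franz_run(run)
        kp_est = res.steady_state_flux / cd
        assert abs(kp_est / truth.kp_cm_per_h - 1) < 0.05

    @pytest.mark.filterwarnings("ignore::UserWarning")
    def test_noisy_kp_recovery_unbiased(self, membrane, geometry):
        """500 seeded replicates at sigma = 0.05: |bias| < 2%."""
        cd = 2500.0
        estimates = []
        for seed in range(500):
            run, _ = simulate_franz_run(
                membrane, geometry, cd,
                noise=NoiseModel(sigma_rel=0.05, seed=seed),
            )
            res = analyze_franz_run(run)
            estimates.append(res.steady_state_flux / cd)
        bias = np.mean(estimates) / membrane.kp - 1
        assert abs(bias) < 0.02

    def test_same_seed_bit_identical_different_seed_not(self, membrane, geometry):
        noise = NoiseModel(sigma_rel=0.1, seed=123)
        run1, _ = simulate_franz_run(membrane, geometry, 2500.0, noise=noise)
        run2, _ = simulate_franz_run(membrane, geometry, 2500.0, noise=noise)
        run3, _ = simulate_franz_run(
            membrane, geometry, 2500.0, noise=NoiseModel(sigma_rel=0.1, seed=124)
        )
        assert run1.samples == run2.samples
        assert run1.samples != run3.samples

    def test_lod_censoring_applied(self, membrane, geometry):
        run, _ = simulate_franz_run(
            membrane, geometry, 2500.0, noise=NoiseModel(lod=1e9)
        )
        assert all(s.censored for s in run.samples)

    @pytest.mark.filterwarnings("ignore::UserWarning")
    def test_kp_sweep_recovery(self, geometry):
        """Seeded kp sweep, zero noise, lag < 0.5 h: recovery within 5%."""
        rng = np.random.default_rng(7)
        for _ in range(10):
            kp_true = 10 ** rng.uniform(-4, np.log10(0.5))
            lag = rng.uniform(0.01, 0.45)
            params = MembraneParams.from_permeability(kp_true, lag)
            run, _ = simulate_franz_run(params, geometry, 1000.0)
            res = analyze_franz_run(run)
            kp_est = res.steady_state_flux / 1000.0
            assert abs(kp_est / kp_true - 1) < 0.05


class TestSimulateRetention:
    def test_noise_free_inversion(self):
        from skinperm import extrapolate_logkw

        ms = simulate_retention(2.0, -5.0, 2.0, [0.1, 0.2, 0.3])
        fit = extrapolate_logkw(ms)
        assert fit.log_kw == pytest.approx(2.0, abs=1e-12)
        assert fit.slope == pytest.approx(-5.0, abs=1e-12)

    def test_deterministic_retention_times(self):
        # realistic magnitude: the most lipophilic ester in the benchmark
        ms = simulate_retention(2.292, -6.0, 2.0, [0.1, 0.2, 0.3])
        expected = [2 * (1 + 10 ** (2.292 - 6.0 * phi)) for phi in (0.1, 0.2, 0.3)]
        assert [m.t_r for m in ms] == pytest.approx(expected)

    def test_phi_zero_rejected(self):
        with pytest.raises(ValidationError):
            simulate_retention(2.0, -5.0, 2.0, [0.0, 0.1, 0.2])
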