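"""Franz-cell metrics: correction formula, fluxes, Kp and aggregation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from skinperm import (
    CellGeometry,
    FranzRun,
    InsufficientDataError,
    SamplePoint,
    ValidationError,
    aggregate_replicates,
    analyze_franz_run,
    cumulative_amounts,
    flux_profile,
    kp_log_cm_per_s,
    max_flux,
    permeability_coefficient,
    total_absorption_percent,
)


def make_run(concentrations, times=None, sample_volume=0.5, cd=1000.0,
             censored=None, compound="MP", cell_id="c1"):
    times = times or [0.5 * (i + 1) for i in range(len(concentrations))]
    censored = censored or [False] * len(concentrations)
    return FranzRun(
        cell_id=cell_id,
        compound=compound,
        geometry=CellGeometry(sample_volume=sample_volume),
        donor_concentration=cd,
        samples=tuple(
            SamplePoint(t, c, z) for t, c, z in zip(times, concentrations, censored)
        ),
    )


class TestCumulativeAmounts:
    def test_withdrawal_replacement_correction(self):
        # V_r = 5, V_s = 0.5: Q = [5*1, 5*2 + 0.5*1] = [5, 10.5]
        _, q, _ = cumulative_amounts(make_run([1, 2]))
        assert q == pytest.approx([5.0, 10.5])

    def test_all_zero_concentrations(self):
        _, q, _ = cumulative_amounts(make_run([0, 0, 0]))
        assert q == pytest.approx([0, 0, 0])

    def test_no_withdrawal_limit(self):
        _, q, _ = cumulative_amounts(make_run([1, 1], sample_volume=0.0))
        assert q == pytest.approx([5.0, 5.0])

    def test_censored_points_contribute_zero_mass(self):
        _, q, cens = cumulative_amounts(
            make_run([1, 2], censored=[True, False])
        )
        assert q == pytest.approx([0.0, 10.0])
        assert list(cens) == [True, False]

    @given(
        concs=st.lists(st.floats(min_value=0, max_value=100), min_size=1, max_size=10),
        factor=st.floats(min_value=0.1, max_value=10),
    )
    @settings(derandomize=True, max_examples=100, deadline=None)
    def test_scale_equivariance(self, concs, factor):
        """Doubling concentrations doubles Q (and hence J and %)."""
        _, q1, _ = cumulative_amounts(make_run(concs))
        _, q2, _ = cumulative_amounts(make_run([c * factor for c in concs]))
        np.testing.assert_allclose(q2, q1 * factor, rtol=1e-12, atol=1e-12)


class TestFluxProfile:
    def test_first_interval_from_origin(self):
        j = flux_profile(np.array([0.5]), np.array([5.0]), area=0.6)
        assert j == pytest.approx([5.0 / (0.6 * 0.5)])

    def test_constant_q_gives_zero_later_fluxes(self):
        j = flux_profile(np.array([1, 2, 3.0]), np.array([4, 4, 4.0]), area=0.6)
        assert j[0] > 0
        assert j[1:] == pytest.approx([0.0, 0.0])

    def test_linear_q_gives_constant_flux_any_partition(self):
        times = np.array([0.5, 1, 2, 3, 4, 5, 6, 24.0])
        c = 7.3
        j = flux_profile(times, c * times, area=0.6)
        np.testing.assert_allclose(j, c / 0.6, rtol=1e-12)

    def test_non_increasing_times_rejected(self):
        with pytest.raises(ValidationError):
            flux_profile(np.array([1.0, 1.0]), np.array([1.0, 2.0]), area=0.6)


class TestScalarMetrics:
    def test_max_flux(self):
        assert max_flux([2, 7, 3]) == 7
        assert max_flux([4.2]) == 4.2
        with pytest.raises(InsufficientDataError):
            max_flux([])

    def test_permeability_coefficient(self):
        assert permeability_coefficient(10, 1000) == pytest.approx(0.01)
        assert permeability_coefficient(0, 1000) == 0
        # donor concentration back-implied from a published Kp of 0.305 cm/h
        assert permeability_coefficient(76.23, 250) == pytest.approx(0.30492)
        with pytest.raises(ValidationError):
            permeability_coefficient(1.0, 0.0)

    @pytest.mark.parametrize(
        "kp_cm_per_h, expected",
        [(0.012, -5.48), (0.305, -4.07), (9.4e-4, -6.58)],
    )
    def test_log_conversion_reproduces_published_values(self, kp_cm_per_h, expected):
        assert round(kp_log_cm_per_s(kp_cm_per_h), 2) == expected

    def test_log_conversion_nan_propagates_and_nonpositive_errors(self):
        assert math.isnan(kp_log_cm_per_s(math.nan))
        with pytest.raises(ValidationError):
            kp_log_cm_per_s(0.0)

    @given(x=st.floats(min_value=-8, max_value=2))
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_log_conversion_inverts_exponential(self, x):
        assert kp_log_cm_per_s(10**x * 3600.0) == pytest.approx(x, abs=1e-9)

    def test_total_absorption_percent(self):
        assert total_absorption_percent(50, 50) == 100.0
        assert total_absorption_percent(0, 50) == 0.0
        assert total_absorption_percent(9.148, 100) == pytest.approx(9.148)
        with pytest.raises(ValidationError):
            total_absorption_percent(1, 0)

    def test_over_recovery_capped_with_warning(self):
        with pytest.warns(UserWarning, match="capped"):
            assert total_absorption_percent(120, 100) == 100.0


class TestAnalyzeAndAggregate:
    def test_mass_conservation_warning(self):
        # 24 ug recovered from a 10 ug applied dose
        run = make_run([4.0], times=[1.0], cd=10.0, sample_volume=0.0)
        with pytest.warns(UserWarning, match="mass-balance"):
            analyze_franz_run(run)

    def test_kp_equals_max_flux_over_cd(self):
        run = make_run([1, 2, 4], cd=500.0)
        res = analyze_franz_run(run)
        assert res.kp_cm_per_h == pytest.approx(res.max_flux / 500.0)
        assert res.detected

    def test_all_censored_run_is_not_detected(self):
        run = make_run([0.1, 0.1], censored=[True, True])
        res = analyze_franz_run(run)
        assert not res.detected
        assert math.isnan(res.max_flux) and math.isnan(res.kp_cm_per_h)

    def test_aggregate_mean_sd(self):
        runs = [make_run([c], times=[1.0], cell_id=f"c{c}") for c in (1, 2, 3)]
        results = [analyze_franz_run(r) for r in runs]
        # per-cell max flux = 5*c/(0.6*1)
        summary = aggregate_replicates(results, n_boot=200, seed=1)
        assert summary.max_flux_mean == pytest.approx(5 * 2 / 0.6)
        assert summary.max_flux_sd == pytest.approx(np.std([5/0.6, 10/0.6, 15/0.6], ddof=1))

    def test_aggregate_identical_replicates_degenerate_ci(self):
        runs = [make_run([2.0], times=[1.0], cell_id=f"r{i}") for i in range(3)]
        results = [analyze_franz_run(r) for r in runs]
        summary = aggregate_replicates(results, n_boot=500, seed=7)
        assert summary.max_flux_sd == 0.0
        assert summary.percent_ci_low == summary.percent_ci_high == summary.percent_median

    def test_aggregate_all_nd_row(self):
        runs = [
            make_run([0.1], times=[1.0], censored=[True], cell_id=f"n{i}")
            for i in range(3)
        ]
        results = [analyze_franz_run(r) for r in runs]
        summary = aggregate_replicates(results, n_boot=100, seed=0)
        assert not summary.detected
        assert math.isnan(summary.max_flux_mean)

    def test_mixed_compounds_rejected(self):
        a = analyze_franz_run(make_run([1.0], times=[1.0], compound="MP"))
        b = analyze_franz_run(make_run([1.0], times=[1.0], compound="EP"))
        with pytest.raises(ValidationError):
            aggregate_replicates([a, b])

    def test_bootstrap_ci_reproducible_with_seed(self):
        runs = [make_run([c], times=[1.0], cell_id=str(c)) for c in (1.0, 1.5, 3.0)]
        results = [analyze_franz_run(r) for r in runs]
        s1 = aggregate_replicates(results, n_boot=2000, seed=11)
        s2 = aggregate_replicates(results, n_boot=2000, seed=11)
        assert (s1.percent_ci_low, s1.percent_ci_high) == (
            s2.percent_ci_low, s2.percent_ci_high
        )
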