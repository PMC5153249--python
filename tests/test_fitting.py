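"""Tests for isotherm fitting, model comparison, censoring and aggregation."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from picshift.fitting import (
    aggregate_replicates,
    censor_apparent_kd,
    compare_isotherms,
    fit_hill,
    fit_langmuir,
)
from picshift.gelshift import CorrectedCurve, CorrectedPoint, tc_binding_curve
from picshift.synth import (
    IsothermDesign,
    NoiseModel,
    TitrationDesign,
    default_40s_grid,
    default_eif3_grid,
    simulate_isotherm_titration,
    simulate_titration,
)


def curve(x, y):
    return CorrectedCurve(
        tuple(CorrectedPoint(float(a), float(b)) for a, b in zip(x, y)),
        "frac_43s_eif3",
    )


class TestLangmuir:
    def test_exact_recovery_on_noiseless_data(self):
        x = np.array([10.0, 30.0, 100.0, 300.0, 1000.0])
        fit = fit_langmuir(curve(x, 0.8 * x / (100.0 + x)))
        assert fit.success
        assert fit.k_app == pytest.approx(100.0, rel=1e-6)
        assert fit.amplitude == pytest.approx(0.8, rel=1e-6)
        assert fit.hill_n == 1.0

    def test_flat_saturated_response_is_failure_not_exception(self):
        x = np.array([10.0, 30.0, 100.0, 300.0])
        fit = fit_langmuir(curve(x, np.full(4, 0.8)))
        assert not fit.success
        assert "flat" in fit.message
        assert math.isnan(fit.k_app)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match=">= 4 points"):
            fit_langmuir(curve([10.0, 100.0, 400.0], [0.1, 0.4, 0.6]))

    def test_narrow_range_rejected(self):
        x = [100.0, 120.0, 140.0, 160.0]
        with pytest.raises(ValueError, match="4-fold"):
            fit_langmuir(curve(x, [0.3, 0.35, 0.38, 0.4]))

    def test_noisy_replicates_recover_tc_affinity_within_ten_percent(self):
        """8 replicate 40S titrations at sigma=0.02 recover K_D = 104 nM."""
        design = IsothermDesign(default_40s_grid(), kd=104.0, amplitude=0.8, n_replicates=8)
        experiments = simulate_isotherm_titration(design, NoiseModel(0.02, 0))
        fits = [fit_langmuir(tc_binding_curve(e)) for e in experiments]
        assert all(f.success for f in fits)
        assert np.mean([f.k_app for f in fits]) == pytest.approx(104.0, rel=0.10)


class TestHill:
    def test_exact_recovery_on_noiseless_data(self):
        x = np.geomspace(10.0, 1000.0, 8)
        fit = fit_hill(curve(x, 0.9 * x**2.2 / (120.0**2.2 + x**2.2)))
        assert fit.success
        assert fit.k_app == pytest.approx(120.0, rel=1e-6)
        assert fit.hill_n == pytest.approx(2.2, rel=1e-6)
        assert fit.amplitude == pytest.approx(0.9, rel=1e-6)

    def test_langmuir_data_gives_unit_hill_coefficient(self):
        x = np.array([10.0, 30.0, 100.0, 300.0, 1000.0])
        y = 0.8 * x / (100.0 + x)
        hill = fit_hill(curve(x, y))
        langmuir = fit_langmuir(curve(x, y))
        assert hill.hill_n == pytest.approx(1.0, abs=1e-4)
        assert hill.k_app == pytest.approx(langmuir.k_app, rel=1e-4)

    def test_nesting_identity_with_fixed_unit_coefficient(self, rng):
        x = np.geomspace(10.0, 1000.0, 8)
        y = 0.8 * x / (100.0 + x) + rng.normal(0.0, 0.02, 8)
        langmuir = fit_langmuir(curve(x, y))
        nested = fit_hill(curve(x, y), fix_n=1.0)
        assert nested.rss == pytest.approx(langmuir.rss, abs=1e-9)
        assert nested.k_app == pytest.approx(langmuir.k_app, rel=1e-6)

    def test_steep_sigmoid_breaks_langmuir_but_not_hill(self):
        """Severe, cooperative binding defects defeat the hyperbolic fit.

        A steep curve half-saturating beyond the titrated range drives the
        bounded Langmuir K into its search limit (reported as failure),
        while the Hill fit models the same points exactly.
        """
        x = np.geomspace(10.0, 500.0, 8)
        y = 0.9 * x**4 / (800.0**4 + x**4)
        langmuir = fit_langmuir(curve(x, y))
        hill = fit_hill(curve(x, y))
        assert not langmuir.success
        assert "bound" in langmuir.message
        assert hill.success
        assert hill.k_app == pytest.approx(800.0, rel=1e-3)
        assert hill.hill_n == pytest.approx(4.0, rel=1e-3)

    def test_bias_vanishes_as_noise_shrinks(self):
        x = np.geomspace(10.0, 1000.0, 8)
        truth = 0.85 * x**2.0 / (150.0**2.0 + x**2.0)
        errors = []
        for sigma in (0.05, 0.01, 0.002):
            rng = np.random.default_rng(5)
            recovered = [
                fit_hill(curve(x, truth + rng.normal(0.0, sigma, 8))).k_app
                for _ in range(20)
            ]
            errors.append(abs(np.mean(recovered) - 150.0))
        assert errors[2] < errors[0]
        assert errors[2] < 1.5  # nM, essentially unbiased at sigma=0.002


class TestModelComparison:
    def test_hyperbolic_data_prefers_langmuir_by_parsimony(self, rng):
        x = np.geomspace(10.0, 1000.0, 8)
        y = 0.8 * x / (100.0 + x) + rng.normal(0.0, 0.02, 8)
        assert compare_isotherms(curve(x, y)).preferred == "langmuir"

    def test_cooperative_data_prefers_hill_in_simulation(self):
        """n=2.5 curves at sigma=0.02: Hill wins in >= 95% of 200 draws."""
        x = np.geomspace(10.0, 1000.0, 8)
        truth = 0.85 * x**2.5 / (120.0**2.5 + x**2.5)
        rng = np.random.default_rng(7)
        wins = sum(
            compare_isotherms(curve(x, np.clip(truth + rng.normal(0.0, 0.02, 8), 0, 1.05))).preferred
            == "hill"
            for _ in range(200)
        )
        assert wins >= 190

    def test_failed_langmuir_forces_hill(self):
        x = np.geomspace(10.0, 500.0, 8)
        y = 0.9 * x**4 / (800.0**4 + x**4)
        comparison = compare_isotherms(curve(x, y))
        assert comparison.preferred == "hill"
        assert not comparison.langmuir.success

    def test_both_failing_raises(self):
        x = np.array([10.0, 30.0, 100.0, 300.0])
        with pytest.raises(RuntimeError, match="both"):
            compare_isotherms(curve(x, np.full(4, 0.5)))


class TestCensoring:
    def test_below_limit_is_censored(self):
        fit = fit_langmuir(curve(
            np.array([5.0, 15.0, 45.0, 135.0, 405.0]),
            0.8 * np.array([5.0, 15.0, 45.0, 135.0, 405.0])
            / (15.0 + np.array([5.0, 15.0, 45.0, 135.0, 405.0])),
        ))
        censored = censor_apparent_kd(fit, limiting_40s=30.0)
        assert censored.censored
        assert censored.censor_limit == 30.0
        assert censored.k_app == pytest.approx(15.0, rel=1e-6)  # value retained

    def test_above_limit_untouched(self):
        x = np.array([10.0, 30.0, 100.0, 300.0, 1000.0])
        fit = fit_langmuir(curve(x, 0.8 * x / (95.0 + x)))
        assert not censor_apparent_kd(fit, 30.0).censored

    def test_boundary_is_inclusive(self):
        x = np.array([10.0, 30.0, 100.0, 300.0, 1000.0])
        fit = fit_langmuir(curve(x, 0.8 * x / (30.0 + x)))
        assert censor_apparent_kd(fit, 30.0).censored

    def test_resolution_floor_in_stoichiometric_regime(self, assay_totals):
        """True K2 far below the 30 nM 40S: apparent K sits near 15 nM, censored.

        On the total-eIF3 axis the titration is stoichiometric, so the
        half-saturation lands near half the limiting 40S concentration no
        matter how tight the true constant is.
        """
        from picshift.equilibria import EquilibriumConstants
        from picshift.gelshift import correct_titration

        constants = EquilibriumConstants.from_cycle(104.0, 0.5, 15.0)
        design = TitrationDesign("eif3", default_eif3_grid(8), constants, assay_totals, 3)
        for exp in simulate_titration(design, NoiseModel(0.01, 1)):
            fit = fit_hill(correct_titration(exp, axis="total"))
            assert fit.success
            fit = censor_apparent_kd(fit, 30.0)
            assert fit.censored
            assert 30.0 / 4 <= fit.k_app <= 30.0


class TestAggregation:
    @pytest.mark.parametrize(
        "values,mean,sem",
        [
            ([10.0, 10.0, 10.0], 10.0, 0.0),
            ([12.0, 18.0], 15.0, 3.0),
            ([0.25, 0.29, 0.27, 0.31], 0.28, 0.0129),
        ],
    )
    def test_known_values(self, values, mean, sem):
        summary = aggregate_replicates(values)
        assert summary.mean == pytest.approx(mean, rel=1e-6)
        assert summary.sem == pytest.approx(sem, abs=5e-5)
        assert summary.n == len(values)

    def test_single_replicate_has_undefined_sem(self):
        summary = aggregate_replicates([42.0])
        assert summary.mean == 42.0
        assert math.isnan(summary.sem)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_replicates([])

    @given(
        values=st.lists(st.floats(min_value=0.1, max_value=1e4), min_size=2, max_size=10),
        scale=st.floats(min_value=0.01, max_value=100.0),
    )
    def test_permutation_invariant_and_scale_equivariant(self, values, scale):
        base = aggregate_replicates(values)
        shuffled = aggregate_replicates(list(reversed(values)))
        assert shuffled.mean == pytest.approx(base.mean, rel=1e-12)
        assert shuffled.sem == pytest.approx(base.sem, rel=1e-9, abs=1e-12)
        scaled = aggregate_replicates([v * scale for v in values])
        assert scaled.mean == pytest.approx(base.mean * scale, rel=1e-9)
        assert scaled.sem == pytest.approx(base.sem * scale, rel=1e-6, abs=1e-9)
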