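"""Unit and property tests for the coupled binding-equilibria model."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from picshift.equilibria import (
    EquilibriumConstants,
    EquilibriumError,
    MixtureTotals,
    SpeciesState,
    band_fractions,
    derive_fourth_constant,
    solve_equilibrium,
)

K_RANGE = st.floats(min_value=1e-2, max_value=1e5)
TOTAL_RANGE = st.floats(min_value=0.0, max_value=1000.0)


def bisection_oracle(totals: MixtureTotals, k: EquilibriumConstants, iters: int = 200):
    """Independent nested plain-bisection solver (outer E_free, inner T_free).

    R_free is eliminated through its conservation law; both residuals are
    monotone in their own free variable so plain interval halving converges.
    """

    def species(t_free, e_free):
        denom = 1 + t_free / k.k1 + e_free / k.k4 + t_free * e_free / (k.k1 * k.k2)
        r_free = totals.r_total / denom
        rt = r_free * t_free / k.k1
        re = r_free * e_free / k.k4
        rte = r_free * t_free * e_free / (k.k1 * k.k2)
        return r_free, rt, re, rte

    def inner_t(e_free):
        lo, hi = 0.0, totals.t_total
        for _ in range(iters):
            mid = 0.5 * (lo + hi)
            _, rt, _, rte = species(mid, e_free)
            if mid + rt + rte > totals.t_total:
                hi = mid
            else:
                lo = mid
        return 0.5 * (lo + hi)

    lo, hi = 0.0, totals.e_total
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        t_free = inner_t(mid)
        _, _, re, rte = species(t_free, mid)
        if mid + re + rte > totals.e_total:
            hi = mid
        else:
            lo = mid
    e_free = 0.5 * (lo + hi)
    t_free = inner_t(e_free)
    r_free, rt, re, rte = species(t_free, e_free)
    return SpeciesState(r_free, t_free, e_free, rt, re, rte)


class TestCycleClosure:
    @pytest.mark.parametrize(
        "k1,k2,k3,expected",
        [
            (100.0, 50.0, 50.0, 100.0),  # symmetric cycle
            (104.0, 38.0, 15.0, 104.0 * 38.0 / 15.0),  # measured wild-type constants
            (15.0, 38.0, 15.0, 38.0),  # K1 == K3 forces K4 == K2
        ],
    )
    def test_fourth_constant(self, k1, k2, k3, expected):
        assert derive_fourth_constant(k1, k2, k3) == pytest.approx(expected, rel=1e-12)

    def test_wildtype_value_rounds_as_expected(self):
        assert round(derive_fourth_constant(104.0, 38.0, 15.0), 2) == 263.47

    @pytest.mark.parametrize("bad", [0.0, -5.0, math.inf, math.nan])
    def test_nonpositive_inputs_rejected(self, bad):
        with pytest.raises(EquilibriumError):
            derive_fourth_constant(bad, 38.0, 15.0)

    @given(k1=K_RANGE, k2=K_RANGE, k3=K_RANGE)
    def test_every_constructed_cycle_closes(self, k1, k2, k3):
        k = EquilibriumConstants.from_cycle(k1, k2, k3)
        assert k.k1 * k.k2 == pytest.approx(k.k3 * k.k4, rel=1e-9)

    def test_open_cycle_rejected(self):
        with pytest.raises(EquilibriumError, match="closure"):
            EquilibriumConstants(104.0, 38.0, 15.0, 100.0)


class TestSolveEquilibrium:
    def test_no_eif3_collapses_to_two_species_quadratic(self, wt_constants):
        state = solve_equilibrium(MixtureTotals(30.0, 2.0, 0.0), wt_constants)
        assert state.re == 0.0 and state.rte == 0.0
        rt = state.rt
        # root of RT^2 - (R+T+K1)*RT + R*T = 0 in [0, min(R, T)]
        assert rt**2 - (30 + 2 + 104) * rt + 30 * 2 == pytest.approx(0.0, abs=1e-9)
        assert 0.0 <= rt <= 2.0

    def test_no_binding_limit(self):
        k = EquilibriumConstants.from_cycle(1e12, 1e12, 1e12)
        totals = MixtureTotals(30.0, 2.0, 10.0)
        state = solve_equilibrium(totals, k)
        # mass action pins each complex near total*total/K, far below 1 nM
        assert max(state.rt, state.re, state.rte) < 1e-9
        assert state.r_free == pytest.approx(30.0, rel=1e-9)
        assert state.t_free == pytest.approx(2.0, rel=1e-9)
        assert state.e_free == pytest.approx(10.0, rel=1e-9)

    def test_matches_bisection_oracle_reference_point(self, wt_constants):
        totals = MixtureTotals(30.0, 2.0, 100.0)
        state = solve_equilibrium(totals, wt_constants)
        oracle = bisection_oracle(totals, wt_constants)
        for name in ("r_free", "t_free", "e_free", "rt", "re", "rte"):
            assert getattr(state, name) == pytest.approx(
                getattr(oracle, name), rel=1e-8
            ), name

    def test_matches_oracle_on_random_instances(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            k = EquilibriumConstants.from_cycle(
                *np.exp(rng.uniform(np.log(1.0), np.log(1000.0), 3))
            )
            totals = MixtureTotals(*rng.uniform(0.5, 500.0, 3))
            state = solve_equilibrium(totals, k)
            oracle = bisection_oracle(totals, k)
            for name in ("r_free", "t_free", "e_free", "rt", "re", "rte"):
                got, want = getattr(state, name), getattr(oracle, name)
                assert got == pytest.approx(want, rel=1e-8, abs=1e-10), name

    def test_conservation_and_nonnegativity_randomized(self):
        # broad randomized sweep incl. extreme constants and zero totals
        rng = np.random.default_rng(2)
        for _ in range(10_000):
            k = EquilibriumConstants.from_cycle(
                *np.exp(rng.uniform(np.log(0.1), np.log(1e4), 3))
            )
            totals = MixtureTotals(*np.where(rng.random(3) < 0.05, 0.0, rng.uniform(0.0, 1000.0, 3)))
            state = solve_equilibrium(totals, k)
            values = (state.r_free, state.t_free, state.e_free, state.rt, state.re, state.rte)
            assert min(values) >= 0.0
            assert abs(state.r_total - totals.r_total) <= 1e-9 * max(totals.r_total, 1e-9)
            assert abs(state.t_total - totals.t_total) <= 1e-9 * max(totals.t_total, 1e-9)
            assert abs(state.e_total - totals.e_total) <= 1e-9 * max(totals.e_total, 1e-9)

    def test_reaction_residuals_vanish(self, wt_constants):
        state = solve_equilibrium(MixtureTotals(30.0, 2.0, 100.0), wt_constants)
        k = wt_constants
        assert state.r_free * state.t_free == pytest.approx(k.k1 * state.rt, rel=1e-9)
        assert state.e_free * state.rt == pytest.approx(k.k2 * state.rte, rel=1e-9)
        assert state.t_free * state.re == pytest.approx(k.k3 * state.rte, rel=1e-9)
        assert state.e_free * state.r_free == pytest.approx(k.k4 * state.re, rel=1e-9)

    def test_rte_nondecreasing_in_eif3_total(self, wt_constants):
        previous = -1.0
        for e_total in np.linspace(0.0, 2000.0, 40):
            state = solve_equilibrium(MixtureTotals(30.0, 2.0, e_total), wt_constants)
            assert state.rte >= previous - 1e-12
            previous = state.rte

    def test_eif3_bound_pic_fraction_nondecreasing_in_40s_assay_range(self, wt_constants):
        # holds over the titrated 40S range with saturating eIF3; at extreme
        # 40S excess the doubly bound species declines again (anti-cooperative
        # dilution), so the claim is deliberately scoped to the assay regime
        previous = -1.0
        for r_total in np.linspace(1.0, 320.0, 40):
            state = solve_equilibrium(MixtureTotals(r_total, 2.0, 500.0), wt_constants)
            fraction = state.rte / 2.0
            assert fraction >= previous - 1e-12
            previous = fraction

    @given(
        k1=K_RANGE, k2=K_RANGE, k3=K_RANGE,
        r=TOTAL_RANGE, t=TOTAL_RANGE, e=TOTAL_RANGE,
    )
    def test_exchange_symmetry(self, k1, k2, k3, r, t, e):
        """Relabeling (T<->E, K1<->K4, K2<->K3) maps solutions onto each other."""
        k = EquilibriumConstants.from_cycle(k1, k2, k3)
        state = solve_equilibrium(MixtureTotals(r, t, e), k)
        mirrored = solve_equilibrium(MixtureTotals(r, e, t), k.swapped())
        assert state.t_free == pytest.approx(mirrored.e_free, rel=1e-6, abs=1e-9)
        assert state.e_free == pytest.approx(mirrored.t_free, rel=1e-6, abs=1e-9)
        assert state.rt == pytest.approx(mirrored.re, rel=1e-6, abs=1e-9)
        assert state.re == pytest.approx(mirrored.rt, rel=1e-6, abs=1e-9)
        assert state.rte == pytest.approx(mirrored.rte, rel=1e-6, abs=1e-9)


class TestBandFractions:
    def test_plain_arithmetic(self):
        state = SpeciesState(0.0, 1.0, 0.0, 0.6, 0.0, 0.4)
        assert band_fractions(state) == pytest.approx((0.5, 0.3, 0.2))

    def test_fractions_sum_to_one(self, wt_constants):
        state = solve_equilibrium(MixtureTotals(30.0, 2.0, 100.0), wt_constants)
        assert sum(band_fractions(state)) == pytest.approx(1.0, abs=1e-9)

    def test_no_eif3_means_empty_eif3_band(self, wt_constants):
        state = solve_equilibrium(MixtureTotals(30.0, 2.0, 0.0), wt_constants)
        assert band_fractions(state)[2] == 0.0

    def test_zero_tracer_is_an_error(self):
        state = SpeciesState(10.0, 0.0, 5.0, 0.0, 1.0, 0.0)
        with pytest.raises(EquilibriumError, match="zero"):
            band_fractions(state)
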