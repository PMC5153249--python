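"""Exact coupled-equilibria model of eIF3 and ternary-complex binding to the 40S subunit.

The binding network couples three components — R, the 40S subunit carrying
eIF1 and eIF1A; T, the ternary complex eIF2(GTP)Met-tRNAi; and E, the eIF3
holocomplex — through four mass-action dissociation reactions::

    T + R  <=> RT    (K1)   43S PIC formation
    E + RT <=> RTE   (K2)   eIF3 binding to the 43S PIC
    T + RE <=> RTE   (K3)   TC binding to the 40S-eIF3 complex
    E + R  <=> RE    (K4)   eIF3 binding to the free 40S subunit

The four reactions close a thermodynamic cycle, so only three constants are
independent: K1*K2 = K3*K4.  ``K4`` is therefore always derived and never a
free parameter.  All concentrations are in nM.

Given total concentrations of the three components, :func:`solve_equilibrium`
returns the unique physically admissible equilibrium concentration of all six
species.  The free-tRNAi, 43S and 43S-eIF3 bands resolved on a native gel map
onto the species through :func:`band_fractions`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

__all__ = [
    "EquilibriumConstants",
    "MixtureTotals",
    "SpeciesState",
    "EquilibriumError",
    "SolverError",
    "derive_fourth_constant",
    "solve_equilibrium",
    "band_fractions",
]

#: relative tolerance on the K1*K2 = K3*K4 cycle-closure identity
CLOSURE_RTOL = 1e-9
#: relative tolerance on conservation / reaction residuals of a solved state
RESIDUAL_RTOL = 1e-9
#: iteration cap for the equilibrium solver
MAX_ITER = 200


class EquilibriumError(ValueError):
    """Invalid equilibrium constants or totals."""


class SolverError(RuntimeError):
    """Equilibrium solver failed to converge; carries the residuals."""

    def __init__(self, message: str, residuals: tuple[float, float] | None = None):
        if residuals is not None:
            message = f"{message} (conservation residuals: T={residuals[0]:.3e}, E={residuals[1]:.3e})"
        super().__init__(message)
        self.residuals = residuals


def _check_positive(name: str, value: float) -> None:
    if not (math.isfinite(value) and value > 0):
        raise EquilibriumError(f"{name} must be strictly positive and finite, got {value!r}")


def derive_fourth_constant(k1: float, k2: float, k3: float) -> float:
    """Close the thermodynamic cycle: return K4 = K1*K2/K3 (all nM).

    K4 is the dissociation constant of eIF3 from the free 40S subunit, which
    is never measured directly in the gel-shift assay; cycle closure is its
    only definition.
    """
    for name, value in (("K1", k1), ("K2", k2), ("K3", k3)):
        _check_positive(name, value)
    return k1 * k2 / k3


@dataclass(frozen=True)
class EquilibriumConstants:
    """The four dissociation constants of the binding cycle, in nM.

    Construct via :meth:`from_cycle` so that K4 is derived; a directly
    supplied K4 must satisfy closure to within ``CLOSURE_RTOL``.
    """

    k1: float
    k2: float
    k3: float
    k4: float

    def __post_init__(self) -> None:
        for name in ("k1", "k2", "k3", "k4"):
            _check_positive(name.upper(), getattr(self, name))
        lhs, rhs = self.k1 * self.k2, self.k3 * self.k4
        if abs(lhs - rhs) > CLOSURE_RTOL * max(lhs, rhs):
            raise EquilibriumError(
                f"cycle closure violated: K1*K2={lhs:g} != K3*K4={rhs:g}"
            )

    @classmethod
    def from_cycle(cls, k1: float, k2: float, k3: float) -> "EquilibriumConstants":
        """Build a closed cycle from the three measurable constants."""
        return cls(k1, k2, k3, derive_fourth_constant(k1, k2, k3))

    def swapped(self) -> "EquilibriumConstants":
        """Constants of the relabelled network T<->E (K1<->K4, K2<->K3)."""
        return EquilibriumConstants(self.k4, self.k3, self.k2, self.k1)


@dataclass(frozen=True)
class MixtureTotals:
    """Total (loaded) concentrations of the three components, in nM."""

    r_total: float
    t_total: float
    e_total: float

    def __post_init__(self) -> None:
        for name in ("r_total", "t_total", "e_total"):
            value = getattr(self, name)
            if not (math.isfinite(value) and value >= 0):
                raise EquilibriumError(f"{name} must be finite and >= 0, got {value!r}")


@dataclass(frozen=True)
class SpeciesState:
    """Equilibrium concentrations of all six species, in nM."""

    r_free: float
    t_free: float
    e_free: float
    rt: float
    re: float
    rte: float

    @property
    def r_total(self) -> float:
        return self.r_free + self.rt + self.re + self.rte

    @property
    def t_total(self) -> float:
        return self.t_free + self.rt + self.rte

    @property
    def e_total(self) -> float:
        return self.e_free + self.re + self.rte


def _duplex(a_total: float, b_total: float, k: float) -> float:
    """Bound complex of a single A + B <=> AB reaction (exact quadratic root).

    Returns the root of AB^2 - (A+B+K)*AB + A*B = 0 lying in [0, min(A, B)].
    """
    s = a_total + b_total + k
    disc = s * s - 4.0 * a_total * b_total
    ab = 0.5 * (s - math.sqrt(max(disc, 0.0)))
    return min(max(ab, 0.0), a_total, b_total)


def _species_from_free(
    t_free: float, e_free: float, totals: MixtureTotals, k: EquilibriumConstants
):
    """All species + conservation residuals given the two free concentrations."""
    denom = 1.0 + t_free / k.k1 + e_free / k.k4 + t_free * e_free / (k.k1 * k.k2)
    r_free = totals.r_total / denom
    rt = r_free * t_free / k.k1
    re = r_free * e_free / k.k4
    rte = r_free * t_free * e_free / (k.k1 * k.k2)
    f_t = t_free + rt + rte - totals.t_total
    f_e = e_free + re + rte - totals.e_total
    return r_free, rt, re, rte, f_t, f_e


def _solve_newton(totals: MixtureTotals, k: EquilibriumConstants):
    """Damped Newton (trust-region hybr) on log free concentrations."""

    def fun(z: np.ndarray) -> list[float]:
        t_free, e_free = np.exp(z)
        *_, f_t, f_e = _species_from_free(t_free, e_free, totals, k)
        return [f_t, f_e]

    x0 = np.log([totals.t_total / 2.0, totals.e_total / 2.0])
    sol = optimize.root(fun, x0, method="hybr", options={"xtol": 1e-14, "maxfev": MAX_ITER})
    if not sol.success:
        return None
    return float(np.exp(sol.x[0])), float(np.exp(sol.x[1]))


def _solve_nested_brentq(totals: MixtureTotals, k: EquilibriumConstants):
    """Fallback: outer bracketing on E_free, inner on T_free.

    Both conservation residuals are monotone increasing in their own free
    variable, so [0, total] always brackets the root.
    """

    def inner_t(e_free: float) -> float:
        f = lambda t_free: _species_from_free(t_free, e_free, totals, k)[4]
        if f(totals.t_total) <= 0.0:
            return totals.t_total
        return optimize.brentq(
            f, 0.0, totals.t_total, xtol=1e-30, rtol=8.9e-16, maxiter=MAX_ITER
        )

    def outer(e_free: float) -> float:
        return _species_from_free(inner_t(e_free), e_free, totals, k)[5]

    if outer(totals.e_total) <= 0.0:
        e_free = totals.e_total
    else:
        e_free = optimize.brentq(
            outer, 0.0, totals.e_total, xtol=1e-30, rtol=8.9e-16, maxiter=MAX_ITER
        )
    return inner_t(e_free), e_free


def _within_tolerance(f_t: float, f_e: float, totals: MixtureTotals) -> bool:
    # each conservation law judged on its own component's scale
    return abs(f_t) <= RESIDUAL_RTOL * max(totals.t_total, 1e-12) and abs(
        f_e
    ) <= RESIDUAL_RTOL * max(totals.e_total, 1e-12)


def solve_equilibrium(
    totals: MixtureTotals, constants: EquilibriumConstants
) -> SpeciesState:
    """Solve the coupled binding network for its unique admissible equilibrium.

    The problem reduces to two unknowns (free T, free E) after eliminating
    free R via its conservation law.  Degenerate mixtures with any zero total
    collapse to at most one reaction and are solved analytically.

    Raises
    ------
    SolverError
        if the iterative solver fails to reach ``RESIDUAL_RTOL`` relative
        conservation residuals within the iteration budget.
    """
    r_t, t_t, e_t = totals.r_total, totals.t_total, totals.e_total
    k = constants

    if r_t == 0.0:
        return SpeciesState(0.0, t_t, e_t, 0.0, 0.0, 0.0)
    if t_t == 0.0 and e_t == 0.0:
        return SpeciesState(r_t, 0.0, 0.0, 0.0, 0.0, 0.0)
    if e_t == 0.0:
        rt = _duplex(r_t, t_t, k.k1)
        return SpeciesState(r_t - rt, t_t - rt, 0.0, rt, 0.0, 0.0)
    if t_t == 0.0:
        re = _duplex(r_t, e_t, k.k4)
        return SpeciesState(r_t - re, 0.0, e_t - re, 0.0, re, 0.0)

    solution = _solve_newton(totals, k)
    if solution is not None:
        t_free, e_free = solution
        *_, f_t, f_e = _species_from_free(t_free, e_free, totals, k)
        if not _within_tolerance(f_t, f_e, totals):
            solution = None
    if solution is None:
        solution = _solve_nested_brentq(totals, k)
    t_free, e_free = solution
    r_free, rt, re, rte, f_t, f_e = _species_from_free(t_free, e_free, totals, k)
    if not _within_tolerance(f_t, f_e, totals):
        raise SolverError("equilibrium solver did not converge", (f_t, f_e))
    return SpeciesState(r_free, t_free, e_free, rt, re, rte)


def band_fractions(
    state: SpeciesState, tracer: str = "trna_i"
) -> tuple[float, float, float]:
    """Partition of the radiolabel across the three gel bands.

    With the tRNAi tracer (the only label used in titration assays) the
    resolved bands are free tRNAi, the 43S PIC (RT) and the 43S-eIF3 complex
    (RTE); fractions are relative to total T and sum to 1.
    """
    if tracer not in ("trna_i",):
        raise ValueError(f"unknown tracer {tracer!r}; titration assays label tRNA_i")
    t_total = state.t_total
    if t_total <= 0.0:
        raise EquilibriumError("band fractions undefined: total tracer concentration is zero")
    return state.t_free / t_total, state.rt / t_total, state.rte / t_total
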