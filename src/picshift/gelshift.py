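"""Free-eIF3 correction and binding-curve assembly from quantified gel shifts.

A native gel resolves every tRNAi-containing species, so the 43S (RT) and
43S-eIF3 (RTE) concentrations in a lane are measured directly.  The species
that competes for eIF3 without carrying label — eIF3 bound to free 40S
subunits (RE) — is not visible, but at equilibrium it is pinned by the
measured bands through the TC/40S-eIF3 dissociation constant K3::

    RE = K3 * RTE / T_free

which lets the free-eIF3 concentration be reconstructed lane by lane:

    E_free = E_total - RTE - RE

Fitting the eIF3:PIC isotherm on this corrected free-ligand axis is what
makes the apparent K2 meaningful despite ligand depletion by free 40S.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, NamedTuple

import numpy as np

from .equilibria import MixtureTotals

__all__ = [
    "Lane",
    "TitrationExperiment",
    "CorrectedPoint",
    "CorrectedCurve",
    "FreeEif3",
    "free_eif3_in_lane",
    "correct_titration",
    "tc_binding_curve",
]

#: allowed range for the per-lane fraction sum (phosphorimager slack)
FRACTION_SUM_RANGE = (0.95, 1.05)


@dataclass(frozen=True)
class Lane:
    """One gel lane: titrant total (nM) and the three quantified band fractions."""

    titrant_total: float
    frac_free: float
    frac_43s: float
    frac_43s_eif3: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.titrant_total) and self.titrant_total >= 0):
            raise ValueError(f"titrant_total must be >= 0, got {self.titrant_total!r}")
        for name in ("frac_free", "frac_43s", "frac_43s_eif3"):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {value!r}")
        total = self.frac_free + self.frac_43s + self.frac_43s_eif3
        lo, hi = FRACTION_SUM_RANGE
        if not (lo <= total <= hi):
            raise ValueError(
                f"lane fractions sum to {total:.4f}, outside quantification slack [{lo}, {hi}]"
            )


@dataclass(frozen=True)
class TitrationExperiment:
    """One replicate of a titration: ordered lanes plus the fixed mixture totals.

    ``k3_assumed`` (nM) is required for eIF3 titrations, where it feeds the
    free-eIF3 correction; it is a per-experiment input because the TC
    affinity for the 40S-eIF3 complex is itself condition/variant specific.
    """

    replicate_id: str
    titrant: Literal["eif3", "40s"]
    lanes: tuple[Lane, ...]
    fixed_totals: MixtureTotals
    k3_assumed: float | None = None

    def __post_init__(self) -> None:
        if self.titrant not in ("eif3", "40s"):
            raise ValueError(f"titrant must be 'eif3' or '40s', got {self.titrant!r}")
        object.__setattr__(self, "lanes", tuple(self.lanes))
        if not self.lanes:
            raise ValueError("a titration needs at least one lane")
        totals = [lane.titrant_total for lane in self.lanes]
        if any(b <= a for a, b in zip(totals, totals[1:])):
            raise ValueError("titrant totals must be strictly increasing across lanes")
        if self.k3_assumed is not None and not self.k3_assumed > 0:
            raise ValueError(f"k3_assumed must be > 0, got {self.k3_assumed!r}")


@dataclass(frozen=True)
class CorrectedPoint:
    free_ligand: float
    response: float
    flagged: bool = False


@dataclass(frozen=True)
class CorrectedCurve:
    """Binding-curve points on a (free or total) ligand axis.

    ``response_def`` records what the y-axis is: the fraction of PICs that
    carry eIF3 (RTE/(RT+RTE), the eIF3-binding readout), the raw label
    fraction in the 43S-eIF3 band (RTE/T_total), or total TC bound
    ((RT+RTE)/T_total, the TC-binding readout of 40S titrations).
    """

    points: tuple[CorrectedPoint, ...]
    response_def: Literal["frac_pic_eif3", "frac_43s_eif3", "frac_tc_bound"]

    def __post_init__(self) -> None:
        object.__setattr__(self, "points", tuple(self.points))
        if any(p.free_ligand < 0 for p in self.points):
            raise ValueError("corrected ligand concentrations must be >= 0")

    @property
    def x(self) -> np.ndarray:
        return np.array([p.free_ligand for p in self.points], dtype=float)

    @property
    def y(self) -> np.ndarray:
        return np.array([p.response for p in self.points], dtype=float)

    @property
    def flags(self) -> np.ndarray:
        return np.array([p.flagged for p in self.points], dtype=bool)


class FreeEif3(NamedTuple):
    e_free: float
    re: float
    rte: float
    floored: bool  # raw E_free was negative and was clamped to 0


def free_eif3_in_lane(
    lane: Lane, t_total: float, e_total: float, k3: float
) -> FreeEif3:
    """Reconstruct free eIF3 in one lane from the measured band fractions.

    RTE and free T come straight off the gel; RE follows from K3; the free
    eIF3 concentration is the total minus both bound pools.  A negative raw
    value (possible with noisy fractions) is floored at 0 and flagged rather
    than rejected, so noisy replicates stay analyzable.
    """
    if k3 <= 0:
        raise ValueError(f"K3 must be > 0, got {k3!r}")
    if lane.frac_free <= 0.0:
        raise ZeroDivisionError(
            "free-tracer band fraction is 0: free tRNA_i is unmeasurable in this "
            "lane, exclude it from the correction"
        )
    rte = lane.frac_43s_eif3 * t_total
    t_free = lane.frac_free * t_total
    re = k3 * rte / t_free
    e_free = e_total - rte - re
    floored = e_free < 0.0
    return FreeEif3(max(e_free, 0.0), re, rte, floored)


def _lane_response(lane: Lane, response: str) -> tuple[float, bool]:
    if response == "frac_43s_eif3":
        return lane.frac_43s_eif3, False
    pic = lane.frac_43s + lane.frac_43s_eif3
    if pic <= 0.0:
        return 0.0, True  # no PIC signal in the lane; flag rather than divide by zero
    return lane.frac_43s_eif3 / pic, False


def correct_titration(
    exp: TitrationExperiment,
    axis: Literal["free", "total"] = "free",
    response: Literal["frac_pic_eif3", "frac_43s_eif3"] = "frac_pic_eif3",
) -> CorrectedCurve:
    """Turn an eIF3 titration into a binding curve for isotherm fitting.

    The default response is the fraction of PICs carrying eIF3,
    RTE/(RT+RTE) — the readout whose isotherm against free eIF3 has its
    half-saturation exactly at K2 (RTE/RT = E_free/K2 at equilibrium, so
    the fraction is E_free/(K2+E_free)).  The raw 43S-eIF3 label fraction
    RTE/T_total is also available but saturates below 1 and half-saturates
    above K2, because the tracer redistributes between free T and PICs as
    eIF3 stabilizes TC binding.

    By default the ligand axis is the corrected free-eIF3 concentration;
    ``axis="total"`` keeps the loaded totals (useful to quantify how much
    the correction matters, and for stoichiometric-regime diagnostics).
    Lanes whose raw free-eIF3 came out negative are flagged, never dropped.
    """
    if exp.titrant != "eif3":
        raise ValueError("correct_titration applies to eIF3 titrations only")
    if response not in ("frac_pic_eif3", "frac_43s_eif3"):
        raise ValueError(f"unknown response {response!r}")
    if axis == "total":
        points = [
            CorrectedPoint(lane.titrant_total, *_lane_response(lane, response))
            for lane in exp.lanes
        ]
        return CorrectedCurve(tuple(points), response)
    if exp.k3_assumed is None:
        raise ValueError("free-eIF3 correction requires k3_assumed on the experiment")
    t_total = exp.fixed_totals.t_total
    points = []
    for lane in exp.lanes:
        result = free_eif3_in_lane(lane, t_total, lane.titrant_total, exp.k3_assumed)
        value, bad = _lane_response(lane, response)
        points.append(CorrectedPoint(result.e_free, value, result.floored or bad))
    return CorrectedCurve(tuple(points), response)


def tc_binding_curve(exp: TitrationExperiment) -> CorrectedCurve:
    """Binding curve of a 40S titration read out as total TC bound.

    The response pools both TC-containing complexes (43S and 43S-eIF3).  No
    free-ligand correction is applied: the tracer sits at 1-2 nM, at least
    5-fold below the smallest fitted K_D, so total and free 40S coincide to
    within the tracer concentration (documented approximation).
    """
    if exp.titrant != "40s":
        raise ValueError("tc_binding_curve applies to 40S titrations only")
    points = [
        CorrectedPoint(lane.titrant_total, lane.frac_43s + lane.frac_43s_eif3)
        for lane in exp.lanes
    ]
    return CorrectedCurve(tuple(points), "frac_tc_bound")
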