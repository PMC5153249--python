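"""Synthetic gel-shift and time-course data with the assay's statistical structure.

The generator emulates quantified native-gel experiments: band fractions are
computed either from the exact coupled-equilibria model (mechanistic eIF3 /
40S titrations) or directly from an isotherm or single-exponential law, then
perturbed with additive truncated-Gaussian measurement noise per band and
organized into replicate-structured tables identical to the ones the readers
consume.  Every stage of the analysis — free-eIF3 correction, isotherm and
kinetic fitting, aggregation — can therefore be validated end-to-end by
parameter recovery with no laboratory data.

Default concentration designs follow the assay conditions the model targets:
eIF3 titrated 30-500 nM against 30 nM 40S subunits and 2 nM tracer TC; 40S
titrated 10-320 nM against 1 nM tracer TC; time courses within 0-120 min.
The default noise SD of 0.02 on a band fraction is a realistic scale for
phosphorimager quantification and is configurable, since the true
measurement noise of any given quantification is unknown.

Reproducibility contract: one master seed expands into independent
per-replicate substreams (numpy ``SeedSequence.spawn``); the generated
tables are bit-identical for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping

import numpy as np

from .equilibria import EquilibriumConstants, MixtureTotals, band_fractions, solve_equilibrium
from .gelshift import Lane, TitrationExperiment
from .kinetics import TimeCourse

__all__ = [
    "NoiseModel",
    "TitrationDesign",
    "IsothermDesign",
    "TimeCourseDesign",
    "EndpointDesign",
    "default_eif3_grid",
    "default_40s_grid",
    "default_time_grid",
    "simulate_titration",
    "simulate_isotherm_titration",
    "simulate_timecourse",
    "simulate_endpoints",
    "variant_panel",
    "PanelBundle",
]

DEFAULT_SIGMA = 0.02
DEFAULT_N_REPLICATES = 2


@dataclass(frozen=True)
class NoiseModel:
    """Additive truncated-Gaussian noise on each band fraction.

    Noisy fractions are clipped to [0, 1] and renormalized to the pre-noise
    lane total, mimicking per-lane normalization of band volumes.
    """

    sigma: float = DEFAULT_SIGMA
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma!r}")

    def substreams(self, n: int) -> list[np.random.Generator]:
        return [np.random.default_rng(s) for s in np.random.SeedSequence(self.seed).spawn(n)]


def _perturb_fractions(fracs: np.ndarray, rng: np.random.Generator, sigma: float) -> np.ndarray:
    # noise lands only on bands that carry signal: a structurally dark band
    # (e.g. the 43S band when eIF3 is saturating) is never quantified, and
    # clipping half-normal noise onto it would otherwise bias every lane up
    pre_sum = fracs.sum()
    mask = fracs > 0.0
    noisy = fracs.copy()
    noisy[mask] = np.clip(fracs[mask] + rng.normal(0.0, sigma, size=int(mask.sum())), 0.0, 1.0)
    total = noisy.sum()
    if total > 0:
        noisy = noisy * (pre_sum / total)
    return noisy


def default_eif3_grid(n: int = 8) -> tuple[float, ...]:
    """Log-spaced eIF3 totals over the 30-500 nM titration window."""
    return tuple(float(v) for v in np.geomspace(30.0, 500.0, n))


def default_40s_grid() -> tuple[float, ...]:
    """Two-fold 40S titration steps over 10-320 nM."""
    return tuple(10.0 * 2.0**i for i in range(6))


def default_time_grid(k: float, n: int = 8, t_max: float = 120.0) -> tuple[float, ...]:
    """Log-spaced sampling from an early point out to ~5/k (capped at t_max)."""
    if k <= 0:
        raise ValueError("rate constant must be > 0")
    t_end = min(5.0 / k, t_max)
    return tuple(float(v) for v in np.geomspace(t_end / 60.0, t_end, n))


@dataclass(frozen=True)
class TitrationDesign:
    """Mechanistic titration design: lanes generated from the equilibrium model.

    For an eIF3 titration the grid lists total eIF3 per lane and
    ``fixed_totals`` carries the 40S and tracer-TC totals; for a 40S
    titration the grid lists total 40S and ``fixed_totals`` carries tracer
    TC and (possibly zero) eIF3.
    """

    titrant: Literal["eif3", "40s"]
    grid: tuple[float, ...]
    constants: EquilibriumConstants
    fixed_totals: MixtureTotals
    n_replicates: int = DEFAULT_N_REPLICATES

    def __post_init__(self) -> None:
        object.__setattr__(self, "grid", tuple(float(g) for g in self.grid))
        if not self.grid:
            raise ValueError("titration grid must not be empty")
        if any(b <= a for a, b in zip(self.grid, self.grid[1:])):
            raise ValueError("titration grid must be strictly increasing")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass(frozen=True)
class IsothermDesign:
    """Law-based titration design: bound fraction follows A*x^n/(K^n+x^n)."""

    grid: tuple[float, ...]
    kd: float
    amplitude: float
    hill_n: float = 1.0
    titrant: Literal["eif3", "40s"] = "40s"
    bound_band: Literal["43s", "43s_eif3"] = "43s"
    tracer_total: float = 1.0
    n_replicates: int = DEFAULT_N_REPLICATES

    def __post_init__(self) -> None:
        object.__setattr__(self, "grid", tuple(float(g) for g in self.grid))
        if not self.grid:
            raise ValueError("titration grid must not be empty")
        if self.kd <= 0 or self.amplitude <= 0 or self.hill_n <= 0:
            raise ValueError("kd, amplitude and hill_n must be > 0")


@dataclass(frozen=True)
class TimeCourseDesign:
    """Single-exponential time-course design with true (A, k)."""

    times: tuple[float, ...]
    amplitude: float
    k: float  # 1/min
    mrna_label: str = ""
    condition: str = ""
    n_replicates: int = DEFAULT_N_REPLICATES

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", tuple(float(t) for t in self.times))
        if not self.times:
            raise ValueError("time grid must not be empty")
        if self.k <= 0:
            raise ValueError("a recruitment process needs k > 0")
        if not 0 < self.amplitude <= 1.05:
            raise ValueError("amplitude must lie in (0, 1.05]")


@dataclass(frozen=True)
class EndpointDesign:
    """Terminal-lane design: one completed-reaction measurement per replicate."""

    endpoint: float
    condition: str = ""
    mrna_label: str = ""
    n_replicates: int = DEFAULT_N_REPLICATES

    def __post_init__(self) -> None:
        if not 0.0 <= self.endpoint <= 1.0:
            raise ValueError("endpoint must lie in [0, 1]")


def _lane_fractions(design: TitrationDesign, titrant_total: float) -> np.ndarray:
    ft = design.fixed_totals
    if design.titrant == "eif3":
        totals = MixtureTotals(ft.r_total, ft.t_total, titrant_total)
    else:
        totals = MixtureTotals(titrant_total, ft.t_total, ft.e_total)
    state = solve_equilibrium(totals, design.constants)
    return np.array(band_fractions(state), dtype=float)


def simulate_titration(
    design: TitrationDesign, noise: NoiseModel
) -> list[TitrationExperiment]:
    """Simulate replicate titrations from the coupled-equilibrium model.

    Per lane: solve the equilibrium, read off band fractions, add noise.
    Replicates share the noiseless model and differ only by noise stream.
    """
    clean = np.array([_lane_fractions(design, g) for g in design.grid])
    experiments = []
    for rep, rng in enumerate(noise.substreams(design.n_replicates), start=1):
        lanes = tuple(
            Lane(g, *_perturb_fractions(clean[i], rng, noise.sigma))
            for i, g in enumerate(design.grid)
        )
        experiments.append(
            TitrationExperiment(
                replicate_id=f"rep{rep}",
                titrant=design.titrant,
                lanes=lanes,
                fixed_totals=design.fixed_totals,
                k3_assumed=design.constants.k3 if design.titrant == "eif3" else None,
            )
        )
    return experiments


def simulate_isotherm_titration(
    design: IsothermDesign, noise: NoiseModel
) -> list[TitrationExperiment]:
    """Simulate replicate titrations whose bound fraction follows an isotherm law.

    Used for recovery studies in the tracer regime, where the reported
    apparent K_D *is* the half-saturation constant of the binding law (no
    depletion to model).  The bound signal goes into the 43S band by default
    or the 43S-eIF3 band when the bound species contains eIF3.
    """
    x = np.asarray(design.grid, dtype=float)
    xn = np.power(x, design.hill_n)
    bound = design.amplitude * xn / (design.kd**design.hill_n + xn)
    experiments = []
    for rep, rng in enumerate(noise.substreams(design.n_replicates), start=1):
        lanes = []
        for g, b in zip(design.grid, bound):
            if design.bound_band == "43s":
                fracs = np.array([1.0 - b, b, 0.0])
            else:
                fracs = np.array([1.0 - b, 0.0, b])
            lanes.append(Lane(g, *_perturb_fractions(fracs, rng, noise.sigma)))
        fixed = (
            MixtureTotals(0.0, design.tracer_total, 0.0)
            if design.titrant == "40s"
            else MixtureTotals(30.0, design.tracer_total, 0.0)
        )
        experiments.append(
            TitrationExperiment(f"rep{rep}", design.titrant, tuple(lanes), fixed)
        )
    return experiments


def simulate_timecourse(
    design: TimeCourseDesign, noise: NoiseModel
) -> list[TimeCourse]:
    """Simulate replicate recruitment time courses from the exponential law."""
    t = np.asarray(design.times, dtype=float)
    clean = design.amplitude * (1.0 - np.exp(-design.k * t))
    courses = []
    for rep, rng in enumerate(noise.substreams(design.n_replicates), start=1):
        y = np.clip(clean + rng.normal(0.0, noise.sigma, size=clean.shape), 0.0, 1.0)
        courses.append(
            TimeCourse(
                replicate_id=f"rep{rep}",
                times=tuple(t),
                fractions=tuple(float(v) for v in y),
                mrna_label=design.mrna_label,
                condition=design.condition,
            )
        )
    return courses


def simulate_endpoints(design: EndpointDesign, noise: NoiseModel) -> list[float]:
    """Simulate terminal-lane recruitment fractions across replicates."""
    return [
        float(np.clip(design.endpoint + rng.normal(0.0, noise.sigma), 0.0, 1.0))
        for rng in noise.substreams(design.n_replicates)
    ]


Design = TitrationDesign | IsothermDesign | TimeCourseDesign | EndpointDesign


@dataclass(frozen=True)
class PanelBundle:
    """A named-condition dataset bundle plus a manifest of true parameters."""

    datasets: Mapping[str, object]
    manifest: Mapping[str, Mapping[str, object]]


def _true_parameters(design: Design) -> dict[str, object]:
    if isinstance(design, TitrationDesign):
        k = design.constants
        return {
            "kind": "eif3_titration" if design.titrant == "eif3" else "40s_titration",
            "k1_nM": k.k1, "k2_nM": k.k2, "k3_nM": k.k3, "k4_nM": k.k4,
        }
    if isinstance(design, IsothermDesign):
        return {
            "kind": "tc_titration",
            "kd_nM": design.kd,
            "amplitude": design.amplitude,
            "hill_n": design.hill_n,
        }
    if isinstance(design, TimeCourseDesign):
        return {"kind": "timecourse", "k_per_min": design.k, "amplitude": design.amplitude}
    if isinstance(design, EndpointDesign):
        return {"kind": "endpoint", "endpoint": design.endpoint}
    raise TypeError(f"unsupported design type {type(design).__name__}")


def variant_panel(
    conditions: Mapping[str, Design], noise: NoiseModel
) -> PanelBundle:
    """Simulate a panel of named conditions (e.g. WT plus variants).

    Returns the per-condition datasets and a manifest of the true generating
    parameters for later recovery scoring.  Condition names must be unique
    (guaranteed for a mapping; duplicate names in any list-style input should
    be rejected before reaching this point) and non-empty.
    """
    if not conditions:
        raise ValueError("variant panel needs at least one condition")
    names = list(conditions)
    if len(set(names)) != len(names):
        raise ValueError("duplicate condition names in panel")
    datasets: dict[str, object] = {}
    manifest: dict[str, dict[str, object]] = {}
    children = np.random.SeedSequence(noise.seed).spawn(len(names))
    for name, child in zip(names, children):
        design = conditions[name]
        sub_noise = NoiseModel(noise.sigma, int(child.generate_state(1)[0] % 2**31))
        if isinstance(design, TitrationDesign):
            datasets[name] = simulate_titration(design, sub_noise)
        elif isinstance(design, IsothermDesign):
            datasets[name] = simulate_isotherm_titration(design, sub_noise)
        elif isinstance(design, TimeCourseDesign):
            datasets[name] = simulate_timecourse(design, sub_noise)
        elif isinstance(design, EndpointDesign):
            datasets[name] = simulate_endpoints(design, sub_noise)
        else:
            raise TypeError(f"unsupported design type {type(design).__name__}")
        manifest[name] = _true_parameters(design)
    return PanelBundle(datasets, manifest)
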