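"""Single-exponential analysis of mRNA-recruitment time courses.

The fraction of labeled mRNA recruited into 48S complexes follows

    y(t) = A * (1 - exp(-k * t))

with the intercept fixed at zero (reactions start on simultaneous addition
of mRNA and ATP, so there is no burst phase to model).  ``k`` is the
observed first-order rate constant in 1/min and ``A`` the endpoint, i.e. the
maximal extent of stable recruitment.

A reaction that is essentially complete by the first sampled time point is
faster than the time resolution of the assay; its endpoint is still
meaningful but the rate is reported as unresolved rather than as a number.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import lmfit
import numpy as np

from .fitting import ReplicateSummary, aggregate_replicates

__all__ = [
    "TimeCourse",
    "KineticFit",
    "fit_single_exponential",
    "extent_at_completion",
    "rate_ratio",
]

#: fraction of the fitted amplitude that the earliest sampled point may reach
#: before the rate is declared unresolved by the assay's time resolution
RESOLUTION_FRACTION = 0.9
MIN_POINTS = 5
K_SEARCH_BOUNDS = (1e-6, 1e4)  # 1/min


@dataclass(frozen=True)
class TimeCourse:
    """One replicate time course of mRNA recruitment."""

    replicate_id: str
    times: tuple[float, ...]  # min
    fractions: tuple[float, ...]  # fraction of label in the 48S band
    mrna_label: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", tuple(float(t) for t in self.times))
        object.__setattr__(self, "fractions", tuple(float(f) for f in self.fractions))
        if len(self.times) != len(self.fractions):
            raise ValueError("times and fractions must have equal length")
        t = np.asarray(self.times)
        if len(t) and (t[0] < 0 or np.any(np.diff(t) <= 0)):
            raise ValueError("times must be >= 0 and strictly increasing")
        if any(not 0.0 <= f <= 1.0 for f in self.fractions):
            raise ValueError("recruited fractions must lie in [0, 1]")


@dataclass(frozen=True)
class KineticFit:
    """Observed rate constant (1/min) and endpoint from one time course."""

    k_obs: float
    endpoint: float
    rss: float
    rate_resolved: bool
    success: bool
    message: str = ""

    @classmethod
    def failure(cls, message: str) -> "KineticFit":
        return cls(math.nan, math.nan, math.nan, False, False, message)


def _exp_model(params: lmfit.Parameters, t: np.ndarray) -> np.ndarray:
    return params["amp"].value * (1.0 - np.exp(-params["k"].value * t))


def fit_single_exponential(tc: TimeCourse) -> KineticFit:
    """Unweighted least-squares fit of y(t) = A*(1 - exp(-k t)).

    Multi-start over log-spaced rate guesses spanning the sampled window.
    Flat-zero data and optimizer non-convergence yield a failure result.
    ``rate_resolved`` is False when the fitted curve already reaches
    ``RESOLUTION_FRACTION`` of its amplitude at the earliest positive time
    point — the reaction outran the sampling.
    """
    if len(tc.times) < MIN_POINTS:
        raise ValueError(f"rate fitting needs >= {MIN_POINTS} time points, got {len(tc.times)}")
    t = np.asarray(tc.times, dtype=float)
    y = np.asarray(tc.fractions, dtype=float)
    if y.max() < 1e-3:
        return KineticFit.failure("no recruitment detected (flat zero time course)")
    t_pos = t[t > 0]
    k_starts = np.geomspace(0.1 / t_pos.max(), 10.0 / t_pos.min(), 5)
    amp0 = float(np.clip(y.max(), 0.05, 1.05))
    best = None
    for k0 in k_starts:
        params = lmfit.Parameters()
        params.add("amp", value=amp0, min=0.0, max=1.05)
        params.add("k", value=float(np.clip(k0, *K_SEARCH_BOUNDS)),
                   min=K_SEARCH_BOUNDS[0], max=K_SEARCH_BOUNDS[1])
        try:
            result = lmfit.minimize(
                lambda p: _exp_model(p, t) - y, params, method="least_squares",
                xtol=1e-13, ftol=1e-13, gtol=1e-13,
            )
        except Exception:
            continue
        if result.success and (best is None or result.chisqr < best.chisqr):
            best = result
    if best is None:
        return KineticFit.failure("optimizer did not converge")
    k = float(best.params["k"].value)
    amp = float(best.params["amp"].value)
    first_t = float(t_pos.min())
    resolved = (1.0 - math.exp(-k * first_t)) < RESOLUTION_FRACTION
    return KineticFit(k, amp, float(best.chisqr), resolved, True)


def extent_at_completion(endpoint_lanes: Sequence[float]) -> ReplicateSummary:
    """Mean and SEM of terminal recruitment fractions across replicates.

    Each lane is a single measurement taken after incubation to completion;
    no kinetic model is involved.
    """
    return aggregate_replicates(endpoint_lanes)


def rate_ratio(fit_a: KineticFit, fit_b: KineticFit) -> float:
    """Fold difference k_obs(a) / k_obs(b) between two resolved rates."""
    for name, fit in (("a", fit_a), ("b", fit_b)):
        if not (fit.success and fit.rate_resolved):
            raise ValueError(
                f"rate of fit {name} is unresolved or failed; report a bound on the "
                "fold change instead of a ratio"
            )
    return fit_a.k_obs / fit_b.k_obs
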