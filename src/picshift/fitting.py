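"""Isotherm fitting, model comparison, censoring and replicate aggregation.

Binding curves are modeled with the single-site Langmuir isotherm

    y = A * x / (K + x)

and the cooperative Hill equation in half-saturation form

    y = A * x**n / (K**n + x**n)

so that K is always the apparent half-saturation concentration in nM, the
quantity reported for every condition.  The amplitude A floats in [0, 1.05]
because the reaction endpoint is itself condition dependent and reported.

Apparent affinities at or below the limiting 40S concentration cannot be
resolved by the assay — the titration becomes stoichiometric — and are
flagged as censored upper limits rather than point estimates.

Replicates are always fit individually and summarized as mean and SEM of the
per-replicate parameters, never as one pooled fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal, Sequence

import lmfit
import numpy as np

from .gelshift import CorrectedCurve

__all__ = [
    "IsothermFit",
    "ModelComparison",
    "ReplicateSummary",
    "fit_langmuir",
    "fit_hill",
    "compare_isotherms",
    "censor_apparent_kd",
    "aggregate_replicates",
]

HILL_N_BOUNDS = (0.5, 6.0)
AMPLITUDE_BOUNDS = (0.0, 1.05)
#: K search bounds relative to the sampled x-range; a K pinned at either
#: bound is treated as a failed (unidentifiable) fit.
K_BOUND_FACTOR = 10.0
N_STARTS = 5
_TIGHT = {"xtol": 1e-13, "ftol": 1e-13, "gtol": 1e-13}


@dataclass(frozen=True)
class IsothermFit:
    """Result of a single-curve isotherm fit (one gel-shift replicate)."""

    model: Literal["langmuir", "hill"]
    k_app: float
    amplitude: float
    hill_n: float
    rss: float
    n_points: int
    success: bool
    message: str = ""
    censored: bool = False
    censor_limit: float = math.nan

    @classmethod
    def failure(cls, model: str, n_points: int, message: str) -> "IsothermFit":
        return cls(model, math.nan, math.nan, math.nan, math.nan, n_points, False, message)


@dataclass(frozen=True)
class ModelComparison:
    preferred: Literal["langmuir", "hill"]
    langmuir: IsothermFit
    hill: IsothermFit
    aicc_langmuir: float
    aicc_hill: float


@dataclass(frozen=True)
class ReplicateSummary:
    """Mean and SEM over individually fitted replicates.

    With a single replicate the SEM is undefined and reported as NaN.
    """

    mean: float
    sem: float
    n: int


def _check_curve(curve: CorrectedCurve) -> tuple[np.ndarray, np.ndarray]:
    x, y = curve.x, curve.y
    if len(x) < 4:
        raise ValueError(f"isotherm fitting needs >= 4 points, got {len(x)}")
    positive = x[x > 0]
    if len(positive) == 0 or positive.max() / positive.min() < 4.0:
        raise ValueError("titrant concentrations must span at least a 4-fold range")
    return x, y


def _k_bounds(x: np.ndarray) -> tuple[float, float]:
    positive = x[x > 0]
    return positive.min() / K_BOUND_FACTOR, positive.max() * K_BOUND_FACTOR


def _langmuir(params: lmfit.Parameters, x: np.ndarray) -> np.ndarray:
    return params["amp"].value * x / (params["kd"].value + x)


def _hill(params: lmfit.Parameters, x: np.ndarray) -> np.ndarray:
    amp, kd, n = params["amp"].value, params["kd"].value, params["n"].value
    xn = np.power(x, n)
    return amp * xn / (kd**n + xn)


def _multistart(
    model_fn, x, y, k_lo, k_hi, hill: bool, fix_n: float | None = None
) -> lmfit.minimizer.MinimizerResult | None:
    amp0 = float(np.clip(y.max(), 0.05, AMPLITUDE_BOUNDS[1]))
    k_starts = np.geomspace(max(x[x > 0].min(), k_lo), min(x.max(), k_hi), N_STARTS)
    n_starts = [fix_n] if fix_n is not None else ([1.0, 2.0, 3.0] if hill else [1.0])
    best = None
    for k0 in k_starts:
        for n0 in n_starts:
            params = lmfit.Parameters()
            params.add("amp", value=amp0, min=AMPLITUDE_BOUNDS[0], max=AMPLITUDE_BOUNDS[1])
            params.add("kd", value=k0, min=k_lo, max=k_hi)
            if hill:
                params.add("n", value=n0, vary=fix_n is None,
                           min=HILL_N_BOUNDS[0], max=HILL_N_BOUNDS[1])
            try:
                result = lmfit.minimize(
                    lambda p: model_fn(p, x) - y,
                    params,
                    method="least_squares",
                    **_TIGHT,
                )
            except Exception:
                continue
            if result.success and (best is None or result.chisqr < best.chisqr):
                best = result
    return best


def _at_bound(value: float, lo: float, hi: float, rtol: float = 1e-3) -> bool:
    return value <= lo * (1 + rtol) or value >= hi * (1 - rtol)


def _finish(model: str, result, x, y, hill: bool) -> IsothermFit:
    kd = float(result.params["kd"].value)
    amp = float(result.params["amp"].value)
    n = float(result.params["n"].value) if hill else 1.0
    k_lo, k_hi = _k_bounds(x)
    if _at_bound(kd, k_lo, k_hi):
        return IsothermFit.failure(
            model, len(x), f"apparent K pinned at search bound ({kd:.3g} nM); unidentifiable"
        )
    return IsothermFit(model, kd, amp, n, float(result.chisqr), len(x), True)


def fit_langmuir(curve: CorrectedCurve) -> IsothermFit:
    """Fit the Langmuir isotherm by bounded multi-start least squares.

    Returns a failure result (not an exception) when the optimizer cannot
    converge, the response carries no information (flat/saturated), or the
    fitted K runs into a search bound — the behavior of curves that a
    hyperbolic isotherm cannot model.
    """
    x, y = _check_curve(curve)
    if np.ptp(y) < 1e-3:
        return IsothermFit.failure("langmuir", len(x), "flat response; K unidentifiable")
    k_lo, k_hi = _k_bounds(x)
    best = _multistart(_langmuir, x, y, k_lo, k_hi, hill=False)
    if best is None:
        return IsothermFit.failure("langmuir", len(x), "optimizer did not converge")
    return _finish("langmuir", best, x, y, hill=False)


def fit_hill(curve: CorrectedCurve, fix_n: float | None = None) -> IsothermFit:
    """Fit the Hill equation (half-saturation parameterization, n in [0.5, 6]).

    ``fix_n`` freezes the Hill coefficient; ``fix_n=1`` reduces the model to
    the Langmuir isotherm exactly.
    """
    x, y = _check_curve(curve)
    if np.ptp(y) < 1e-3:
        return IsothermFit.failure("hill", len(x), "flat response; K unidentifiable")
    k_lo, k_hi = _k_bounds(x)
    best = _multistart(_hill, x, y, k_lo, k_hi, hill=True, fix_n=fix_n)
    if best is None:
        return IsothermFit.failure("hill", len(x), "optimizer did not converge")
    return _finish("hill", best, x, y, hill=True)


def _aicc(rss: float, n_points: int, n_params: int) -> float:
    if n_points - n_params - 1 <= 0:
        return math.inf
    rss = max(rss, 1e-12)  # guard exact fits against -inf log-likelihood
    return (
        n_points * math.log(rss / n_points)
        + 2 * n_params
        + 2 * n_params * (n_params + 1) / (n_points - n_params - 1)
    )


def compare_isotherms(curve: CorrectedCurve) -> ModelComparison:
    """Fit both isotherms and pick one by small-sample-corrected AIC.

    The Hill model nests the Langmuir model (n = 1), so the comparison is
    between 2 and 3 parameters; AICc makes the parsimony penalty explicit.
    A failed Langmuir fit auto-selects Hill (and vice versa); both failing
    raises ``RuntimeError``.
    """
    langmuir = fit_langmuir(curve)
    hill = fit_hill(curve)
    if not langmuir.success and not hill.success:
        raise RuntimeError(
            f"both isotherm fits failed: langmuir: {langmuir.message}; hill: {hill.message}"
        )
    aicc_l = _aicc(langmuir.rss, langmuir.n_points, 2) if langmuir.success else math.inf
    aicc_h = _aicc(hill.rss, hill.n_points, 3) if hill.success else math.inf
    preferred = "langmuir" if aicc_l <= aicc_h else "hill"
    return ModelComparison(preferred, langmuir, hill, aicc_l, aicc_h)


def censor_apparent_kd(fit: IsothermFit, limiting_40s: float) -> IsothermFit:
    """Flag apparent affinities at or below the limiting 40S concentration.

    When the fitted K_app is <= the 40S subunit concentration the titration
    is (partly) stoichiometric and the estimate is only an upper limit; the
    value is retained but marked censored with the limit recorded.  The
    boundary is inclusive.
    """
    if not fit.success:
        raise ValueError("cannot censor a failed fit")
    if fit.k_app <= limiting_40s:
        return replace(fit, censored=True, censor_limit=float(limiting_40s))
    return fit


def aggregate_replicates(values: Sequence[float]) -> ReplicateSummary:
    """Mean and SEM (sample SD / sqrt(n)) of per-replicate fitted parameters."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("no replicate values to aggregate")
    if arr.size == 1:
        return ReplicateSummary(float(arr[0]), math.nan, 1)
    sem = float(arr.std(ddof=1) / math.sqrt(arr.size))
    return ReplicateSummary(float(arr.mean()), sem, int(arr.size))
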