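"""Kinetic estimators: maximum dechlorination rate, first-order constants, CO IC50.

Estimators operate on per-flask analyte time courses (days, μmol) and
endpoint dose-response data.  The maximum dechlorination rate is the largest
ordinary-least-squares slope over a sliding window of consecutive sampling
points; first-order production/adsorption constants come from exponential
fits seeded by a log-linear regression; carbon monoxide dose-response uses a
four-parameter log-logistic curve parameterized directly on dose so that the
zero-dose control is a regular data point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "TimeSeries",
    "DoseResponse",
    "FitResult",
    "max_rate",
    "first_order_fit",
    "mitigation_margin",
    "ic50_fit",
    "four_pl",
    "co_yield",
]


class KineticsError(ValueError):
    """Raised for invalid series, doses or fit preconditions."""


@dataclass
class TimeSeries:
    """A per-flask analyte time course (times in days, values in μmol or copies/mL)."""

    times: np.ndarray
    values: np.ndarray
    analyte: str = ""
    flask_id: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise KineticsError("times and values must be 1-D arrays of equal length")
        if len(self.times) < 3:
            raise KineticsError("a time series needs at least 3 points")
        if np.any(np.diff(self.times) <= 0):
            raise KineticsError("times must be strictly increasing")
        if np.any(self.values < 0):
            raise KineticsError("amounts must be nonnegative")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class DoseResponse:
    """Endpoint inhibitor dose (μmol/flask) vs residual activity (μmol Cl- released)."""

    doses: np.ndarray
    responses: np.ndarray

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.doses.shape != self.responses.shape or self.doses.ndim != 1:
            raise KineticsError("doses and responses must be 1-D arrays of equal length")
        if np.any(self.doses < 0):
            raise KineticsError("doses must be nonnegative")
        if len(np.unique(self.doses)) < 4:
            raise KineticsError("four-parameter fitting needs at least 4 distinct doses")


@dataclass
class FitResult:
    """Named parameters with asymptotic standard errors and a convergence flag."""

    parameters: dict = field(default_factory=dict)
    standard_errors: dict = field(default_factory=dict)
    residual_sd: float = float("nan")
    converged: bool = True
    detail: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.converged:
            self.standard_errors = {}


def max_rate(ts: TimeSeries, window_points: int = 4) -> FitResult:
    """Maximum dechlorination rate (μmol Cl-/day) by sliding-window OLS.

    Fits an ordinary-least-squares line to every window of ``window_points``
    consecutive samples and returns the largest slope, its standard error and
    the window it came from.  ``window_points`` defaults to 4; widen it to the
    sustained linear phase when the whole course is linear.
    """
    n = len(ts)
    if not (3 <= window_points <= n):
        raise KineticsError(f"window_points must be in [3, {n}], got {window_points}")
    best = None
    for start in range(n - window_points + 1):
        sl = slice(start, start + window_points)
        res = stats.linregress(ts.times[sl], ts.values[sl])
        if best is None or res.slope > best[0]:
            resid = ts.values[sl] - (res.intercept + res.slope * ts.times[sl])
            dof = max(window_points - 2, 1)
            best = (res.slope, res.stderr, float(np.sqrt(np.sum(resid**2) / dof)), start)
    slope, stderr, resid_sd, start = best
    return FitResult(
        parameters={"rate": slope},
        standard_errors={"rate": stderr},
        residual_sd=resid_sd,
        converged=True,
        detail={"window_start_index": start, "window_points": window_points,
                "window_days": (float(ts.times[start]),
                                float(ts.times[start + window_points - 1]))},
    )


def _exp_model(t, a, k):
    return a * np.exp(k * t)


def first_order_fit(ts: TimeSeries, direction: str = "decay") -> FitResult:
    """First-order rate constant k (day^-1) from A*exp(k*t).

    ``direction='decay'`` (adsorptive loss to activated carbon; k <= 0)
    requires strictly positive values; ``direction='production'`` allows
    k >= 0.  A log-linear regression provides the starting point for the
    nonlinear least squares.
    """
    if direction not in ("decay", "production"):
        raise KineticsError("direction must be 'decay' or 'production'")
    if direction == "decay" and np.any(ts.values <= 0):
        raise KineticsError("decay fitting needs strictly positive values")
    t, y = ts.times, ts.values
    if np.all(y > 0):
        k0, loga0 = np.polyfit(t, np.log(y), 1)
        a0 = math.exp(loga0)
    else:
        k0, a0 = 0.0, max(float(np.mean(y)), 1e-12)
    try:
        popt, pcov = optimize.curve_fit(_exp_model, t, y, p0=[a0, k0], maxfev=10000)
    except (RuntimeError, optimize.OptimizeWarning):
        return FitResult(parameters={"a0": a0, "k": k0}, converged=False)
    perr = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else [np.nan, np.nan]
    resid = y - _exp_model(t, *popt)
    dof = max(len(t) - 2, 1)
    return FitResult(
        parameters={"a0": float(popt[0]), "k": float(popt[1])},
        standard_errors={"a0": float(perr[0]), "k": float(perr[1])},
        residual_sd=float(np.sqrt(np.sum(resid**2) / dof)),
        converged=True,
    )


def mitigation_margin(k_production: float, k_removal: float) -> tuple[float, bool]:
    """Margin (day^-1) by which first-order removal outpaces production.

    ``k_production`` is the daughter-product production constant (>= 0) and
    ``k_removal`` the adsorption constant on activated carbon (<= 0).
    Returns ``(|k_removal| - k_production, margin > 0)``.
    """
    if k_production < 0:
        raise KineticsError("production constant must be nonnegative")
    if k_removal > 0:
        raise KineticsError("removal constant must be nonpositive")
    margin = abs(k_removal) - k_production
    return margin, margin > 0


def four_pl(dose, top: float, bottom: float, ic50: float, hill: float):
    """Four-parameter log-logistic curve on the dose scale.

    response = bottom + (top - bottom) / (1 + (dose / ic50)^hill); the
    zero-dose response is exactly ``top``.
    """
    dose = np.asarray(dose, dtype=float)
    return bottom + (top - bottom) / (1.0 + (dose / ic50) ** hill)


def ic50_fit(dr: DoseResponse, ic50_max: float | None = None,
             weighting: str | None = "relative") -> FitResult:
    """Four-parameter log-logistic fit of an inhibition dose-response.

    Fits (top, bottom, ic50, hill) with bottom constrained >= 0 and, by
    default, ic50 bounded by roughly three times the largest dose (beyond
    which the half-maximal point is not identified by the design).  The
    default ``weighting='relative'`` scales residuals by the response
    magnitude, matching the constant-CV (multiplicative) error structure of
    replicate headspace-GC measurements; pass ``weighting=None`` for an
    unweighted fit.  A fit showing no inhibition (fitted top <= bottom) or
    failing to converge is returned flagged rather than raising.
    """
    doses, resp = dr.doses, dr.responses
    top0 = float(np.max(resp))
    bottom0 = max(float(np.min(resp)), 0.0)
    if top0 <= 0:
        return FitResult(parameters={}, converged=False)
    if ic50_max is None:
        ic50_max = 3.0 * float(np.max(doses))
    mid = bottom0 + 0.5 * (top0 - bottom0)
    above = doses[resp > mid]
    ic50_0 = float(np.median(above)) if len(above) else float(np.median(doses[doses > 0]))
    ic50_0 = min(max(ic50_0, 1e-3), ic50_max)
    p0 = [top0, bottom0, ic50_0, 1.5]
    bounds = ([0.0, 0.0, 1e-6, 0.2], [np.inf, np.inf, ic50_max, 10.0])
    if weighting == "relative":
        sigma = np.maximum(np.abs(resp), 0.05 * top0)
    elif weighting is None:
        sigma = None
    else:
        raise KineticsError("weighting must be 'relative' or None")
    try:
        popt, pcov = optimize.curve_fit(four_pl, doses, resp, p0=p0, bounds=bounds,
                                        sigma=sigma, maxfev=20000,
                                        xtol=1e-14, ftol=1e-14, gtol=1e-14)
    except (RuntimeError, ValueError):
        return FitResult(parameters={}, converged=False)
    top, bottom, ic50, hill = (float(v) for v in popt)
    if top <= bottom:  # monotonically rising data: no inhibition to halve
        return FitResult(parameters={"top": top, "bottom": bottom, "ic50": ic50, "hill": hill},
                         converged=False)
    perr = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else [np.nan] * 4
    resid = resp - four_pl(doses, *popt)
    dof = max(len(doses) - 4, 1)
    return FitResult(
        parameters={"top": top, "bottom": bottom, "ic50": ic50, "hill": hill},
        standard_errors=dict(zip(("top", "bottom", "ic50", "hill"), (float(e) for e in perr))),
        residual_sd=float(np.sqrt(np.sum(resid**2) / dof)),
        converged=True,
    )


def co_yield(co_umol: float, cl_umol: float, project_to_cl_umol: float = 0.0) -> tuple[float, float]:
    """CO produced per Cl- released, and its linear projection.

    Returns ``(co/cl, (co/cl) * project_to_cl)``.  The simple ratio is the
    bookkeeping used for autotoxicity projections; note that abstracts of
    closed-flask studies sometimes quote a per-parent rather than per-chloride
    basis, which this ratio makes explicit.
    """
    if cl_umol <= 0:
        raise KineticsError("chloride amount must be positive")
    y = co_umol / cl_umol
    return y, y * project_to_cl_umol
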