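"""Semi-lethal temperature (LT50) from specific extracellular resistance.

Freezing injury releases symplastic electrolytes into the apoplast, so the
specific extracellular resistance r_e of a tissue sample changes
sigmoidally with the exposure temperature.  The response is modelled with
the four-parameter logistic

    y(x) = A / (1 + exp(B * (C - x))) + D

where x is exposure temperature (deg C), y is r_e (ohm * m), A and D set
the two asymptotes, B (per deg C) the slope at the inflection and C (deg C)
the inflection temperature.  The inflection C is taken as the LT50: the
temperature at which half of the full resistance transition — and hence,
by proxy, half-lethal membrane injury — has occurred.  With B < 0, r_e
rises as temperature falls (the usual orientation for freeze injury).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import InsufficientDataError

__all__ = [
    "FreezeResponseSeries",
    "SigmoidFit",
    "LT50Estimate",
    "sigmoid",
    "fit_sigmoid",
    "estimate_lt50",
]

# quality flags
DEGENERATE = "DEGENERATE"
EXTRAPOLATED = "EXTRAPOLATED"
LOW_CONFIDENCE = "LOW_CONFIDENCE"

#: Fits with r^2 below this are reported but flagged LOW_CONFIDENCE.
R2_CONFIDENCE_THRESHOLD = 0.8

MIN_TEMPERATURES = 5

_EXP_CLAMP = 700.0


@dataclass(frozen=True)
class FreezeResponseSeries:
    """(temperature, r_e) observations for one condition cell.

    ``condition`` identifies the cell (species, moisture content %, cooling
    rate, duration); ``temperatures_c`` are the freezing exposures (<= 0),
    ``re_specific`` the matching specific extracellular resistances
    (ohm * m, > 0) and ``replicates`` an integer label per observation so
    several replicates may share a temperature.
    """

    condition: tuple
    temperatures_c: np.ndarray
    re_specific: np.ndarray
    replicates: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures_c, dtype=float)
        y = np.asarray(self.re_specific, dtype=float)
        if t.shape != y.shape or t.ndim != 1:
            raise ValueError("temperatures and re_specific must be matching 1-D arrays")
        reps = self.replicates
        if reps is None:
            reps = np.ones(len(t), dtype=int)
        else:
            reps = np.asarray(reps, dtype=int)
            if reps.shape != t.shape:
                raise ValueError("replicates must match temperatures in shape")
        if np.unique(t).size < MIN_TEMPERATURES:
            raise InsufficientDataError(
                f"need >= {MIN_TEMPERATURES} distinct temperatures, "
                f"got {np.unique(t).size}"
            )
        if np.any(t > 0):
            raise ValueError("exposure temperatures must be <= 0 deg C")
        if np.any(~np.isfinite(y)) or np.any(y <= 0):
            raise ValueError("re_specific must be finite and positive")
        object.__setattr__(self, "temperatures_c", t)
        object.__setattr__(self, "re_specific", y)
        object.__setattr__(self, "replicates", reps)

    def per_temperature_means(self) -> tuple[np.ndarray, np.ndarray]:
        """Unique temperatures (descending, i.e. warm to cold) and mean r_e."""
        t_unique = np.unique(self.temperatures_c)[::-1]
        means = np.array(
            [self.re_specific[self.temperatures_c == t].mean() for t in t_unique]
        )
        return t_unique, means


@dataclass(frozen=True)
class SigmoidFit:
    """Fitted four-parameter logistic; ``inflection_c`` is the LT50."""

    sig_a: float
    slope_b: float
    inflection_c: float
    offset_d: float
    r_squared: float
    converged: bool
    quality_flags: frozenset[str] = frozenset()


@dataclass(frozen=True)
class LT50Estimate:
    """LT50 (deg C) with the diagnostics of the fit behind it."""

    lt50_c: float
    r_squared: float
    converged: bool
    quality_flags: frozenset[str] = frozenset()
    fit: SigmoidFit | None = None


def sigmoid(x, params) -> np.ndarray | float:
    """Evaluate the logistic at ``x``.

    ``params`` may be a :class:`SigmoidFit` or an (A, B, C, D) sequence.
    The exponent is clamped to +/- 700 so extreme arguments saturate at the
    asymptotes instead of overflowing.
    """
    if isinstance(params, SigmoidFit):
        a, b, c, d = params.sig_a, params.slope_b, params.inflection_c, params.offset_d
    else:
        a, b, c, d = params
    x = np.asarray(x, dtype=float)
    expo = np.clip(b * (c - x), -_EXP_CLAMP, _EXP_CLAMP)
    out = a / (1.0 + np.exp(expo)) + d
    return float(out) if out.ndim == 0 else out


def _fit_window(series: FreezeResponseSeries,
                temperature_window: tuple[float, float] | None):
    t, y = series.per_temperature_means()
    if temperature_window is not None:
        lo, hi = min(temperature_window), max(temperature_window)
        keep = (t >= lo) & (t <= hi)
        t, y = t[keep], y[keep]
        if t.size < MIN_TEMPERATURES:
            raise InsufficientDataError(
                f"temperature window keeps {t.size} temperatures; "
                f">= {MIN_TEMPERATURES} required"
            )
    return t, y


def fit_sigmoid(
    series: FreezeResponseSeries,
    temperature_window: tuple[float, float] | None = None,
) -> SigmoidFit:
    """Nonlinear least squares fit of the logistic to per-temperature means.

    Initialisation reads the data: D0 = min(y), A0 = max(y) - min(y), C0 =
    the temperature whose mean is nearest the half-transition D0 + A0/2,
    and B0 = +/- 4 * (local slope at C0) / A0 — both signs are attempted
    because the orientation is not assumed, and the converged fit with the
    lower residual wins (ties go to B < 0, the physically usual direction).

    A constant series has no inflection: the result carries ``DEGENERATE``
    with ``converged=False``.
    """
    t, y = _fit_window(series, temperature_window)

    d0 = float(np.min(y))
    a0 = float(np.max(y) - np.min(y))
    if a0 <= 0 or np.allclose(y, y[0], rtol=1e-12, atol=0):
        return SigmoidFit(
            sig_a=0.0, slope_b=0.0, inflection_c=float(np.mean(t)), offset_d=d0,
            r_squared=0.0, converged=False, quality_flags=frozenset({DEGENERATE}),
        )

    half = d0 + a0 / 2.0
    k = int(np.argmin(np.abs(y - half)))
    c0 = float(t[k])
    # centred finite-difference slope near the half-transition point
    k_lo, k_hi = max(k - 1, 0), min(k + 1, len(t) - 1)
    dt = t[k_hi] - t[k_lo]
    slope = (y[k_hi] - y[k_lo]) / dt if dt != 0 else 0.0
    b_mag = abs(4.0 * slope / a0) if slope != 0 else 0.1

    def residuals(theta):
        return sigmoid(t, theta) - y

    span = float(t.max() - t.min())
    lo = [0.0, -np.inf, t.min() - 2 * span, -np.inf]
    hi = [np.inf, np.inf, t.max() + 2 * span, np.inf]

    best = None
    best_b_sign = 0.0
    for b0 in (-b_mag, b_mag):
        theta0 = np.array([a0, b0, c0, d0])
        sol = least_squares(
            residuals, theta0, bounds=(lo, hi),
            method="trf", xtol=1e-15, ftol=1e-15, gtol=None, max_nfev=2000,
        )
        better = (
            best is None
            or sol.cost < best.cost * (1 - 1e-12)
            or (abs(sol.cost - best.cost) <= 1e-12 * max(best.cost, 1e-300)
                and sol.x[1] < 0 <= best_b_sign)
        )
        if better:
            best, best_b_sign = sol, np.sign(sol.x[1])

    a, b, c, d = best.x
    ss_res = float(2.0 * best.cost)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    flags: set[str] = set()
    if r2 < R2_CONFIDENCE_THRESHOLD:
        flags.add(LOW_CONFIDENCE)
    return SigmoidFit(
        sig_a=float(a), slope_b=float(b), inflection_c=float(c), offset_d=float(d),
        r_squared=r2, converged=bool(best.success),
        quality_flags=frozenset(flags),
    )


def estimate_lt50(
    series: FreezeResponseSeries,
    temperature_window: tuple[float, float] | None = None,
) -> LT50Estimate:
    """LT50 of one condition cell: the fitted inflection temperature C.

    The estimate inherits the sigmoid fit's convergence flag and r^2; an
    inflection outside the observed temperature range is flagged
    ``EXTRAPOLATED`` (the fit is an extrapolation, not an interpolated
    transition).
    """
    fit = fit_sigmoid(series, temperature_window=temperature_window)
    flags = set(fit.quality_flags)
    t = series.temperatures_c
    if fit.converged and not (t.min() <= fit.inflection_c <= t.max()):
        flags.add(EXTRAPOLATED)
    return LT50Estimate(
        lt50_c=fit.inflection_c,
        r_squared=fit.r_squared,
        converged=fit.converged,
        quality_flags=frozenset(flags),
        fit=fit,
    )
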