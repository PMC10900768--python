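"""Single distributed-circuit-element (DCE) impedance model.

Plant tissue measured over a frequency sweep traces a depressed circular
arc in the Nyquist plane.  The single-DCE (Cole-type) model captures it
with four parameters:

    Z(omega) = R_inf + R / (1 + (i * tau * omega)**psi)

where ``R_inf`` (ohm) is the high-frequency limiting resistance, ``R``
(ohm) the difference between the direct-current resistance and ``R_inf``,
``tau`` (s) the relaxation time and ``psi`` in (0, 1] the distribution
coefficient (arc-depression exponent; psi = 1 is an ideal RC semicircle).

From a fitted arc the lumped two-pathway resistances follow:

    Re = R_inf + R                 (extracellular, low-frequency current path)
    Ri = R_inf * (1 + R_inf / R)   (intracellular)

which satisfy 1/Re + 1/Ri = 1/R_inf exactly.  Both are normalised by the
electrode geometry, r = (A / l) * R, to specific resistances in ohm * m.

The complex power uses the principal branch; because the base is a positive
real multiple of i, (i*tau*omega)**psi = (tau*omega)**psi * exp(i*psi*pi/2)
with no branch ambiguity, and Im(Z) <= 0 for all psi in (0, 1].
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .spectra import ImpedanceSpectrum, SampleMeta

__all__ = [
    "DCEParameters",
    "DCEFitResult",
    "LumpedResistances",
    "ParameterBounds",
    "DEFAULT_BOUNDS",
    "dce_impedance",
    "initial_guess",
    "fit_dce",
    "extracellular_resistance",
    "intracellular_resistance",
    "specific_resistance",
    "lumped_resistances",
]

# quality flags
NO_ARC = "NO_ARC"
EDGE_OF_BOUNDS = "EDGE_OF_BOUNDS"


@dataclass(frozen=True)
class DCEParameters:
    """Parameters of the single-DCE arc (all strictly positive, psi <= 1)."""

    r_inf: float
    r_arc: float
    tau: float
    psi: float

    def __post_init__(self) -> None:
        if not (self.r_inf > 0 and self.r_arc > 0 and self.tau > 0):
            raise ValueError("r_inf, r_arc and tau must be positive")
        if not (0 < self.psi <= 1):
            raise ValueError(f"psi must lie in (0, 1], got {self.psi!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.r_inf, self.r_arc, self.tau, self.psi])


@dataclass(frozen=True)
class LumpedResistances:
    """Extracellular/intracellular resistances, lumped and geometry-specific."""

    re_ohm: float
    ri_ohm: float
    re_specific: float
    ri_specific: float


@dataclass(frozen=True)
class DCEFitResult:
    """Fitted parameters plus diagnostics of one spectrum fit."""

    params: DCEParameters
    residual_norm: float
    converged: bool
    n_iter: int
    quality_flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.residual_norm < 0:
            raise ValueError("residual_norm must be >= 0")


@dataclass(frozen=True)
class ParameterBounds:
    """Box constraints for the fit, (low, high) per parameter."""

    r_inf: tuple[float, float] = (1e-6, 1e12)
    r_arc: tuple[float, float] = (1e-6, 1e12)
    tau: tuple[float, float] = (1e-9, 1e3)
    psi: tuple[float, float] = (0.3, 1.0)

    def contains(self, p: DCEParameters) -> bool:
        return (
            self.r_inf[0] <= p.r_inf <= self.r_inf[1]
            and self.r_arc[0] <= p.r_arc <= self.r_arc[1]
            and self.tau[0] <= p.tau <= self.tau[1]
            and self.psi[0] <= p.psi <= self.psi[1]
        )

    def clip(self, p: DCEParameters) -> DCEParameters:
        return DCEParameters(
            r_inf=float(np.clip(p.r_inf, *self.r_inf)),
            r_arc=float(np.clip(p.r_arc, *self.r_arc)),
            tau=float(np.clip(p.tau, *self.tau)),
            psi=float(np.clip(p.psi, *self.psi)),
        )


#: Default box: spans many decades of resistance so the intracellular path
#: (1e-6 .. 1e-7 of the extracellular one in sapwood) fits with margin.
DEFAULT_BOUNDS = ParameterBounds()


def dce_impedance(
    params: DCEParameters, frequencies: np.ndarray | list[float]
) -> np.ndarray:
    """Forward-evaluate the model at the given frequencies (Hz).

    Returns complex impedance in ohms, one value per frequency.
    """
    f = np.asarray(frequencies, dtype=float)
    if np.any(f <= 0):
        raise ValueError("frequencies must be positive")
    omega = 2.0 * math.pi * f
    x = (params.tau * omega) ** params.psi
    rot = np.exp(1j * params.psi * math.pi / 2.0)
    return params.r_inf + params.r_arc / (1.0 + x * rot)


def extracellular_resistance(params: DCEParameters) -> float:
    """Lumped extracellular resistance Re = R_inf + R, ohm."""
    return params.r_inf + params.r_arc


def intracellular_resistance(params: DCEParameters) -> float:
    """Lumped intracellular resistance Ri = R_inf * (1 + R_inf / R), ohm."""
    if params.r_arc == 0:
        raise ValueError("r_arc must be nonzero for Ri")
    return params.r_inf * (1.0 + params.r_inf / params.r_arc)


def specific_resistance(resistance: float, meta: SampleMeta) -> float:
    """Geometry-normalised specific resistance (A / l) * R, ohm * m."""
    if meta.cross_area <= 0 or meta.length <= 0:
        raise ValueError("geometry must be positive")
    if resistance < 0:
        raise ValueError("resistance must be >= 0")
    return (meta.cross_area / meta.length) * resistance


def lumped_resistances(
    params: DCEParameters, meta: SampleMeta | None = None
) -> LumpedResistances:
    """Derive Re, Ri and (with geometry) their specific values."""
    re_ohm = extracellular_resistance(params)
    ri_ohm = intracellular_resistance(params)
    if meta is None:
        meta = SampleMeta(sample_id="<default-geometry>")
    return LumpedResistances(
        re_ohm=re_ohm,
        ri_ohm=ri_ohm,
        re_specific=specific_resistance(re_ohm, meta),
        ri_specific=specific_resistance(ri_ohm, meta),
    )


def initial_guess(
    spectrum: ImpedanceSpectrum, bounds: ParameterBounds = DEFAULT_BOUNDS
) -> tuple[DCEParameters, frozenset[str]]:
    """Starting point for the nonlinear fit, read off the raw sweep.

    ``r_inf`` from the high-frequency plateau (min of the real part),
    ``r_arc`` from the arc width (range of the real part, floored so the
    guess stays strictly positive), ``tau`` from the frequency of the
    -Im(Z) peak (for psi = 1 the peak sits exactly at omega * tau = 1) and
    psi = 0.8, a typical arc depression for woody tissue.

    When -Im(Z) has no interior peak (monotone, or no capacitive response
    at all) the guess carries the ``NO_ARC`` flag; the fit is still
    attempted from it.
    """
    zr = spectrum.z_real
    neg_zi = -spectrum.z_imag
    flags: set[str] = set()

    r_inf0 = float(np.min(zr))
    r_arc0 = max(float(np.max(zr) - np.min(zr)), 1e-6 * r_inf0)

    k = int(np.argmax(neg_zi))
    if neg_zi[k] <= 0 or k in (0, len(neg_zi) - 1):
        flags.add(NO_ARC)
    f_peak = spectrum.frequencies[k]
    tau0 = 1.0 / (2.0 * math.pi * f_peak)

    guess = bounds.clip(DCEParameters(r_inf=r_inf0, r_arc=r_arc0, tau=tau0, psi=0.8))
    return guess, frozenset(flags)


def _theta_from_params(p: DCEParameters) -> np.ndarray:
    return np.array([math.log10(p.r_inf), math.log10(p.r_arc), math.log10(p.tau), p.psi])


def _params_from_theta(theta: np.ndarray) -> DCEParameters:
    return DCEParameters(
        r_inf=10.0 ** theta[0],
        r_arc=10.0 ** theta[1],
        tau=10.0 ** theta[2],
        psi=min(float(theta[3]), 1.0),
    )


def _residuals(theta: np.ndarray, omega: np.ndarray, zr: np.ndarray,
               zi: np.ndarray, modulus_weight: bool) -> np.ndarray:
    r_inf = 10.0 ** theta[0]
    r_arc = 10.0 ** theta[1]
    tau = 10.0 ** theta[2]
    psi = theta[3]
    x = (tau * omega) ** psi
    z = r_inf + r_arc / (1.0 + x * np.exp(1j * psi * math.pi / 2.0))
    if modulus_weight:
        w = 1.0 / np.abs(z)
    else:
        w = np.ones_like(omega)
    return np.concatenate([(z.real - zr) * w, (z.imag - zi) * w])


def residual_norm(
    spectrum: ImpedanceSpectrum, params: DCEParameters, weighting: str = "modulus"
) -> float:
    """Objective value (weighted SSR) of ``params`` on ``spectrum``."""
    res = _residuals(
        _theta_from_params(params),
        spectrum.omega,
        spectrum.z_real,
        spectrum.z_imag,
        weighting == "modulus",
    )
    return float(np.sum(res**2))


def _restart_seed(spectrum: ImpedanceSpectrum) -> int:
    sid = spectrum.meta.sample_id if spectrum.meta is not None else ""
    return zlib.crc32(sid.encode("utf-8"))


def fit_dce(
    spectrum: ImpedanceSpectrum,
    weighting: str = "modulus",
    bounds: ParameterBounds = DEFAULT_BOUNDS,
    max_restarts: int = 5,
) -> DCEFitResult:
    """Complex nonlinear least squares fit of the single-DCE model.

    The residual stacks the real and imaginary misfits; under ``modulus``
    weighting (the default) each point is weighted by 1/|Z_model| so the
    low- and high-frequency ends of a sweep spanning orders of magnitude
    contribute comparably, while ``unit`` weighting leaves them raw.
    R_inf, R and tau are optimised in log10 space (they are positive scale
    parameters), psi directly within its box.

    If the first solve does not converge, up to ``max_restarts`` restarts
    are made from log-uniformly jittered (x0.3 .. x3) copies of the initial
    guess, seeded deterministically from the sample id; a fit that still
    fails returns ``converged=False`` with the best diagnostics found
    rather than raising.
    """
    if weighting not in ("unit", "modulus"):
        raise ValueError(f"weighting must be 'unit' or 'modulus', got {weighting!r}")
    guess, flags = initial_guess(spectrum, bounds)
    if not bounds.contains(guess):
        raise ValueError("initial guess outside fit bounds")

    omega = spectrum.omega
    zr, zi = spectrum.z_real, spectrum.z_imag
    lo = np.array([
        math.log10(bounds.r_inf[0]), math.log10(bounds.r_arc[0]),
        math.log10(bounds.tau[0]), bounds.psi[0],
    ])
    hi = np.array([
        math.log10(bounds.r_inf[1]), math.log10(bounds.r_arc[1]),
        math.log10(bounds.tau[1]), bounds.psi[1],
    ])

    def solve(theta0: np.ndarray):
        theta0 = np.clip(theta0, lo, hi)
        return least_squares(
            _residuals,
            theta0,
            bounds=(lo, hi),
            args=(omega, zr, zi, weighting == "modulus"),
            method="trf",
            xtol=1e-15,
            ftol=1e-15,
            gtol=None,
            max_nfev=4000,
        )

    theta_guess = _theta_from_params(guess)
    best = solve(theta_guess)
    n_iter = best.nfev
    if not best.success:
        rng = np.random.default_rng(_restart_seed(spectrum))
        for _ in range(max_restarts):
            jitter = rng.uniform(math.log10(0.3), math.log10(3.0), size=3)
            theta0 = theta_guess.copy()
            theta0[:3] += jitter
            theta0[3] = rng.uniform(bounds.psi[0], bounds.psi[1])
            trial = solve(theta0)
            n_iter += trial.nfev
            if trial.cost < best.cost or (trial.success and not best.success):
                best = trial
            if best.success:
                break

    fit_flags = set(flags)
    # edge detection in the optimisation coordinates (log10 units / psi units)
    at_edge = np.minimum(np.abs(best.x - lo), np.abs(hi - best.x)) < 1e-6
    if np.any(at_edge):
        fit_flags.add(EDGE_OF_BOUNDS)

    return DCEFitResult(
        params=_params_from_theta(best.x),
        residual_norm=float(2.0 * best.cost),
        converged=bool(best.success),
        n_iter=int(n_iter),
        quality_flags=frozenset(fit_flags),
    )
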