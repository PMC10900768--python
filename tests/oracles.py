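"""Independent brute-force oracles used by the test suite.

Kept free of any dependence on the code paths they check: the grid search
below evaluates the arc model directly on a dense logarithmic lattice and
returns the best unweighted sum of squared residuals found, nothing more.
"""

import numpy as np


def grid_search_best(spectrum, bounds, points_per_decade=50, n_psi=36):
    """Exhaustive lattice search of the single-DCE objective.

    Logarithmic grids at ``points_per_decade`` for the three positive scale
    parameters over ``bounds``, a linear grid of ``n_psi`` points for psi,
    unit weighting.  Exploits that Z is affine in (R_inf, R) at fixed
    (tau, psi) to evaluate whole resistance planes at once; every lattice
    node is still evaluated exactly.

    Returns (best_ssr, (r_inf, r_arc, tau, psi)).
    """

    def loggrid(lo, hi):
        n = max(2, int(round(np.log10(hi / lo) * points_per_decade)) + 1)
        return np.logspace(np.log10(lo), np.log10(hi), n)

    g_rinf = loggrid(*bounds.r_inf)
    g_rarc = loggrid(*bounds.r_arc)
    g_tau = loggrid(*bounds.tau)
    g_psi = np.linspace(bounds.psi[0], bounds.psi[1], n_psi)

    omega = spectrum.omega
    zr, zi = spectrum.z_real, spectrum.z_imag
    best = np.inf
    arg = None
    for tau in g_tau:
        for psi in g_psi:
            g = 1.0 / (1.0 + (tau * omega) ** psi * np.exp(1j * psi * np.pi / 2.0))
            zre = g_rinf[:, None, None] + g_rarc[None, :, None] * g.real
            zim = np.broadcast_to(
                g_rarc[None, :, None] * g.imag, zre.shape
            )
            ssr = ((zre - zr) ** 2).sum(-1) + ((zim - zi) ** 2).sum(-1)
            k = np.unravel_index(np.argmin(ssr), ssr.shape)
            if ssr[k] < best:
                best = float(ssr[k])
                arg = (g_rinf[k[0]], g_rarc[k[1]], float(tau), float(psi))
    return best, arg


def narrow_box(params, half_decades=0.25, psi_range=(0.3, 1.0)):
    """A bound box of +/- ``half_decades`` around true scale parameters."""
    from frosteis.dce import ParameterBounds

    h = 10.0**half_decades
    return ParameterBounds(
        r_inf=(params.r_inf / h, params.r_inf * h),
        r_arc=(params.r_arc / h, params.r_arc * h),
        tau=(params.tau / h, params.tau * h),
        psi=psi_range,
    )
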