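import numpy as np
import pytest

import frosteis as fe


@pytest.fixture
def freq_grid():
    """40 log-spaced frequencies over the measurement band, Hz."""
    return np.logspace(np.log10(80.0), 6.0, 40)


@pytest.fixture
def canonical_params():
    """A well-conditioned reference arc used across the suite."""
    return fe.DCEParameters(r_inf=100.0, r_arc=900.0, tau=1e-3, psi=0.8)


@pytest.fixture
def make_spectrum(freq_grid):
    """Factory: forward-model spectrum with optional proportional noise."""

    def _make(params, noise=0.0, rng=None, frequencies=None, meta=None):
        f = freq_grid if frequencies is None else np.asarray(frequencies)
        z = fe.dce_impedance(params, f)
        zr, zi = z.real.copy(), z.imag.copy()
        if noise > 0:
            if rng is None:
                raise ValueError("noise > 0 needs an rng")
            zr *= 1.0 + rng.normal(0.0, noise, len(f))
            zi *= 1.0 + rng.normal(0.0, noise, len(f))
        return fe.ImpedanceSpectrum(frequencies=f, z_real=zr, z_imag=zi, meta=meta)

    return _make
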