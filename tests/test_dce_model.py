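import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import frosteis as fe
from frosteis.dce import DEFAULT_BOUNDS, NO_ARC

positive_scale = st.floats(min_value=1e-2, max_value=1e6)
tau_values = st.floats(min_value=1e-7, max_value=1e-1)
psi_values = st.floats(min_value=0.3, max_value=1.0)


def f_at_omega_tau_one(tau):
    return 1.0 / (2.0 * math.pi * tau)


class TestForwardModel:
    def test_low_frequency_limit_is_dc_resistance(self):
        p = fe.DCEParameters(100, 900, 1e-3, 1.0)
        z = fe.dce_impedance(p, [1e-9])[0]
        assert z.real == pytest.approx(1000.0, rel=1e-9)
        assert z.imag == pytest.approx(0.0, abs=1e-3)

    def test_characteristic_frequency_ideal_capacitor(self):
        # at omega*tau = 1 and psi = 1: Z = R_inf + R*(1 - i)/2
        p = fe.DCEParameters(100, 900, 1e-3, 1.0)
        z = fe.dce_impedance(p, [f_at_omega_tau_one(1e-3)])[0]
        assert z == pytest.approx(550 - 450j, rel=1e-12)

    @pytest.mark.parametrize("psi", [0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0])
    def test_characteristic_frequency_closed_form(self, psi):
        # real part R_inf + R/2 for every psi; imaginary -R/2 * tan(psi*pi/4)
        p = fe.DCEParameters(100, 900, 1e-3, psi)
        z = fe.dce_impedance(p, [f_at_omega_tau_one(1e-3)])[0]
        assert z.real == pytest.approx(550.0, rel=1e-12)
        assert z.imag == pytest.approx(-450.0 * math.tan(psi * math.pi / 4), rel=1e-12)

    def test_rejects_invalid_psi_and_frequencies(self):
        with pytest.raises(ValueError):
            fe.DCEParameters(100, 900, 1e-3, 1.2)
        with pytest.raises(ValueError):
            fe.DCEParameters(100, 900, 1e-3, 0.0)
        p = fe.DCEParameters(100, 900, 1e-3, 0.8)
        with pytest.raises(ValueError):
            fe.dce_impedance(p, [-10.0])

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(r_inf=positive_scale, r_arc=positive_scale, tau=tau_values, psi=psi_values)
    def test_capacitive_sign_and_monotone_real_part(self, r_inf, r_arc, tau, psi):
        p = fe.DCEParameters(r_inf, r_arc, tau, psi)
        f = np.logspace(-2, 8, 300)
        z = fe.dce_impedance(p, f)
        assert np.all(z.imag <= 1e-12 * (r_inf + r_arc))
        assert np.all(np.diff(z.real) <= 1e-12 * (r_inf + r_arc))

    def test_ideal_arc_lies_on_semicircle(self):
        # psi = 1: locus is the circle centred at (R_inf + R/2, 0), radius R/2
        p = fe.DCEParameters(100, 900, 1e-3, 1.0)
        f = np.logspace(-3, 9, 2000)
        z = fe.dce_impedance(p, f)
        radius = np.hypot(z.real - (100 + 450), z.imag)
        assert np.max(np.abs(radius - 450.0)) <= 1e-9 * 900


class TestLumpedResistances:
    @pytest.mark.parametrize(
        "r_inf, r_arc, re_expected, ri_expected",
        [(100, 900, 1000, 100 * (1 + 1 / 9)), (1, 1, 2, 2), (100, 100, 200, 200)],
    )
    def test_two_pathway_values(self, r_inf, r_arc, re_expected, ri_expected):
        p = fe.DCEParameters(r_inf, r_arc, 1e-3, 0.8)
        assert fe.extracellular_resistance(p) == pytest.approx(re_expected)
        assert fe.intracellular_resistance(p) == pytest.approx(ri_expected)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(r_inf=positive_scale, r_arc=positive_scale)
    def test_parallel_pathway_identity(self, r_inf, r_arc):
        # 1/Re + 1/Ri = 1/R_inf for every parameter pair
        p = fe.DCEParameters(r_inf, r_arc, 1e-3, 0.8)
        lhs = 1 / fe.extracellular_resistance(p) + 1 / fe.intracellular_resistance(p)
        assert lhs == pytest.approx(1 / r_inf, rel=1e-12)

    def test_specific_resistance_geometry(self):
        meta = fe.SampleMeta(sample_id="g")  # 1 cm cube defaults
        assert fe.specific_resistance(1000.0, meta) == pytest.approx(10.0)
        assert fe.specific_resistance(0.0, meta) == 0.0
        big = fe.SampleMeta(sample_id="g2", cross_area=2e-4)
        assert fe.specific_resistance(2000.0, big) == pytest.approx(40.0)
        with pytest.raises(ValueError):
            fe.specific_resistance(-1.0, meta)

    def test_extracellular_exceeds_intracellular_when_arc_dominates(self):
        p = fe.DCEParameters(10.0, 1000.0, 1e-3, 0.8)
        lumped = fe.lumped_resistances(p)
        assert lumped.re_ohm > lumped.ri_ohm


class TestInitialGuess:
    def test_reads_plateaus_and_peak(self, canonical_params):
        f = np.logspace(np.log10(80), 6, 200)
        p = fe.DCEParameters(100, 900, 1e-3, 1.0)
        z = fe.dce_impedance(p, f)
        spec = fe.ImpedanceSpectrum(f, z.real, z.imag)
        guess, flags = fe.initial_guess(spec)
        assert not flags
        # for psi = 1 the -Im(Z) peak sits exactly at omega*tau = 1
        grid_step = f[1] / f[0]
        assert guess.tau / 1e-3 == pytest.approx(1.0, rel=grid_step - 1)
        assert guess.r_inf <= 110.0
        assert guess.r_arc >= 600.0
        assert guess.psi == 0.8

    def test_flat_imaginary_part_flags_no_arc(self, freq_grid):
        spec = fe.ImpedanceSpectrum(
            freq_grid, np.linspace(1000, 100, len(freq_grid)),
            np.zeros(len(freq_grid)),
        )
        _, flags = fe.initial_guess(spec)
        assert NO_ARC in flags


class TestFit:
    def test_zero_noise_self_consistency(self, canonical_params, make_spectrum):
        spec = make_spectrum(canonical_params)
        result = fe.fit_dce(spec)
        assert result.converged
        rel = np.abs(result.params.as_array() / canonical_params.as_array() - 1.0)
        assert np.max(rel) <= 1e-6
        # composition: recovered Re matches the planted DC resistance
        assert fe.extracellular_resistance(result.params) == pytest.approx(
            1000.0, abs=1e-3
        )

    def test_noise_error_grows_with_noise_level(self, canonical_params, make_spectrum):
        rng = np.random.default_rng(1905)
        medians = []
        for sigma in (0.005, 0.01, 0.02, 0.05):
            errs = []
            for _ in range(40):
                spec = make_spectrum(canonical_params, noise=sigma, rng=rng)
                res = fe.fit_dce(spec)
                errs.append(
                    np.abs(res.params.as_array() / canonical_params.as_array() - 1)
                )
            medians.append(np.median(np.array(errs)))
        assert all(a < b for a, b in zip(medians, medians[1:]))

    def test_no_arc_input_still_fits_with_flag(self, freq_grid):
        spec = fe.ImpedanceSpectrum(
            freq_grid, np.full(len(freq_grid), 500.0), np.zeros(len(freq_grid))
        )
        result = fe.fit_dce(spec)
        assert NO_ARC in result.quality_flags

    def test_edge_of_bounds_flagged(self, canonical_params, make_spectrum):
        from frosteis.dce import ParameterBounds

        spec = make_spectrum(canonical_params)
        # box whose psi ceiling sits below the true 0.8: fit must land on it
        box = ParameterBounds(psi=(0.3, 0.6))
        result = fe.fit_dce(spec, bounds=box)
        assert "EDGE_OF_BOUNDS" in result.quality_flags

    def test_unit_and_modulus_weighting_agree_at_zero_noise(
        self, canonical_params, make_spectrum
    ):
        spec = make_spectrum(canonical_params)
        for weighting in ("unit", "modulus"):
            res = fe.fit_dce(spec, weighting=weighting)
            rel = np.abs(res.params.as_array() / canonical_params.as_array() - 1.0)
            assert np.max(rel) <= 1e-6

    def test_default_bounds_contain_study_scale_parameters(self):
        p = fe.DCEParameters(3e-4, 2e3, 1e-3, 0.8)
        assert DEFAULT_BOUNDS.contains(p)
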