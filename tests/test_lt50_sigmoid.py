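import numpy as np
import pytest

import frosteis as fe
from frosteis.errors import InsufficientDataError
from frosteis.lt50 import DEGENERATE, EXTRAPOLATED, LOW_CONFIDENCE

TRUE = (40.0, -0.3, -45.0, 5.0)  # (A, B, C, D)
TEMPS = np.arange(-10.0, -81.0, -10.0)


def make_series(params=TRUE, temps=TEMPS, noise=0.0, replicates=1, rng=None,
                scale=1.0):
    t_all, y_all, r_all = [], [], []
    y0 = np.asarray(fe.sigmoid(temps, params)) * scale
    for rep in range(1, replicates + 1):
        y = y0.copy()
        if noise > 0:
            y = y0 * (1.0 + rng.normal(0.0, noise, len(temps)))
        t_all.append(temps)
        y_all.append(y)
        r_all.append(np.full(len(temps), rep))
    return fe.FreezeResponseSeries(
        condition=("Pi", 100.0, "Slow", 0.5),
        temperatures_c=np.concatenate(t_all),
        re_specific=np.concatenate(y_all),
        replicates=np.concatenate(r_all),
    )


class TestSigmoidFunction:
    def test_midpoint_value_is_half_amplitude(self):
        assert fe.sigmoid(-45.0, TRUE) == pytest.approx(25.0)

    def test_asymptotes_with_falling_orientation(self):
        # B < 0: resistance rises toward cold, so cold limit is A + D
        assert fe.sigmoid(-1e6, TRUE) == pytest.approx(45.0)
        assert fe.sigmoid(1e6, TRUE) == pytest.approx(5.0)

    def test_extreme_arguments_do_not_overflow(self):
        out = fe.sigmoid(np.array([-1e8, 1e8]), (1.0, -50.0, 0.0, 0.0))
        assert np.all(np.isfinite(out))


class TestFit:
    def test_noiseless_recovery_exact(self):
        fit = fe.fit_sigmoid(make_series())
        assert fit.converged
        assert fit.inflection_c == pytest.approx(-45.0, abs=1e-6)
        assert fit.sig_a == pytest.approx(40.0, rel=1e-6)
        assert fit.slope_b == pytest.approx(-0.3, rel=1e-6)
        assert fit.offset_d == pytest.approx(5.0, rel=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_rising_orientation_also_recovered(self):
        # positive B: resistance falling toward cold; both signs are tried
        fit = fe.fit_sigmoid(make_series(params=(40.0, 0.3, -45.0, 5.0)))
        assert fit.converged
        assert fit.inflection_c == pytest.approx(-45.0, abs=1e-6)
        assert fit.slope_b > 0

    def test_constant_series_is_degenerate(self):
        series = fe.FreezeResponseSeries(
            condition=("x",),
            temperatures_c=TEMPS,
            re_specific=np.full(len(TEMPS), 7.0),
        )
        fit = fe.fit_sigmoid(series)
        assert not fit.converged
        assert DEGENERATE in fit.quality_flags

    def test_too_few_temperatures_rejected(self):
        with pytest.raises(InsufficientDataError):
            fe.FreezeResponseSeries(
                condition=("x",),
                temperatures_c=np.array([-10.0, -20.0, -30.0, -40.0]),
                re_specific=np.array([5.0, 6.0, 30.0, 44.0]),
            )

    def test_temperature_window_restricts_fit(self):
        series = make_series(temps=np.arange(-10.0, -121.0, -10.0))
        fit = fe.fit_sigmoid(series, temperature_window=(-10.0, -80.0))
        assert fit.converged
        assert fit.inflection_c == pytest.approx(-45.0, abs=1e-6)


class TestEstimateLT50:
    def test_noiseless_estimate_equals_planted_inflection(self):
        est = fe.estimate_lt50(make_series())
        assert est.lt50_c == pytest.approx(-45.0, abs=1e-6)
        assert est.converged
        assert est.lt50_c < 0

    def test_translation_equivariance(self):
        base = fe.estimate_lt50(make_series()).lt50_c
        shifted_temps = TEMPS - 10.0
        shifted = make_series(params=(40.0, -0.3, -55.0, 5.0), temps=shifted_temps)
        assert fe.estimate_lt50(shifted).lt50_c - base == pytest.approx(-10.0, abs=1e-9)

    def test_scale_invariance(self):
        base = fe.estimate_lt50(make_series()).lt50_c
        scaled = fe.estimate_lt50(make_series(scale=3.7)).lt50_c
        assert scaled == pytest.approx(base, abs=1e-9)

    def test_inflection_outside_observed_range_flagged(self):
        # transition centred below the coldest observation: extrapolation
        series = make_series(
            params=(40.0, -0.3, -78.0, 5.0), temps=np.arange(-10.0, -61.0, -10.0)
        )
        est = fe.estimate_lt50(series)
        if est.converged:
            assert est.lt50_c < -60.0
            assert EXTRAPOLATED in est.quality_flags

    def test_poor_fit_flagged_low_confidence(self):
        rng = np.random.default_rng(11)
        y = rng.uniform(5.0, 45.0, len(TEMPS))
        series = fe.FreezeResponseSeries(
            condition=("x",), temperatures_c=TEMPS, re_specific=y
        )
        est = fe.estimate_lt50(series)
        if est.r_squared < 0.8:
            assert LOW_CONFIDENCE in est.quality_flags

    def test_recovery_improves_with_replication(self):
        # SD of the estimated inflection shrinks as replicates grow
        sds = []
        for reps in (1, 3, 5, 10):
            rng = np.random.default_rng(900 + reps)
            chat = [
                fe.estimate_lt50(
                    make_series(noise=0.05, replicates=reps, rng=rng)
                ).lt50_c
                for _ in range(120)
            ]
            sds.append(np.std(chat, ddof=1))
        assert all(a > b for a, b in zip(sds, sds[1:]))
        assert abs(np.mean(chat) + 45.0) < 0.5  # 10-replicate bias is small
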