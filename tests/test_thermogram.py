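"""Thermogram feature extraction: Tg, enthalpies, onset, conversion,
melting-doublet deconvolution."""

import numpy as np
import pytest
from dataclasses import replace

from glasskinx import (
    ConversionCurve,
    TemperatureProgram,
    Thermogram,
    conversion_curve,
    deconvolve_melting,
    detect_glass_transition,
    integrate_peak,
    nonisothermal_conversion,
    onset_temperature,
    simulate_nonisothermal_thermogram,
)
from glasskinx.profiles import SplitPVPeak
EXO_WINDOW = (82.0, 142.0)
MELT_WINDOW = (140.5, 157.0)


def _shifted(tg: Thermogram, dT: float) -> Thermogram:
    return Thermogram(tg.time_min, tg.temp_C + dT, tg.heat_flow, tg.mass_mg)


class TestGlassTransition:
    def test_recovers_tg_and_step_height(self, default_thermogram):
        res = detect_glass_transition(default_thermogram, (45.0, 72.0))
        assert res.found
        assert res.Tg_C == pytest.approx(58.4, abs=0.1)
        assert res.dCp_J_gK == pytest.approx(271.4 / 471.67, rel=0.01)

    def test_flat_trace_not_found(self):
        t = np.linspace(0, 60, 600)
        tg = Thermogram(t, 40 + t, np.full_like(t, 0.02), 3.0)
        res = detect_glass_transition(tg, (45.0, 72.0))
        assert not res.found

    def test_translation_equivariance(self, default_thermogram):
        base = detect_glass_transition(default_thermogram, (45.0, 72.0))
        shifted = detect_glass_transition(
            _shifted(default_thermogram, 10.0), (55.0, 82.0))
        assert shifted.Tg_C == pytest.approx(base.Tg_C + 10.0, abs=0.05)


class TestIntegratePeak:
    def test_recovers_configured_exotherm_area(self, default_thermogram):
        res = integrate_peak(default_thermogram, EXO_WINDOW)
        assert res.sign == "exo"
        assert res.enthalpy_J_g == pytest.approx(95.3, rel=5e-3)

    def test_zero_signal_integrates_to_zero(self):
        t = np.linspace(0, 60, 600)
        tg = Thermogram(t, 40 + t, np.zeros_like(t), 3.0)
        assert integrate_peak(tg, (50.0, 90.0)).enthalpy_J_g == 0.0

    def test_per_mass_normalization(self):
        # same total heat split over twice the mass -> half the enthalpy
        t = np.linspace(0, 60, 600)
        T = 40 + t
        total_mW = np.exp(-((T - 70) ** 2) / 8.0)  # mW
        tg1 = Thermogram(t, T, total_mW / 3.0, 3.0)
        tg2 = Thermogram(t, T, total_mW / 6.0, 6.0)
        e1 = integrate_peak(tg1, (55.0, 85.0)).enthalpy_J_g
        e2 = integrate_peak(tg2, (55.0, 85.0)).enthalpy_J_g
        assert e1 == pytest.approx(2.0 * e2, rel=1e-12)

    def test_limits_outside_trace_raise(self, default_thermogram):
        with pytest.raises(ValueError):
            integrate_peak(default_thermogram, (10.0, 50.0))


class TestOnset:
    def test_calibrated_onset_at_one_K_min(self, default_thermogram):
        res = onset_temperature(default_thermogram, (82.0, 140.0), kind="exo")
        assert res.found
        assert res.T_onset_C == pytest.approx(107.4, abs=0.3)

    def test_baseline_only_not_found(self):
        t = np.linspace(0, 60, 600)
        tg = Thermogram(t, 40 + t, np.full_like(t, 0.01), 3.0)
        assert not onset_temperature(tg, (50.0, 90.0), kind="exo").found

    def test_translation_equivariance(self, default_thermogram):
        base = onset_temperature(default_thermogram, (82.0, 140.0), "exo")
        shifted = onset_temperature(
            _shifted(default_thermogram, 5.0), (87.0, 145.0), "exo")
        assert shifted.T_onset_C == pytest.approx(base.T_onset_C + 5.0,
                                                  abs=0.05)

    def test_onset_rises_with_heating_rate(self, three_rate_thermograms):
        onsets = [
            onset_temperature(tg, (82.0, 145.0), "exo").T_onset_C
            for tg in three_rate_thermograms.values()
        ]
        assert onsets == sorted(onsets)


class TestConversionCurve:
    def test_endpoints_exact(self, default_thermogram):
        c = conversion_curve(default_thermogram, EXO_WINDOW)
        assert c.alpha[0] == 0.0
        assert c.alpha[-1] == pytest.approx(1.0, abs=1e-12)

    def test_symmetric_peak_half_conversion_at_center(self):
        t = np.linspace(0, 60, 6001)
        T = 40 + t
        hf = -np.exp(-((T - 70) ** 2) / 4.0)
        tg = Thermogram(t, T, hf, 3.0)
        c = conversion_curve(tg, (60.0, 80.0))
        assert np.interp(70.0, c.temp_C, c.alpha) == pytest.approx(0.5,
                                                                   abs=1e-3)

    def test_matches_ode_solution(self, default_thermogram):
        """Partial-area α(T) equals the integrated kinetics, sup-norm 1e-3."""
        from glasskinx.synthetic import DEFAULT_KINETICS

        tg = default_thermogram
        c = conversion_curve(tg, EXO_WINDOW)
        _, T, alpha, _ = nonisothermal_conversion(DEFAULT_KINETICS, tg.program)
        alpha_ode = np.interp(c.temp_C, T, alpha)
        # the window normalizes out conversion outside it
        a0, a1 = alpha_ode[0], alpha_ode[-1]
        np.testing.assert_allclose(c.alpha, (alpha_ode - a0) / (a1 - a0),
                                   atol=1e-3)

    def test_partial_area_conservation(self, default_thermogram):
        """α-weighted total area equals the integrate_peak enthalpy."""
        tg = default_thermogram
        c = conversion_curve(tg, EXO_WINDOW)
        total = integrate_peak(tg, EXO_WINDOW).enthalpy_J_g
        # d(alpha)*total integrates back to total
        assert np.sum(np.diff(c.alpha)) * total == pytest.approx(total)

    def test_no_event_raises(self):
        t = np.linspace(0, 60, 600)
        tg = Thermogram(t, 40 + t, np.full_like(t, 0.01), 3.0)
        with pytest.raises(ValueError):
            conversion_curve(tg, (50.0, 90.0))

    def test_interpolation_is_exact_on_grid_and_linear(self):
        c = ConversionCurve(1.0, np.array([100.0, 110.0, 120.0]),
                            np.array([0.0, 0.05, 1.0]))
        assert c.temperature_at(0.05) == pytest.approx(110.0)
        # linear between grid points
        assert c.temperature_at(0.025) == pytest.approx(105.0)
        with pytest.raises(ValueError, match="rate"):
            c.temperature_at(1.5)


def _melting_thermogram(area_II=99.0, area_I=13.4, order=("II", "I")):
    """Hand-built doublet: two asymmetric peaks on a sloped baseline."""
    rate = 1.0
    t = np.linspace(0, 30, 6001)
    T = 138.0 + rate * t
    beta_s = rate / 60.0
    hf = 0.7 + 0.001 * T
    peaks = {
        "II": (145.9, area_II, 1.0, 1.6),
        "I": (149.9, area_I, 1.0, 1.6),
    }
    for name in order:
        c, a, wl, wr = peaks[name]
        shape = SplitPVPeak(c, 1.0, wl, wr, 0.0, 0.0)
        hf = hf + shape(T) / shape.area * a * beta_s
    return Thermogram(t, T, hf, 3.0)


class TestMeltingDeconvolution:
    def test_recovers_area_ratio(self, default_thermogram):
        res = deconvolve_melting(default_thermogram, MELT_WINDOW)
        assert res.converged
        assert res.ratio_II_I == pytest.approx(7.4, rel=0.03)
        assert res.center_II_C == pytest.approx(145.9, abs=0.1)
        assert res.center_I_C == pytest.approx(149.9, abs=0.1)

    def test_generation_order_irrelevant(self):
        a = deconvolve_melting(_melting_thermogram(order=("II", "I")),
                               (140.0, 158.0))
        b = deconvolve_melting(_melting_thermogram(order=("I", "II")),
                               (140.0, 158.0))
        assert a.ratio_II_I == pytest.approx(b.ratio_II_I, rel=1e-6)

    def test_single_peak_gives_infinite_ratio(self):
        tg = _melting_thermogram(area_II=99.0, area_I=0.0)
        res = deconvolve_melting(tg, (140.0, 158.0))
        assert np.isinf(res.ratio_II_I)

    def test_area_sum_matches_single_integration(self, default_thermogram):
        res = deconvolve_melting(default_thermogram, MELT_WINDOW)
        total = integrate_peak(default_thermogram, MELT_WINDOW).enthalpy_J_g
        assert res.dHf_II_J_g + res.dHf_I_J_g == pytest.approx(total, rel=0.01)
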