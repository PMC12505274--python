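"""KAS isoconversional regression, frequency factors and ANCOVA."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glasskinx import (
    ArrheniusAvramiKinetics,
    R_GAS,
    TemperatureProgram,
    ancova_compare,
    extract_iso_temperatures,
    frequency_factor,
    kas_regression,
    kas_summary,
    nonisothermal_conversion,
)
from glasskinx.kas import KASRegression
from glasskinx.synthetic import DEFAULT_KINETICS
from glasskinx.types import ConversionCurve


class TestFrequencyFactor:
    # printed KAS results (Ea kJ/mol, intercept, alpha, n) -> ln A
    @pytest.mark.parametrize(
        "Ea,intercept,alpha,n,expected",
        [
            (134.0e3, 54.2, 0.05, 4.7, 63.3),
            (115.0e3, 47.7, 0.05, 4.1, 56.5),
            (128.2e3, 52.2, 0.10, 4.7, 61.4),
            (110.7e3, 46.3, 0.10, 4.1, 55.2),
        ],
    )
    def test_published_worked_examples(self, Ea, intercept, alpha, n, expected):
        assert frequency_factor(Ea, intercept, alpha, n) == pytest.approx(
            expected, abs=0.1)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            frequency_factor(1e5, 50.0, 1.0, 4.0)
        with pytest.raises(ValueError):
            frequency_factor(1e5, 50.0, 0.05, 0.0)
        with pytest.raises(ValueError):
            frequency_factor(-1e5, 50.0, 0.05, 4.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        Ea=st.floats(5e4, 3e5),
        alpha=st.floats(0.01, 0.5),
        n=st.floats(1.0, 8.0),
        i1=st.floats(10.0, 60.0),
        i2=st.floats(10.0, 60.0),
    )
    def test_additive_structure(self, Ea, alpha, n, i1, i2):
        """lnA − intercept depends only on (Ea, α, n)."""
        d1 = frequency_factor(Ea, i1, alpha, n) - i1
        d2 = frequency_factor(Ea, i2, alpha, n) - i2
        assert d1 == pytest.approx(d2, abs=1e-9)


class TestKASRegression:
    def test_exact_line_recovers_slope(self):
        # three points exactly on y = 10 - 16000 x
        T = np.array([360.0, 380.0, 400.0])
        x = 1.0 / T
        beta = T**2 * np.exp(10.0 - 16000.0 * x)  # so ln(beta/T^2) = y
        reg = KASRegression().fit(beta, T)
        assert reg.Ea_ == pytest.approx(16000.0 * R_GAS, rel=1e-9)  # 133.0 kJ/mol
        assert reg.se_Ea_ == pytest.approx(0.0, abs=1e-4)
        assert reg.intercept_ == pytest.approx(10.0, abs=1e-9)
        assert reg.r2_ == pytest.approx(1.0)

    def test_too_few_rates_raise(self):
        with pytest.raises(ValueError, match="3 heating rates"):
            KASRegression().fit([0.5, 1.0], [370.0, 380.0])

    def test_degenerate_temperatures_raise(self):
        with pytest.raises(ValueError, match="degenerate"):
            KASRegression().fit([0.5, 1.0, 2.0], [380.0, 380.0, 380.0])


class TestIsoTemperatures:
    def test_grid_point_and_linearity(self):
        c = ConversionCurve(1.0, np.array([100.0, 106.85, 120.0]),
                            np.array([0.0, 0.05, 1.0]))
        table = extract_iso_temperatures([c], [0.05, 0.525])
        assert table.row(0.05)[0] == pytest.approx(106.85 + 273.15)
        assert table.row(0.525)[0] == pytest.approx(113.425 + 273.15)

    def test_out_of_range_alpha_names_rate(self):
        c = ConversionCurve(2.0, np.array([100.0, 120.0]),
                            np.array([0.2, 1.0]))
        with pytest.raises(ValueError, match="2.0"):
            extract_iso_temperatures([c], [0.05])

    def test_matches_bisection_on_ode(self, three_rate_curves):
        """Partial-area inversion vs brute-force inversion of α(T)."""
        table = extract_iso_temperatures(three_rate_curves, [0.05, 0.10])
        for j, rate in enumerate((0.5, 1.0, 2.0)):
            prog = TemperatureProgram.single_ramp(25, 160, rate)
            _, T, alpha, _ = nonisothermal_conversion(
                DEFAULT_KINETICS, prog, t_eval=prog.time_grid(max_dT_C=0.005))
            for i, a in enumerate((0.05, 0.10)):
                T_oracle = np.interp(a, alpha, T) + 273.15
                assert table.T_K[i, j] == pytest.approx(T_oracle, abs=0.05)


class TestRoundTrip:
    def test_recovers_activation_energy_and_frequency_factor(
            self, three_rate_curves):
        table = extract_iso_temperatures(three_rate_curves,
                                         [0.05, 0.075, 0.10])
        for a in (0.05, 0.075, 0.10):
            pt = kas_regression(table, a)
            assert pt.Ea_J_mol == pytest.approx(DEFAULT_KINETICS.Ea_J_mol,
                                                rel=0.02)
            lnA = frequency_factor(pt.Ea_J_mol, pt.intercept, a,
                                   DEFAULT_KINETICS.n)
            assert lnA == pytest.approx(DEFAULT_KINETICS.lnA, rel=0.05)

    def test_ea_flat_in_alpha_for_single_step_kinetics(self, three_rate_curves):
        alphas = [round(a, 2) for a in np.arange(0.05, 0.55, 0.05)]
        table = extract_iso_temperatures(three_rate_curves, alphas)
        pts = [kas_regression(table, a) for a in alphas]
        eas = np.array([p.Ea_J_mol for p in pts])
        ses = np.array([max(p.se_Ea_J_mol, 1e-9) for p in pts])
        assert np.all(np.abs(eas - DEFAULT_KINETICS.Ea_J_mol)
                      <= np.maximum(3 * ses, 0.02 * DEFAULT_KINETICS.Ea_J_mol))

    def test_intercept_identity_inverts_exactly(self, three_rate_curves):
        table = extract_iso_temperatures(three_rate_curves, [0.05])
        pt = kas_regression(table, 0.05)
        lnA = frequency_factor(pt.Ea_J_mol, pt.intercept, 0.05, 4.7)
        g = (-np.log1p(-0.05)) ** (1 / 4.7)
        back = lnA - np.log(pt.Ea_J_mol * g / R_GAS)
        assert back == pytest.approx(pt.intercept, abs=1e-12)

    def test_two_process_mixture_gives_decreasing_ea(self):
        """Multistep kinetics: apparent Ea falls with conversion."""
        hot = ArrheniusAvramiKinetics(170e3, 50.4, 4.0)   # dominates early
        cold = ArrheniusAvramiKinetics(100e3, 27.0, 4.0)  # dominates late
        curves = []
        for rate in (0.5, 1.0, 2.0):
            prog = TemperatureProgram.single_ramp(25, 160, rate)
            t, T, a1, _ = nonisothermal_conversion(hot, prog)
            _, _, a2, _ = nonisothermal_conversion(cold, prog)
            mix = 0.5 * a1 + 0.5 * a2
            curves.append(ConversionCurve(rate, T, mix / mix[-1]))
        alphas = [0.10, 0.50, 0.80]
        table = extract_iso_temperatures(curves, alphas)
        eas = [kas_regression(table, a).Ea_J_mol for a in alphas]
        assert eas[0] > eas[1] > eas[2]


class TestAncova:
    def test_offset_groups_detected_on_intercept_only(self):
        rng = np.random.default_rng(0)
        x = np.linspace(1.0, 2.0, 6)
        y1 = 2.0 + 3.0 * x + rng.normal(0, 0.01, 6)
        y2 = 4.0 + 3.0 * x + rng.normal(0, 0.01, 6)
        res = ancova_compare((x, y1), (x, y2))
        assert res.p_slope > 0.05
        assert res.p_intercept < 1e-4

    def test_identical_noise_free_groups_degenerate(self):
        x = np.linspace(0, 1, 5)
        y = 1.0 + 2.0 * x
        res = ancova_compare((x, y), (x, y))
        assert res.degenerate
        assert res.p_slope == 1.0 and res.p_intercept == 1.0

    def test_small_groups_raise(self):
        with pytest.raises(ValueError):
            ancova_compare(([1, 2], [1, 2]), ([1, 2, 3], [1, 2, 3]))


def test_summary_table_shape(three_rate_curves):
    curves = {"A": three_rate_curves, "B": three_rate_curves}
    df = kas_summary(curves, [0.05, 0.10], {"A": 4.7, "B": 4.1})
    assert set(df.columns) >= {"alpha", "condition", "Ea_kJ_mol", "intercept",
                               "lnA", "r2", "p_slope", "p_intercept"}
    assert len(df) == 4
    # identical curve sets -> degenerate ANCOVA flagged as p = 1
    assert df.loc[df.condition == "B", "p_slope"].notna().all()
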