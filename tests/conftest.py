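import pytest

from glasskinx import (
    DEFAULT_KINETICS,
    TemperatureProgram,
    conversion_curve,
    simulate_nonisothermal_thermogram,
)

EXO_WINDOW = (82.0, 142.0)
MELT_WINDOW = (140.5, 157.0)


@pytest.fixture(scope="session")
def default_thermogram():
    """Noise-free thermogram of the well-nucleated glass at 1 °C/min."""
    return simulate_nonisothermal_thermogram()


@pytest.fixture(scope="session")
def three_rate_thermograms():
    """Noise-free thermograms at the three analysis heating rates."""
    out = {}
    for rate in (0.5, 1.0, 2.0):
        program = TemperatureProgram.single_ramp(25.0, 160.0, rate)
        out[rate] = simulate_nonisothermal_thermogram(
            kin=DEFAULT_KINETICS, program=program
        )
    return out


@pytest.fixture(scope="session")
def three_rate_curves(three_rate_thermograms):
    """Partial-area conversion curves for the three heating rates."""
    return [
        conversion_curve(tg, EXO_WINDOW)
        for tg in three_rate_thermograms.values()
    ]
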