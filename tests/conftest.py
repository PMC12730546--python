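import numpy as np
import pytest

from metasers import plasmon

SILVER_EPS = -29.8 + 0.38j  # silver at 785 nm
EPS_FRONT = 1.0  # air / free front half-space
EPS_SUBSTRATE = 2.5  # polycarbonate


@pytest.fixture(scope="session")
def silver():
    return plasmon.OpticalMedium(SILVER_EPS, wavelength_nm=785.0)


@pytest.fixture(scope="session")
def fig_design():
    """The resonant design: L = 400 nm, h = 80 nm, d = 15 nm silver film."""
    return plasmon.MetasurfaceSpec(400.0, 80.0, 15.0)


@pytest.fixture(scope="session")
def silver_geometry(silver, fig_design):
    return plasmon.CylinderGeometry(
        fig_design.alpha,
        fig_design.a,
        (
            plasmon.OpticalMedium(EPS_FRONT),
            silver,
            plasmon.OpticalMedium(EPS_SUBSTRATE),
        ),
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240)
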