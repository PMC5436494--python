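import numpy as np
import pytest

import rampkin as rk


@pytest.fixture(scope="session")
def scheme():
    return rk.snar_scheme()


@pytest.fixture(scope="session")
def design():
    return rk.CampaignDesign()


@pytest.fixture(scope="session")
def clean_table(design, scheme):
    """Noiseless default 12-ramp campaign."""
    return rk.run_campaign(design, scheme)


@pytest.fixture(scope="session")
def small_design():
    """Reduced 3-temperature x 2-equivalents design for expensive fits
    (keeps the reference temperature so the two-stage protocol applies)."""
    return rk.CampaignDesign(
        equivalents_levels=(1.5, 7.0), temperatures_C=(30.0, 90.0, 120.0)
    )


@pytest.fixture(scope="session")
def iso_design():
    """Isothermal design at the reference temperature (90 C)."""
    return rk.CampaignDesign(temperatures_C=(90.0,))


@pytest.fixture(scope="session")
def geometry():
    return rk.ReactorGeometry()


@pytest.fixture(scope="session")
def ethanol():
    return rk.FluidProperties()


@pytest.fixture(scope="session")
def no_expansion():
    return rk.ThermalExpansionModel(alpha_v=0.0)


def relerr(a, b):
    return abs(a - b) / abs(b)


@pytest.fixture(scope="session")
def rel():
    return relerr
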