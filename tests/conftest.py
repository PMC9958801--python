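import numpy as np
import pytest

from biofet2d import (BandStructure, SheetChargeModel, ThermalState)
from biofet2d.presets import table1, table1_functionalized, KQ_PH3, KQ_PH9


@pytest.fixture(scope="session")
def thermal():
    return ThermalState(300.0)


@pytest.fixture(scope="session")
def mos2_sheet(thermal):
    """Two-valley n-type MoS2 conduction band."""
    band = BandStructure(carrier_type="n", m1_rel=0.54, m2_rel=0.58,
                         g1=2, g2=6, de12_ev=0.07)
    return SheetChargeModel(band=band, thermal=thermal)


@pytest.fixture(scope="session")
def baseline():
    """MoS2 BioFET baseline device in ISFET mode (uncharged membrane)."""
    return table1(ph=5.0)


@pytest.fixture(scope="session")
def strep_pair():
    """Functionalized device: buffer vs 100 fM streptavidin at pH 3."""
    buffer = table1_functionalized(ph=3.0, kq=KQ_PH3, nt=0.0)
    bound = table1_functionalized(ph=3.0, kq=KQ_PH3, nt=100e-15)
    return buffer, bound


@pytest.fixture(scope="session")
def coarse_grid():
    """Shared Vlg grid (V) wide enough for every threshold in the tests."""
    return np.arange(-0.2, 1.1001, 0.01)
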