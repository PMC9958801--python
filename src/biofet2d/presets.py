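"""Device presets.

``table1`` reproduces the exfoliated-MoS2 BioFET on 270 nm SiO2 with a
30 nm HfO2 barrier oxide, liquid-gated through an Ag/AgCl reference
electrode, that the model was validated against: a 5 um x 20 um n-type
channel, two conduction valleys (masses 0.54/0.58 m0, degeneracies 2/6,
split by 70 meV), mobility 20 cm^2/Vs, water-like electrolyte and
membrane permittivities (80 eps0), Stern capacitance 20 uF/cm^2, 1 mM
1:1 salt, and an HfO2 hydroxyl site density of 4e14 cm^-2 with
pKa = pKb = 7.

The biotin-streptavidin sensing variant (``table1_functionalized``)
assumes the functionalization leaves 1% of the hydroxyl sites available
(Ns = 4e12 cm^-2) and adds a Langmuir membrane with biotin receptor
density 2.3e13 cm^-2, binding constant 1e13 1/M and a 5 nm membrane
height.  The net streptavidin charge kq is pH dependent (positive below
the isoelectric point pI ~ 5.04): +22.3 at pH 3 and -15.2 at pH 9; at
other pH values it must be supplied by the user.
"""

from __future__ import annotations

from .channel import BandStructure, SheetChargeModel, ThermalState
from .constants import EPS_0
from .electrolyte import ElectrolyteSpec, MembraneSpec
from .oxide import SiteBindingSpec
from .study import Study
from .transport import DeviceParams

__all__ = ["table1", "table1_functionalized", "KQ_PH3", "KQ_PH9"]

#: Net streptavidin charge (elementary charges per molecule) below/above
#: its isoelectric point, as predicted by PROPKA for pH 3 and pH 9.
KQ_PH3 = +22.3
KQ_PH9 = -15.2


def table1(ph: float = 5.0, temperature: float = 300.0) -> Study:
    """Baseline MoS2 BioFET in ion-sensing (ISFET) mode: no membrane charge."""
    thermal = ThermalState(temperature)
    sheet = SheetChargeModel(
        band=BandStructure(carrier_type="n", m1_rel=0.54, m2_rel=0.58,
                           g1=2, g2=6, de12_ev=0.07),
        thermal=thermal,
    )
    device = DeviceParams(
        w=20e-6, l=5e-6,
        t_tox=30e-9, t_box=270e-9,
        eps_tox=25.0 * EPS_0, eps_box=3.9 * EPS_0,
        vgo=0.48, vbo=0.0,
        mu=20e-4,           # 20 cm^2/Vs
        sheet=sheet,
    )
    electrolyte = ElectrolyteSpec(
        i0=1e-3,            # 1 mM
        eps_w=80.0 * EPS_0,
        eps_m=80.0 * EPS_0,
        c_stern=0.2,        # 20 uF/cm^2
        thermal=thermal,
    )
    site = SiteBindingSpec(ns=4e18, pka=7.0, pkb=7.0, ph=ph)  # 4e14 cm^-2
    # Full membrane parameter set; kq = 0 keeps it uncharged (ISFET mode)
    # until a molecular net charge is supplied.
    membrane = MembraneSpec.langmuir(
        nr=2.3e17,          # 2.3e13 cm^-2
        nt=100e-15,         # 100 fM
        kc=1e13,            # 1/M
        hm=5e-9,            # 5 nm
        kq=0.0,
    )
    return Study(device=device, electrolyte=electrolyte, site=site,
                 membrane=membrane, vds=1.0)


def table1_functionalized(ph: float = 3.0, kq: float = KQ_PH3,
                          nt: float = 0.0, temperature: float = 300.0) -> Study:
    """Biotin-functionalized surface with a streptavidin Langmuir membrane.

    Parameters
    ----------
    ph : float
        Solution pH (drives both the residual site binding and, through
        the user-chosen ``kq``, the membrane charge sign).
    kq : float
        Net charge per bound streptavidin (elementary charges, signed).
    nt : float
        Streptavidin molar concentration, mol/L (0 = buffer only).
    """
    study = table1(ph=ph, temperature=temperature)
    return study.with_sites(4e16).with_target(nt, kq=kq)  # Ns = 4e12 cm^-2
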