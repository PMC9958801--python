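"""Sheet-charge statistics of a two-valley 2D semiconductor channel.

The mobile charge of a monolayer transition-metal dichalcogenide (TMD)
channel is described in the effective-mass approximation: a parabolic
dispersion around the two lowest conduction (or highest valence) valleys,
populated with Fermi-Dirac statistics.  Integrating the Fermi-Dirac
occupation over a constant 2D density of states yields a closed form for
the sheet charge,

    n-type:  sigma_2D(phi_ch) = -phi_th * Cdq * log(1 + exp(-phi_ch/phi_th))

where ``phi_ch`` is the chemical potential (band edge minus quasi-Fermi
level, in volts), ``phi_th = kB*T/q`` the thermal voltage and
``Cdq = q^2 * D0`` the degenerate quantum capacitance -- the upper limit of
the channel charge-voltage response reached deep in degeneracy.  The
second valley enters the areal density of states ``D0`` through a
Boltzmann factor of the inter-valley separation, which in most TMDs is
only a few ``kB*T`` and therefore not negligible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import HBAR, K_B, M_E, Q_E

__all__ = [
    "ThermalState",
    "BandStructure",
    "SheetChargeModel",
    "density_of_states",
    "sheet_charge",
    "u_value",
]


def _softplus(x):
    """Numerically stable log(1 + exp(x)), elementwise.

    Branches at x = 0 so that neither exp() overflows: for x > 0 the
    identity log(1+e^x) = x + log1p(e^-x) is used.  Safe for
    |x| up to at least 2000.
    """
    x = np.asarray(x, dtype=float)
    pos = x > 0
    out = np.log1p(np.exp(-np.abs(x)))
    out = np.where(pos, x + out, out)
    return out


def _match_scalar(value, template):
    if np.isscalar(template) or np.ndim(template) == 0:
        return float(value)
    return value


@dataclass(frozen=True)
class ThermalState:
    """Lattice/electrolyte temperature and the derived thermal voltage."""

    temperature: float = 300.0

    def __post_init__(self) -> None:
        if not self.temperature > 0:
            raise ValueError("temperature must be positive (kelvin)")

    @property
    def phi_th(self) -> float:
        """Thermal voltage kB*T/q in volts."""
        return K_B * self.temperature / Q_E


@dataclass(frozen=True)
class BandStructure:
    """Two-valley effective-mass band structure of the 2D channel.

    Parameters
    ----------
    carrier_type : {"n", "p"}
        Conduction branch of the device.
    m1_rel, m2_rel : float
        Effective masses of the first and second valley in units of the
        free-electron mass.
    g1, g2 : int
        Valley degeneracy factors.
    de12_ev : float
        Energy separation between the first and second valley, eV.
    """

    carrier_type: str
    m1_rel: float
    m2_rel: float
    g1: int
    g2: int
    de12_ev: float

    def __post_init__(self) -> None:
        if self.carrier_type not in ("n", "p"):
            raise ValueError("carrier_type must be 'n' or 'p'")
        if self.m1_rel <= 0 or self.m2_rel <= 0:
            raise ValueError("effective masses must be positive")
        if self.g1 < 1 or self.g2 < 1:
            raise ValueError("valley degeneracies must be >= 1")
        if self.de12_ev < 0:
            raise ValueError("inter-valley separation must be >= 0")


def density_of_states(band: BandStructure, thermal: ThermalState) -> float:
    """Areal density of states of the two lowest valleys, 1/(J*m^2).

    D0 = g1*m1/(2*pi*hbar^2) + g2*m2/(2*pi*hbar^2) * exp(-dE12/kB*T)

    The second valley is thermally weighted by its energy separation from
    the first; valleys further up in the band structure are neglected.
    """
    base = 1.0 / (2.0 * np.pi * HBAR**2)
    m1 = band.m1_rel * M_E
    m2 = band.m2_rel * M_E
    boltz = np.exp(-band.de12_ev * Q_E / (K_B * thermal.temperature))
    return band.g1 * m1 * base + band.g2 * m2 * base * boltz


@dataclass(frozen=True)
class SheetChargeModel:
    """Band structure + temperature, with the derived DOS and quantum capacitance."""

    band: BandStructure
    thermal: ThermalState = ThermalState()

    @property
    def d0(self) -> float:
        """Areal density of states, 1/(J*m^2)."""
        return density_of_states(self.band, self.thermal)

    @property
    def c_dq(self) -> float:
        """Degenerate quantum capacitance q^2 * D0, F/m^2."""
        return Q_E**2 * self.d0

    @property
    def phi_th(self) -> float:
        return self.thermal.phi_th


def u_value(phi_ch, model: SheetChargeModel):
    """Dimensionless occupation function u(phi_ch) >= 0.

    u = log(1 + exp(-phi_ch/phi_th)) for n-type (mirrored for p-type);
    the sheet charge magnitude is exactly phi_th * Cdq * u.
    """
    x = np.asarray(phi_ch, dtype=float) / model.phi_th
    if model.band.carrier_type == "n":
        u = _softplus(-x)
    else:
        u = _softplus(x)
    return _match_scalar(u, phi_ch)


def sheet_charge(phi_ch, model: SheetChargeModel):
    """Sheet charge density sigma_2D(phi_ch) in C/m^2.

    Negative (electrons) for n-type, positive (holes) for p-type.  Stable
    over |phi_ch/phi_th| <= 2000.
    """
    u = u_value(phi_ch, model)
    sign = -1.0 if model.band.carrier_type == "n" else 1.0
    return _match_scalar(sign * model.phi_th * model.c_dq * np.asarray(u), phi_ch)
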