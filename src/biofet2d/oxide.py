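"""Site-binding charge of the amphoteric barrier-oxide surface.

Hydroxyl groups on the oxide surface (-MOH) exchange protons with the
electrolyte, forming protonated (-MOH2+) and deprotonated (-MO-) species.
At equilibrium the two reactions are governed by the dissociation
constants Ka and Kb (dimensionless molar activities), and the surface
proton activity follows the bulk one through a Boltzmann factor of the
oxide surface potential psi0 (taken relative to the bulk electrolyte).
Eliminating the individual site densities gives the closed-form surface
charge used here, bounded by +/- q*Ns and vanishing at the point of zero
charge pH_pzc = (pKa + pKb)/2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .channel import ThermalState
from .constants import Q_E

__all__ = [
    "SiteBindingSpec",
    "surface_proton_activity",
    "oxide_surface_charge",
    "surface_charge",
    "site_fractions",
    "point_of_zero_charge",
]


@dataclass(frozen=True)
class SiteBindingSpec:
    """Amphoteric surface chemistry of the barrier oxide.

    Parameters
    ----------
    ns : float
        Total surface site density, 1/m^2 (0 disables the surface charge,
        e.g. for a fully functionalized surface).
    pka, pkb : float
        -log10 of the two dissociation constants (dimensionless molar
        activity scale).
    ph : float
        Bulk pH, so the bulk proton activity is 10**(-ph).
    """

    ns: float
    pka: float
    pkb: float
    ph: float

    def __post_init__(self) -> None:
        if self.ns < 0:
            raise ValueError("site density ns must be >= 0")

    @property
    def ka(self) -> float:
        return 10.0 ** (-self.pka)

    @property
    def kb(self) -> float:
        return 10.0 ** (-self.pkb)

    @property
    def bulk_activity(self) -> float:
        return 10.0 ** (-self.ph)


def surface_proton_activity(ph: float, psi0, thermal: ThermalState):
    """Proton activity at the oxide surface (dimensionless).

    a_H+,s = 10**(-pH) * exp(-psi0/phi_th): a positive surface potential
    repels protons from the surface.
    """
    return 10.0 ** (-ph) * np.exp(-np.asarray(psi0, dtype=float) / thermal.phi_th)


def oxide_surface_charge(a_hs, spec: SiteBindingSpec):
    """Surface charge density sigma_0 in C/m^2 from the surface proton activity.

    sigma_0 = q*Ns * (a^2 - Ka*Kb) / (a^2 + Kb*a + Ka*Kb), strictly inside
    (-q*Ns, +q*Ns) and monotone increasing in the activity ``a_hs``.
    """
    a = np.asarray(a_hs, dtype=float)
    if np.any(a <= 0):
        raise ValueError("surface proton activity must be positive")
    ka, kb = spec.ka, spec.kb
    num = a * a - ka * kb
    den = a * a + kb * a + ka * kb
    out = Q_E * spec.ns * num / den
    return float(out) if np.ndim(a_hs) == 0 else out


def surface_charge(spec: SiteBindingSpec, psi0, thermal: ThermalState):
    """sigma_0(psi0): site-binding charge at surface potential psi0 (V)."""
    return oxide_surface_charge(surface_proton_activity(spec.ph, psi0, thermal), spec)


def site_fractions(spec: SiteBindingSpec, psi0: float, thermal: ThermalState):
    """Diagnostic: fractions of (-MOH2+, -MOH, -MO-) sites at psi0."""
    a = surface_proton_activity(spec.ph, psi0, thermal)
    ka, kb = spec.ka, spec.kb
    den = a * a + kb * a + ka * kb
    return a * a / den, kb * a / den, ka * kb / den


def point_of_zero_charge(spec: SiteBindingSpec) -> float:
    """pH at which the surface is uncharged for psi0 = 0: (pKa + pKb)/2."""
    return 0.5 * (spec.pka + spec.pkb)
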