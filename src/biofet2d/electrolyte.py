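"""Electrolyte-side charge: diffuse layer, Donnan membrane and Langmuir binding.

The electrolyte is a symmetric 1:1 salt of ionic strength ``i0``.  The
layer of receptor-target macromolecules bound near the oxide is treated
as a planar ion-permeable membrane carrying a uniform volumetric fixed
charge ``Nm`` (signed by the net molecular charge).  The membrane is
assumed thick enough for internal charge neutrality, so its core sits at
the Donnan potential

    psi_DP = phi_th * asinh(Nm / (2*n0))

relative to the bulk.  The combined membrane + diffuse-layer charge per
unit area follows from a first integral of the Poisson-Boltzmann
equation; for ``Nm = 0`` it collapses to the classical Gouy-Chapman
expression.  The occupancy of surface receptors by targets at molar
concentration ``Nt`` is the equilibrium Langmuir isotherm
``Kc*Nt / (1 + Kc*Nt)``.

All potentials here are measured relative to the bulk electrolyte
(local minus bulk).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .channel import ThermalState
from .constants import EPS_0, N_A, Q_E

__all__ = [
    "ElectrolyteSpec",
    "MembraneSpec",
    "bulk_ion_concentration",
    "langmuir_membrane_charge",
    "donnan_potential",
    "membrane_diffuse_charge",
]


def bulk_ion_concentration(i0: float) -> float:
    """Number concentration of ions n0 (1/m^3) from molarity i0 (mol/L)."""
    if i0 < 0:
        raise ValueError("ionic concentration must be >= 0")
    return N_A * i0 * 1e3


@dataclass(frozen=True)
class ElectrolyteSpec:
    """Bulk electrolyte, Stern layer and membrane permittivity.

    Parameters
    ----------
    i0 : float
        Ionic molar concentration, mol/L.
    eps_w : float
        Electrolyte permittivity, F/m (default 80*eps0 for water).
    eps_m : float, optional
        Membrane permittivity, F/m; defaults to ``eps_w`` (macromolecule
        layer treated as water-like unless overridden).
    c_stern : float
        Stern-layer capacitance per unit area, F/m^2.
    thermal : ThermalState
    """

    i0: float
    eps_w: float = 80.0 * EPS_0
    eps_m: float | None = None
    c_stern: float = 0.2
    thermal: ThermalState = field(default_factory=ThermalState)

    def __post_init__(self) -> None:
        if self.i0 < 0:
            raise ValueError("i0 must be >= 0")
        if self.eps_w <= 0 or self.c_stern <= 0:
            raise ValueError("eps_w and c_stern must be positive")
        if self.eps_m is None:
            object.__setattr__(self, "eps_m", self.eps_w)
        elif self.eps_m <= 0:
            raise ValueError("eps_m must be positive")

    @property
    def n0(self) -> float:
        """Bulk ion number concentration, 1/m^3."""
        return bulk_ion_concentration(self.i0)


@dataclass(frozen=True)
class MembraneSpec:
    """Fixed charge of the macromolecular membrane.

    Two modes: a directly prescribed volumetric charge concentration
    (``fixed``) or the Langmuir receptor-target picture (``langmuir``),
    where the bound-target surface density ``Nr * Kc*Nt/(1+Kc*Nt)`` is
    smeared over the membrane thickness ``hm`` with ``kq`` elementary
    charges per bound molecule (signed: positive below the isoelectric
    point of the target, negative above it).
    """

    mode: str = "fixed"
    nm: float = 0.0  # 1/m^3, signed
    nr: float = 0.0  # receptors, 1/m^2
    nt: float = 0.0  # targets, mol/L
    kc: float = 0.0  # binding constant, L/mol
    hm: float = 0.0  # membrane thickness, m
    kq: float = 0.0  # elementary charges per bound molecule, signed

    def __post_init__(self) -> None:
        if self.mode not in ("fixed", "langmuir"):
            raise ValueError("mode must be 'fixed' or 'langmuir'")
        if self.mode == "langmuir":
            if self.hm <= 0:
                raise ValueError("langmuir mode requires hm > 0")
            if self.kc < 0 or self.nr < 0 or self.nt < 0:
                raise ValueError("kc, nr, nt must be >= 0")

    @classmethod
    def fixed(cls, nm: float) -> "MembraneSpec":
        return cls(mode="fixed", nm=nm)

    @classmethod
    def langmuir(cls, nr: float, nt: float, kc: float, hm: float, kq: float) -> "MembraneSpec":
        return cls(mode="langmuir", nr=nr, nt=nt, kc=kc, hm=hm, kq=kq)

    @property
    def occupancy(self) -> float:
        """Langmuir receptor occupancy Kc*Nt/(1+Kc*Nt) (0 in fixed mode)."""
        if self.mode != "langmuir":
            return 0.0
        x = self.kc * self.nt
        return x / (1.0 + x)

    def charge_concentration(self) -> float:
        """Signed volumetric membrane charge Nm, 1/m^3."""
        if self.mode == "fixed":
            return self.nm
        return langmuir_membrane_charge(self)


def langmuir_membrane_charge(mem: MembraneSpec) -> float:
    """Nm = (kq/hm) * Nr * Kc*Nt/(1+Kc*Nt), in 1/m^3 (signed by kq)."""
    if mem.mode != "langmuir":
        raise ValueError("membrane is not in langmuir mode")
    if mem.hm <= 0:
        raise ValueError("degenerate membrane: hm must be > 0")
    return mem.kq / mem.hm * mem.nr * mem.occupancy


def donnan_potential(nm: float, n0: float, thermal: ThermalState) -> float:
    """Donnan potential psi_DP (V) of the membrane core relative to bulk.

    psi_DP = phi_th * log(x + sqrt(x^2 + 1)) with x = Nm/(2*n0); odd in Nm.
    """
    if n0 <= 0:
        if nm == 0:
            return 0.0
        raise ValueError("unscreened membrane: n0 = 0 with Nm != 0 has no Donnan limit")
    return thermal.phi_th * float(np.arcsinh(nm / (2.0 * n0)))


def _sinh_minus_arg(d):
    """sinh(d) - d without cancellation for small d."""
    small = np.abs(d) < 1e-4
    series = d**3 / 6.0 * (1.0 + d * d / 20.0)
    with np.errstate(over="ignore"):
        direct = np.sinh(np.where(small, 0.0, d)) - np.where(small, 0.0, d)
    return np.where(small, series, direct)


def membrane_diffuse_charge(psi_m, psi_dp: float, n0: float, eps_m: float,
                            thermal: ThermalState):
    """Net areal charge of membrane + diffuse layer, sigma_md (C/m^2).

    First integral of the Poisson-Boltzmann equation from the field-free
    Donnan plateau to the outer Helmholtz plane:

        sigma_md = -sgn(psi_m - psi_DP) * sqrt(4*q*n0*phi_th*eps_m * f)

        f = cosh(psi_m/phi_th) - cosh(psi_DP/phi_th)
            - ((psi_m - psi_DP)/phi_th) * sinh(psi_DP/phi_th)

    (the fixed-charge term is eliminated via the Donnan condition
    Nm = 2*n0*sinh(psi_DP/phi_th)).  For psi_DP = 0 this is exactly the
    Gouy-Chapman charge -sqrt(8*eps*kT*n0)*sinh(psi_m/(2*phi_th)).

    ``f`` is non-negative by convexity of cosh and is evaluated in the
    cancellation-free form cosh(x0)*2*sinh^2(d/2) + sinh(x0)*(sinh(d)-d),
    d = x - x0, so sigma_md is smooth through the Donnan point; it
    vanishes at psi_m = psi_DP and decreases monotonically with psi_m.
    """
    phi_th = thermal.phi_th
    x = np.asarray(psi_m, dtype=float) / phi_th
    x0 = psi_dp / phi_th
    d = x - x0
    f = np.cosh(x0) * 2.0 * np.sinh(d / 2.0) ** 2 + np.sinh(x0) * _sinh_minus_arg(d)
    f = np.maximum(f, 0.0)
    mag = np.sqrt(4.0 * Q_E * n0 * phi_th * eps_m * f)
    out = -np.sign(d) * mag
    return float(out) if np.ndim(psi_m) == 0 else out
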