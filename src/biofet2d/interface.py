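"""Self-consistent oxide/electrolyte surface potentials.

Charge neutrality across the electrolyte side of the stack requires the
site-binding charge and the membrane + diffuse-layer charge to balance
(the 2D channel charge is orders of magnitude smaller than either and is
neglected here, which decouples the electrolyte from the transistor
bias).  With the Stern relation psi_m = psi_0 - sigma_0/C_Stern the
balance reduces to one scalar equation

    g(psi_0) = sigma_0(psi_0) + sigma_md(psi_m(psi_0)) = 0.

``g`` is strictly decreasing (sigma_0 falls with psi_0, sigma_md falls
with psi_m, and psi_m rises with psi_0), so the root is unique; it is
found by bracketed root finding with geometric bracket expansion.  The
solved psi_0 is bias-independent and acts on the transistor as a shift
of the liquid-gate potential.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize

from .electrolyte import ElectrolyteSpec, MembraneSpec, donnan_potential, membrane_diffuse_charge
from .oxide import SiteBindingSpec, surface_charge

__all__ = ["InterfaceSolution", "solve_surface_potentials", "electrolyte_drop_vs_ph"]

#: Widest bracket searched for psi_0 before declaring the parameters inconsistent.
PSI_MAX = 5.0


@dataclass(frozen=True)
class InterfaceSolution:
    """Solved electrolyte/oxide interface state.

    Attributes
    ----------
    psi0, psi_m : float
        Oxide-surface and membrane (OHP) potentials relative to the bulk
        electrolyte, V.
    sigma0, sigma_md : float
        Site-binding and membrane+diffuse charge densities, C/m^2.
    psi_dp : float
        Donnan potential of the membrane, V.
    residual : float
        Charge-neutrality residual sigma0 + sigma_md at the solution.
    iterations : int
    """

    psi0: float
    psi_m: float
    sigma0: float
    sigma_md: float
    psi_dp: float
    residual: float
    iterations: int


def solve_surface_potentials(site: SiteBindingSpec, elec: ElectrolyteSpec,
                             mem: MembraneSpec, tol_sigma: float = 1e-12,
                             method: str = "brentq") -> InterfaceSolution:
    """Solve the coupled surface-potential system for psi_0 and psi_m.

    Parameters
    ----------
    site, elec, mem
        Surface chemistry, electrolyte and membrane specifications.
    tol_sigma : float
        Maximum admissible charge-neutrality residual, C/m^2.
    method : {"brentq", "bisect"}
        Root finder (both bracketed; ``bisect`` serves as a cross-check).

    Raises
    ------
    RuntimeError
        If no sign change is found within |psi_0| <= 5 V (inconsistent
        parameters) or the residual tolerance cannot be met.
    """
    thermal = elec.thermal
    nm = mem.charge_concentration()
    n0 = elec.n0
    if n0 <= 0 and nm != 0:
        raise ValueError("unscreened membrane: n0 = 0 with Nm != 0")

    if site.ns == 0 and nm == 0:
        return InterfaceSolution(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0)

    psi_dp = donnan_potential(nm, n0, thermal)

    def g(psi0: float) -> float:
        s0 = surface_charge(site, psi0, thermal)
        psi_m = psi0 - s0 / elec.c_stern
        return s0 + membrane_diffuse_charge(psi_m, psi_dp, n0, elec.eps_m, thermal)

    a, b = -2.0, 2.0
    ga, gb = g(a), g(b)
    while ga * gb > 0:
        a *= 2.0
        b *= 2.0
        if abs(a) > PSI_MAX:
            raise RuntimeError(
                "no charge-neutral solution in physical range |psi0| <= 5 V; "
                "check site-binding/membrane/electrolyte parameters")
        ga, gb = g(a), g(b)

    if method == "brentq":
        psi0, res = optimize.brentq(g, a, b, xtol=1e-14, rtol=1e-15, full_output=True)
        iterations = res.iterations
    elif method == "bisect":
        psi0, res = optimize.bisect(g, a, b, xtol=1e-15, full_output=True)
        iterations = res.iterations
    else:
        raise ValueError(f"unknown method {method!r}")

    s0 = surface_charge(site, psi0, thermal)
    psi_m = psi0 - s0 / elec.c_stern
    smd = membrane_diffuse_charge(psi_m, psi_dp, n0, elec.eps_m, thermal)
    residual = s0 + smd
    if abs(residual) > tol_sigma:
        raise RuntimeError(f"interface solve residual {residual:.3e} C/m^2 "
                           f"exceeds tolerance {tol_sigma:.3e}")
    return InterfaceSolution(float(psi0), float(psi_m), float(s0), float(smd),
                             float(psi_dp), float(residual), int(iterations))


def electrolyte_drop_vs_ph(site: SiteBindingSpec, elec: ElectrolyteSpec,
                           mem: MembraneSpec, ph_grid) -> pd.DataFrame:
    """Vectorized interface solve over a pH grid.

    Returns a DataFrame with one row per pH (input order preserved) and
    columns ``ph``, ``psi0``, ``psi_m``.
    """
    ph_grid = np.atleast_1d(np.asarray(ph_grid, dtype=float))
    if ph_grid.size == 0:
        raise ValueError("pH grid must be non-empty")
    rows = []
    for ph in ph_grid:
        try:
            sol = solve_surface_potentials(replace(site, ph=float(ph)), elec, mem)
        except RuntimeError as err:
            raise RuntimeError(f"interface solve failed at pH {ph}: {err}") from err
        rows.append({"ph": float(ph), "psi0": sol.psi0, "psi_m": sol.psi_m})
    return pd.DataFrame(rows)
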