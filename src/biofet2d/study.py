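"""Bundled device + electrolyte + surface chemistry with sweep helpers."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .interface import InterfaceSolution, solve_surface_potentials
from .oxide import SiteBindingSpec
from .electrolyte import ElectrolyteSpec, MembraneSpec
from .transport import DeviceParams, IVCurve, output_sweep, transfer_sweep

__all__ = ["Study"]


@dataclass(frozen=True)
class Study:
    """One chemical/electrical configuration of a BioFET experiment.

    Bundles the transistor, the electrolyte, the site-binding surface and
    the macromolecular membrane, plus the default drain bias, and exposes
    the common simulation entry points.  All `with_*` helpers return a
    modified copy, which makes parameter studies (pH, salt, titration)
    one-liners.
    """

    device: DeviceParams
    electrolyte: ElectrolyteSpec
    site: SiteBindingSpec
    membrane: MembraneSpec
    vds: float = 1.0
    vb: float = 0.0

    # -- configuration helpers -------------------------------------------
    def replace(self, **kwargs) -> "Study":
        return dataclasses.replace(self, **kwargs)

    def at_ph(self, ph: float) -> "Study":
        return self.replace(site=dataclasses.replace(self.site, ph=ph))

    def with_sites(self, ns: float) -> "Study":
        """Set the hydroxyl surface site density Ns (1/m^2)."""
        return self.replace(site=dataclasses.replace(self.site, ns=ns))

    def with_salt(self, i0: float) -> "Study":
        """Set the ionic strength i0 (mol/L)."""
        return self.replace(electrolyte=dataclasses.replace(self.electrolyte, i0=i0))

    def with_fixed_charge(self, nm: float) -> "Study":
        """Use a prescribed membrane charge concentration Nm (1/m^3, signed)."""
        return self.replace(membrane=MembraneSpec.fixed(nm))

    def with_target(self, nt: float, kq: float | None = None) -> "Study":
        """Set the target (analyte) molar concentration, optionally its charge."""
        if self.membrane.mode != "langmuir":
            raise ValueError("with_target requires a Langmuir membrane")
        updates = {"nt": nt}
        if kq is not None:
            updates["kq"] = kq
        return self.replace(membrane=dataclasses.replace(self.membrane, **updates))

    # -- simulation ------------------------------------------------------
    def interface(self, **kwargs) -> InterfaceSolution:
        """Solve the bias-independent electrolyte/oxide interface."""
        return solve_surface_potentials(self.site, self.electrolyte, self.membrane,
                                        **kwargs)

    def default_vlg_grid(self, psi0: float, span: tuple[float, float] = (-0.6, 1.0),
                         step: float = 0.005) -> np.ndarray:
        """Vlg grid bracketing the threshold.

        The threshold sits near Vgo - psi0 (the gate offset corrected by
        the solved electrolyte drop); the grid spans ``span`` around it.
        """
        center = self.device.vgo - psi0
        return np.arange(center + span[0], center + span[1] + 0.5 * step, step)

    def transfer(self, vlg_grid=None, vds: float | None = None,
                 vb: float | None = None) -> IVCurve:
        """Transfer characteristic Ids(Vlg); solves the interface once."""
        sol = self.interface()
        if vlg_grid is None:
            vlg_grid = self.default_vlg_grid(sol.psi0)
        curve = transfer_sweep(vlg_grid, self.vds if vds is None else vds,
                               self.vb if vb is None else vb, self.device, sol)
        curve.meta.update(ph=self.site.ph, i0=self.electrolyte.i0,
                          nm=self.membrane.charge_concentration())
        return curve

    def output(self, vds_grid, vlg: float, vb: float | None = None) -> IVCurve:
        """Output characteristic Ids(Vds)."""
        sol = self.interface()
        return output_sweep(vds_grid, vlg, self.vb if vb is None else vb,
                            self.device, sol)
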