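"""Double-gate channel electrostatics and drift-diffusion drain current.

The 2D channel is sandwiched between the top barrier oxide (facing the
electrolyte) and the buried back oxide.  Gauss's law at the channel gives
the implicit bias equation for the chemical potential at quasi-Fermi
level phi,

    sigma_2D(phi_ch) + Ctox*(Vtg_eff - Vgo - phi + phi_ch)
                     + Cbox*(Vb  - Vbo - phi + phi_ch) = 0,

where Vtg_eff = Vlg + psi_0 is the liquid-gate potential as seen by the
channel: psi_0 (oxide-surface potential relative to the bulk electrolyte,
solved once per chemical configuration) rigidly shifts the transfer
characteristic.  A more positive surface -- lower pH below the point of
zero charge, or positively charged macromolecules -- therefore lowers the
threshold voltage and raises the current, and vice versa.

The left-hand side is strictly increasing in phi_ch (sigma_2D is
non-decreasing, the oxide terms are linear), so the root is unique and
found by bracketed root finding.  The drain current in the diffusive
regime then follows from the closed form

    Ids = mu*(W/L)*Cdq*phi_th^2 * [ (1 + Cdq/Ctb)*(us^2 - ud^2)/2
                                     + (e^-ud - e^-us) ]          (n-type)

with us = u(phi_ch at source), ud = u(phi_ch at drain), an accurate
closed-form evaluation of the drift-diffusion integral
(W/L)*mu*Int |sigma_2D| dphi along the channel.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .channel import SheetChargeModel, sheet_charge, u_value
from .interface import InterfaceSolution

__all__ = [
    "DeviceParams",
    "BiasPoint",
    "IVCurve",
    "oxide_capacitances",
    "solve_channel_potential",
    "drain_current",
    "transfer_sweep",
    "output_sweep",
]

_COLUMN_UNITS = {
    "vlg": "V", "vb": "V", "vs": "V", "vd": "V", "psi0": "V",
    "phi_ch_s": "V", "phi_ch_d": "V", "u_s": "-", "u_d": "-", "ids": "A",
}


@dataclass(frozen=True)
class DeviceParams:
    """Geometry, oxides, offsets, mobility and channel band structure.

    Lengths in m, permittivities in F/m, voltages in V, mobility in
    m^2/(V*s).  ``vgo``/``vbo`` absorb electrode work-function differences
    and fixed interface charge.
    """

    w: float
    l: float
    t_tox: float
    t_box: float
    eps_tox: float
    eps_box: float
    vgo: float
    vbo: float
    mu: float
    sheet: SheetChargeModel

    def __post_init__(self) -> None:
        if self.w <= 0 or self.l <= 0:
            raise ValueError("channel dimensions must be positive")
        if self.t_tox <= 0 or self.t_box <= 0:
            raise ValueError("oxide thicknesses must be positive")
        if self.eps_tox <= 0 or self.eps_box <= 0:
            raise ValueError("oxide permittivities must be positive")
        if self.mu <= 0:
            raise ValueError("mobility must be positive")

    @property
    def c_tox(self) -> float:
        """Top-oxide capacitance per unit area, F/m^2."""
        return self.eps_tox / self.t_tox

    @property
    def c_box(self) -> float:
        """Back-oxide capacitance per unit area, F/m^2."""
        return self.eps_box / self.t_box

    @property
    def c_tb(self) -> float:
        """Series sum of the geometric gate capacitances, F/m^2."""
        return self.c_tox + self.c_box

    @property
    def aspect(self) -> float:
        return self.w / self.l


def oxide_capacitances(dev: DeviceParams) -> tuple[float, float, float]:
    """(C_tox, C_box, C_tb) per-area capacitances in F/m^2."""
    return dev.c_tox, dev.c_box, dev.c_tb


@dataclass(frozen=True)
class BiasPoint:
    """Terminal voltages of the BioFET, V."""

    vlg: float
    vb: float = 0.0
    vs: float = 0.0
    vd: float = 0.0

    @property
    def vds(self) -> float:
        return self.vd - self.vs


def _psi0_of(interface) -> float:
    if isinstance(interface, InterfaceSolution):
        return interface.psi0
    return float(interface)


def solve_channel_potential(bias: BiasPoint, phi: float, psi0, dev: DeviceParams,
                            tol_sigma: float = 1e-12) -> float:
    """Chemical potential phi_ch (V) at quasi-Fermi level ``phi``.

    ``psi0`` may be an :class:`InterfaceSolution` or a bare float (V).
    The residual of the bias equation at the returned root is below
    ``tol_sigma`` (C/m^2).
    """
    psi0 = _psi0_of(psi0)
    model = dev.sheet
    v_top = bias.vlg + psi0 - dev.vgo - phi
    v_bot = bias.vb - dev.vbo - phi

    def h(phi_ch: float) -> float:
        return (sheet_charge(phi_ch, model)
                + dev.c_tox * (v_top + phi_ch) + dev.c_box * (v_bot + phi_ch))

    a, b = -2.0, 2.0
    ha, hb = h(a), h(b)
    while ha * hb > 0:
        a *= 2.0
        b *= 2.0
        if abs(a) > 64.0:
            raise RuntimeError(
                f"channel-potential bracket failure: h({a/2})={ha:.3e}, "
                f"h({b/2})={hb:.3e}")
        ha, hb = h(a), h(b)
    root = optimize.brentq(h, a, b, xtol=1e-14, rtol=1e-15)
    if abs(h(root)) > tol_sigma:
        raise RuntimeError(f"channel-potential residual {h(root):.3e} exceeds {tol_sigma:.3e}")
    return float(root)


def drain_current(bias: BiasPoint, dev: DeviceParams, interface) -> float:
    """Drain current Ids (A) at one bias point (closed form).

    Positive for n-type with Vds > 0; vanishes identically at Vds = 0.
    """
    psi0 = _psi0_of(interface)
    model = dev.sheet
    phi_ch_s = solve_channel_potential(bias, bias.vs, psi0, dev)
    phi_ch_d = solve_channel_potential(bias, bias.vd, psi0, dev)
    us = u_value(phi_ch_s, model)
    ud = u_value(phi_ch_d, model)
    return _closed_form_current(us, ud, dev)


def _closed_form_current(us: float, ud: float, dev: DeviceParams) -> float:
    model = dev.sheet
    pref = dev.mu * dev.aspect * model.c_dq * model.phi_th**2
    ratio = 1.0 + model.c_dq / dev.c_tb
    if model.band.carrier_type == "n":
        return pref * (ratio * (us**2 - ud**2) / 2.0 + (np.exp(-ud) - np.exp(-us)))
    return pref * (ratio * (ud**2 - us**2) / 2.0 + (np.exp(-us) - np.exp(-ud)))


@dataclass
class IVCurve:
    """A solved bias sweep: one row per bias point, with internal state.

    Columns: vlg, vb, vs, vd (V); psi0 (V); phi_ch_s, phi_ch_d (V);
    u_s, u_d (dimensionless); ids (A).
    """

    frame: pd.DataFrame
    aspect: float
    meta: dict = field(default_factory=dict)

    @property
    def vlg(self) -> np.ndarray:
        return self.frame["vlg"].to_numpy()

    @property
    def ids(self) -> np.ndarray:
        return self.frame["ids"].to_numpy()

    def __len__(self) -> int:
        return len(self.frame)

    def to_csv(self, path) -> None:
        """Write the sweep as commented-header CSV ('.' decimal, ',' separator)."""
        units = ", ".join(f"{c} [{_COLUMN_UNITS.get(c, '?')}]" for c in self.frame.columns)
        with open(path, "w") as fh:
            fh.write(f"# biofet2d IV sweep; columns: {units}\n")
            fh.write(f"# aspect = {self.aspect!r}\n")
            for key, val in sorted(self.meta.items()):
                fh.write(f"# {key} = {val!r}\n")
            self.frame.to_csv(fh, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path) -> "IVCurve":
        aspect = None
        meta = {}
        body = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    stripped = line[1:].strip()
                    if "=" in stripped:
                        key, _, val = stripped.partition("=")
                        key, val = key.strip(), val.strip()
                        try:
                            parsed = eval(val, {"__builtins__": {}}, {})  # noqa: S307 - literals only
                        except Exception:
                            parsed = val
                        if key == "aspect":
                            aspect = float(parsed)
                        else:
                            meta[key] = parsed
                else:
                    body.append(line)
        frame = pd.read_csv(io.StringIO("".join(body)), float_precision="round_trip")
        return cls(frame=frame, aspect=aspect if aspect is not None else np.nan, meta=meta)


def _sweep(points: list[BiasPoint], dev: DeviceParams, psi0: float,
           meta: dict) -> IVCurve:
    model = dev.sheet
    rows = []
    for bias in points:
        phi_ch_s = solve_channel_potential(bias, bias.vs, psi0, dev)
        phi_ch_d = solve_channel_potential(bias, bias.vd, psi0, dev)
        us = u_value(phi_ch_s, model)
        ud = u_value(phi_ch_d, model)
        rows.append({
            "vlg": bias.vlg, "vb": bias.vb, "vs": bias.vs, "vd": bias.vd,
            "psi0": psi0, "phi_ch_s": phi_ch_s, "phi_ch_d": phi_ch_d,
            "u_s": us, "u_d": ud, "ids": _closed_form_current(us, ud, dev),
        })
    return IVCurve(frame=pd.DataFrame(rows), aspect=dev.aspect, meta=meta)


def transfer_sweep(vlg_grid, vds: float, vb: float, dev: DeviceParams,
                   interface, vs: float = 0.0) -> IVCurve:
    """Ids-Vlg sweep at fixed Vds (transfer characteristic).

    ``interface`` is an :class:`InterfaceSolution` (or bare psi0 in V),
    solved once and reused for every bias point.
    """
    vlg_grid = np.atleast_1d(np.asarray(vlg_grid, dtype=float))
    if vlg_grid.size == 0:
        raise ValueError("Vlg grid must be non-empty")
    psi0 = _psi0_of(interface)
    points = [BiasPoint(vlg=v, vb=vb, vs=vs, vd=vs + vds) for v in vlg_grid]
    return _sweep(points, dev, psi0, {"sweep": "transfer", "vds": float(vds)})


def output_sweep(vds_grid, vlg: float, vb: float, dev: DeviceParams,
                 interface, vs: float = 0.0) -> IVCurve:
    """Ids-Vds sweep at fixed Vlg (output characteristic)."""
    vds_grid = np.atleast_1d(np.asarray(vds_grid, dtype=float))
    if vds_grid.size == 0:
        raise ValueError("Vds grid must be non-empty")
    psi0 = _psi0_of(interface)
    points = [BiasPoint(vlg=vlg, vb=vb, vs=vs, vd=vs + v) for v in vds_grid]
    return _sweep(points, dev, psi0, {"sweep": "output", "vlg": float(vlg)})
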