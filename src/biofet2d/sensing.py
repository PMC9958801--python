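"""Sensing figures of merit: threshold voltage, its shift, current sensitivity.

The voltage-domain sensing signal is the threshold-voltage shift between
a reference (buffer) and an analyte condition; since the solved
electrolyte drop psi_0 shifts the transfer curve rigidly, negatively
charged membranes push the threshold up and positively charged ones push
it down.  The current-domain figure of merit is the relative current
change |I_after - I_before| / min(I_before, I_after) at a fixed gate
bias; it is largest in the subthreshold region, where the current depends
exponentially on the gate voltage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .transport import BiasPoint, DeviceParams, IVCurve, drain_current

__all__ = [
    "threshold_voltage",
    "threshold_shift",
    "current_sensitivity",
    "classify_region",
    "region_sensitivities",
    "SensingReport",
]


def _sorted_curve(curve: IVCurve):
    vlg = curve.vlg
    ids = curve.ids
    order = np.argsort(vlg)
    return vlg[order], ids[order]


def threshold_voltage(curve: IVCurve, method: str = "constant_current",
                      ith: float = 1e-7, aspect: float | None = None) -> float:
    """Extract the threshold voltage Vth (V) from a transfer sweep.

    method="constant_current"
        Smallest Vlg where Ids reaches ``ith * (W/L)`` (default
        ith = 1e-7 A), interpolating Vlg linearly in log10(Ids) between
        the bracketing grid points -- exact for an exponential
        subthreshold characteristic.
    method="max_gm"
        Straight-line extrapolation of Ids to zero from the point of
        maximum transconductance.
    """
    vlg, ids = _sorted_curve(curve)
    if method == "constant_current":
        if aspect is None:
            aspect = curve.aspect
        if aspect is None or not np.isfinite(aspect):
            raise ValueError("constant-current extraction needs the W/L aspect ratio")
        level = ith * aspect
        above = ids >= level
        if not above.any():
            raise ValueError(f"current never reaches threshold level {level:.3e} A")
        i = int(np.argmax(above))
        if i == 0:
            return float(vlg[0])
        if ids[i - 1] <= 0:
            return float(vlg[i])
        # log-linear interpolation between the bracketing points
        frac = (np.log10(level) - np.log10(ids[i - 1])) / (np.log10(ids[i]) - np.log10(ids[i - 1]))
        return float(vlg[i - 1] + frac * (vlg[i] - vlg[i - 1]))
    if method == "max_gm":
        gm = np.gradient(ids, vlg)
        i = int(np.argmax(gm))
        if gm[i] <= 0:
            raise ValueError("no positive transconductance in sweep")
        return float(vlg[i] - ids[i] / gm[i])
    raise ValueError(f"unknown threshold method {method!r}")


def threshold_shift(curve_ref: IVCurve, curve_analyte: IVCurve,
                    method: str = "constant_current", **kwargs) -> float:
    """Delta Vth = Vth(analyte) - Vth(reference), V."""
    return (threshold_voltage(curve_analyte, method=method, **kwargs)
            - threshold_voltage(curve_ref, method=method, **kwargs))


def _interp_current(curve: IVCurve, vlg_eval: float) -> float:
    vlg, ids = _sorted_curve(curve)
    if not (vlg[0] <= vlg_eval <= vlg[-1]):
        raise ValueError(f"Vlg = {vlg_eval} V outside the sweep range "
                         f"[{vlg[0]}, {vlg[-1]}] V")
    if np.any(ids <= 0):
        raise ValueError("non-positive currents in sweep; cannot interpolate "
                         "log-current")
    return float(10.0 ** np.interp(vlg_eval, vlg, np.log10(ids)))


def current_sensitivity(curve_before: IVCurve, curve_after: IVCurve,
                        vlg_eval: float) -> float:
    """S = |I_after - I_before| / min(I_before, I_after) at Vlg = vlg_eval.

    Symmetric under exchange of the two curves; dimensionless.
    """
    i_before = _interp_current(curve_before, vlg_eval)
    i_after = _interp_current(curve_after, vlg_eval)
    if i_before <= 0 or i_after <= 0:
        raise ValueError("currents must be positive at the evaluation bias")
    return abs(i_after - i_before) / min(i_before, i_after)


def classify_region(vlg: float, vds: float, vth: float, margin: float = 0.0) -> str:
    """Operating region: subthreshold, saturation or linear."""
    if vlg < vth - margin:
        return "subthreshold"
    if vds > vlg - vth:
        return "saturation"
    return "linear"


#: Default evaluation biases relative to the reference threshold:
#: (Vlg - Vth_ref, Vds) per region.
REGION_BIASES = {
    "subthreshold": (-0.2, None),   # Vds from the sweep setting
    "saturation": (+0.3, None),
    "linear": (+0.5, 0.05),
}


def region_sensitivities(dev: DeviceParams, psi0_before: float, psi0_after: float,
                         vth_ref: float, vds_on: float = 1.0, vb: float = 0.0) -> dict:
    """Current sensitivity evaluated at one representative bias per region.

    The subthreshold and saturation points use the on-state drain bias
    ``vds_on``; the linear point uses a small Vds (50 mV).  Biases are
    taken relative to the reference threshold ``vth_ref``.
    """
    out = {}
    for region, (dvlg, vds) in REGION_BIASES.items():
        vds_eval = vds_on if vds is None else vds
        bias = BiasPoint(vlg=vth_ref + dvlg, vb=vb, vs=0.0, vd=vds_eval)
        i_before = drain_current(bias, dev, psi0_before)
        i_after = drain_current(bias, dev, psi0_after)
        out[region] = abs(i_after - i_before) / min(i_before, i_after)
    return out


@dataclass
class SensingReport:
    """Reference-vs-analyte comparison of a BioFET configuration."""

    vth_ref: float
    vth_analyte: float
    method: str
    s_by_region: dict = field(default_factory=dict)
    eval_biases: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    @property
    def dvth(self) -> float:
        """Threshold shift Vth(analyte) - Vth(reference), V."""
        return self.vth_analyte - self.vth_ref

    def to_dict(self) -> dict:
        return {
            "vth_ref_V": self.vth_ref,
            "vth_analyte_V": self.vth_analyte,
            "dvth_V": self.dvth,
            "vth_method": self.method,
            "sensitivity_by_region": self.s_by_region,
            "evaluation_biases_V": self.eval_biases,
            **self.meta,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text
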