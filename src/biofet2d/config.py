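"""Configuration files, unit conversion, and study orchestration.

A study is described by a single YAML file whose leaf values are either
plain numbers (interpreted in the canonical internal unit of the field,
SI except band energies in eV) or strings with an explicit unit, e.g.
``"30 nm"``, ``"20 uF/cm^2"``, ``"4e14 cm^-2"``, ``"80 eps0"``.  All
values are converted to the internal SI system on load; unknown keys,
unknown units and contradictory settings (e.g. a membrane block that
mixes a fixed charge with Langmuir parameters) are rejected with a
descriptive error.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
import yaml

from .channel import BandStructure, SheetChargeModel, ThermalState
from .constants import EPS_0
from .electrolyte import ElectrolyteSpec, MembraneSpec
from .oxide import SiteBindingSpec
from .sensing import SensingReport, current_sensitivity, region_sensitivities, threshold_shift, threshold_voltage
from .study import Study
from .transport import DeviceParams
from . import presets

__all__ = ["StudyConfig", "load_config", "dump_config", "preset_table1", "run_study"]

log = logging.getLogger("biofet2d")

_UNIT_TABLES = {
    "length": {"m": 1.0, "cm": 1e-2, "mm": 1e-3, "um": 1e-6, "µm": 1e-6, "nm": 1e-9},
    "voltage": {"V": 1.0, "mV": 1e-3, "uV": 1e-6},
    "energy_ev": {"eV": 1.0, "meV": 1e-3},
    "temperature": {"K": 1.0},
    "molar": {"M": 1.0, "mol/L": 1.0, "mM": 1e-3, "uM": 1e-6, "µM": 1e-6,
              "nM": 1e-9, "pM": 1e-12, "fM": 1e-15},
    "areal_density": {"m^-2": 1.0, "1/m^2": 1.0, "cm^-2": 1e4, "1/cm^2": 1e4},
    "volumetric_density": {"m^-3": 1.0, "1/m^3": 1.0, "cm^-3": 1e6, "1/cm^3": 1e6},
    "areal_capacitance": {"F/m^2": 1.0, "uF/cm^2": 1e-2, "µF/cm^2": 1e-2},
    "mobility": {"m^2/Vs": 1.0, "cm^2/Vs": 1e-4},
    "inv_molar": {"M^-1": 1.0, "1/M": 1.0, "L/mol": 1.0},
    "permittivity": {"F/m": 1.0, "eps0": EPS_0, "e0": EPS_0},
    "dimensionless": {"": 1.0},
}


class ConfigError(ValueError):
    """Malformed or contradictory study configuration."""


def parse_quantity(value, kind: str, key: str = "?") -> float:
    """Convert a config value to the canonical unit of ``kind``.

    Numbers pass through unchanged (assumed already canonical); strings
    must be ``"<number> <unit>"`` with a unit known for the kind.
    """
    table = _UNIT_TABLES[kind]
    if isinstance(value, bool):
        raise ConfigError(f"{key}: expected a quantity, got a boolean")
    if isinstance(value, (int, float)):
        return float(value)
    if isinstance(value, str):
        parts = value.split()
        if len(parts) == 1:
            try:
                return float(parts[0])
            except ValueError as err:
                raise ConfigError(f"{key}: cannot parse {value!r}") from err
        if len(parts) == 2:
            try:
                mag = float(parts[0])
            except ValueError as err:
                raise ConfigError(f"{key}: cannot parse number in {value!r}") from err
            unit = parts[1]
            if unit not in table:
                raise ConfigError(
                    f"{key}: unknown unit {unit!r} for {kind} "
                    f"(known: {sorted(table)})")
            return mag * table[unit]
    raise ConfigError(f"{key}: cannot parse quantity {value!r}")


def _take(section: dict, schema: dict, where: str) -> dict:
    """Pop known keys from a section per schema {key: kind-or-None}, reject leftovers."""
    out = {}
    section = dict(section or {})
    for key, kind in schema.items():
        if key in section:
            raw = section.pop(key)
            out[key] = raw if kind is None else parse_quantity(raw, kind, f"{where}.{key}")
    if section:
        raise ConfigError(f"unknown key(s) in '{where}': {sorted(section)}")
    return out


@dataclass
class StudyConfig:
    """A fully validated, SI-normalized study: model objects + sweep plan."""

    study: Study
    sweeps: list = dc_field(default_factory=list)
    out_dir: str = "results"
    vth_method: str = "constant_current"


def preset_table1() -> StudyConfig:
    """The full baseline parameter set of the modeled MoS2 BioFET."""
    return StudyConfig(study=presets.table1())


def load_config(path) -> StudyConfig:
    """Load, validate and unit-convert a YAML study configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("top-level config must be a mapping")
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> StudyConfig:
    raw = dict(raw)
    preset_name = raw.pop("preset", "table1")
    if preset_name not in (None, "table1"):
        raise ConfigError(f"unknown preset {preset_name!r}")
    base = presets.table1()

    thermal_kw = _take(raw.pop("thermal", {}), {"T": "temperature"}, "thermal")
    thermal = ThermalState(thermal_kw.get("T", base.device.sheet.thermal.temperature))

    band_kw = _take(raw.pop("band", {}), {
        "carrier_type": None, "m1_rel": "dimensionless", "m2_rel": "dimensionless",
        "g1": "dimensionless", "g2": "dimensionless", "dE12": "energy_ev",
    }, "band")
    band0 = base.device.sheet.band
    band = BandStructure(
        carrier_type=band_kw.get("carrier_type", band0.carrier_type),
        m1_rel=band_kw.get("m1_rel", band0.m1_rel),
        m2_rel=band_kw.get("m2_rel", band0.m2_rel),
        g1=int(band_kw.get("g1", band0.g1)),
        g2=int(band_kw.get("g2", band0.g2)),
        de12_ev=band_kw.get("dE12", band0.de12_ev),
    )
    sheet = SheetChargeModel(band=band, thermal=thermal)

    dev_kw = _take(raw.pop("device", {}), {
        "W": "length", "L": "length", "ttox": "length", "tbox": "length",
        "eps_tox": "permittivity", "eps_box": "permittivity",
        "vgo": "voltage", "vbo": "voltage", "mu": "mobility",
    }, "device")
    d0 = base.device
    device = DeviceParams(
        w=dev_kw.get("W", d0.w), l=dev_kw.get("L", d0.l),
        t_tox=dev_kw.get("ttox", d0.t_tox), t_box=dev_kw.get("tbox", d0.t_box),
        eps_tox=dev_kw.get("eps_tox", d0.eps_tox),
        eps_box=dev_kw.get("eps_box", d0.eps_box),
        vgo=dev_kw.get("vgo", d0.vgo), vbo=dev_kw.get("vbo", d0.vbo),
        mu=dev_kw.get("mu", d0.mu), sheet=sheet,
    )

    elec_kw = _take(raw.pop("electrolyte", {}), {
        "i0": "molar", "eps_w": "permittivity", "eps_m": "permittivity",
        "c_stern": "areal_capacitance",
    }, "electrolyte")
    e0 = base.electrolyte
    electrolyte = ElectrolyteSpec(
        i0=elec_kw.get("i0", e0.i0), eps_w=elec_kw.get("eps_w", e0.eps_w),
        eps_m=elec_kw.get("eps_m", elec_kw.get("eps_w", e0.eps_m)),
        c_stern=elec_kw.get("c_stern", e0.c_stern), thermal=thermal,
    )

    site_kw = _take(raw.pop("site_binding", {}), {
        "ns": "areal_density", "pKa": "dimensionless", "pKb": "dimensionless",
        "pH": "dimensionless",
    }, "site_binding")
    s0 = base.site
    site = SiteBindingSpec(ns=site_kw.get("ns", s0.ns), pka=site_kw.get("pKa", s0.pka),
                           pkb=site_kw.get("pKb", s0.pkb), ph=site_kw.get("pH", s0.ph))

    mem_raw = raw.pop("membrane", {}) or {}
    fixed_keys = {"nm"} & set(mem_raw)
    langmuir_keys = {"nr", "nt", "kc", "hm", "kq"} & set(mem_raw)
    if fixed_keys and langmuir_keys:
        raise ConfigError("membrane: fixed charge 'nm' conflicts with Langmuir "
                          f"parameters {sorted(langmuir_keys)}; set one mode only")
    mem_kw = _take(mem_raw, {
        "nm": "volumetric_density", "nr": "areal_density", "nt": "molar",
        "kc": "inv_molar", "hm": "length", "kq": "dimensionless",
    }, "membrane")
    if langmuir_keys:
        membrane = MembraneSpec.langmuir(
            nr=mem_kw.get("nr", 0.0), nt=mem_kw.get("nt", 0.0),
            kc=mem_kw.get("kc", 0.0), hm=mem_kw.get("hm", 5e-9),
            kq=mem_kw.get("kq", 0.0))
    else:
        membrane = MembraneSpec.fixed(mem_kw.get("nm", 0.0))

    bias_kw = _take(raw.pop("bias", {}), {"vds": "voltage", "vb": "voltage"}, "bias")

    sweeps = raw.pop("sweeps", []) or []
    if not isinstance(sweeps, list):
        raise ConfigError("'sweeps' must be a list")

    out_kw = _take(raw.pop("output", {}), {"dir": None, "vth_method": None}, "output")
    if raw:
        raise ConfigError(f"unknown top-level key(s): {sorted(raw)}")

    study = Study(device=device, electrolyte=electrolyte, site=site,
                  membrane=membrane, vds=bias_kw.get("vds", base.vds),
                  vb=bias_kw.get("vb", base.vb))
    return StudyConfig(study=study, sweeps=sweeps,
                       out_dir=out_kw.get("dir", "results"),
                       vth_method=out_kw.get("vth_method", "constant_current"))


def dump_config(cfg: StudyConfig) -> dict:
    """Normalized (SI) plain-dict form of a configuration; YAML-serializable
    and accepted back by :func:`config_from_dict` unchanged."""
    st = cfg.study
    band = st.device.sheet.band
    mem = st.membrane
    out = {
        "thermal": {"T": st.device.sheet.thermal.temperature},
        "band": {"carrier_type": band.carrier_type, "m1_rel": band.m1_rel,
                 "m2_rel": band.m2_rel, "g1": band.g1, "g2": band.g2,
                 "dE12": band.de12_ev},
        "device": {"W": st.device.w, "L": st.device.l, "ttox": st.device.t_tox,
                   "tbox": st.device.t_box, "eps_tox": st.device.eps_tox,
                   "eps_box": st.device.eps_box, "vgo": st.device.vgo,
                   "vbo": st.device.vbo, "mu": st.device.mu},
        "electrolyte": {"i0": st.electrolyte.i0, "eps_w": st.electrolyte.eps_w,
                        "eps_m": st.electrolyte.eps_m,
                        "c_stern": st.electrolyte.c_stern},
        "site_binding": {"ns": st.site.ns, "pKa": st.site.pka, "pKb": st.site.pkb,
                         "pH": st.site.ph},
        "bias": {"vds": st.vds, "vb": st.vb},
        "sweeps": list(cfg.sweeps),
        "output": {"dir": cfg.out_dir, "vth_method": cfg.vth_method},
    }
    if mem.mode == "fixed":
        out["membrane"] = {"nm": mem.nm}
    else:
        out["membrane"] = {"nr": mem.nr, "nt": mem.nt, "kc": mem.kc,
                           "hm": mem.hm, "kq": mem.kq}
    return out


# ---------------------------------------------------------------------------
# sweep orchestration
# ---------------------------------------------------------------------------

def _grid(spec, default=None):
    if spec is None:
        return default
    if isinstance(spec, dict):
        return np.arange(float(spec["min"]),
                         float(spec["max"]) + 0.5 * float(spec["step"]),
                         float(spec["step"]))
    return np.asarray(spec, dtype=float)


def _log_interface(study: Study):
    sol = study.interface()
    log.info("interface solved: psi0=%.6f V, psi_m=%.6f V, residual=%.2e C/m^2, "
             "iterations=%d", sol.psi0, sol.psi_m, sol.residual, sol.iterations)
    return sol


def run_study(cfg: StudyConfig, out_dir=None) -> list:
    """Execute every sweep in the configuration and write result files.

    Returns the list of written paths.  An empty sweep list writes
    nothing and logs a warning.
    """
    import pathlib

    out = pathlib.Path(out_dir if out_dir is not None else cfg.out_dir)
    if not cfg.sweeps:
        log.warning("no sweeps requested; nothing to do")
        return []
    out.mkdir(parents=True, exist_ok=True)
    written = []

    for i, sweep in enumerate(cfg.sweeps):
        sweep = dict(sweep)
        kind = sweep.pop("type", None)
        tag = sweep.pop("name", f"{kind}_{i}")
        study = cfg.study
        if kind == "transfer":
            vds = parse_quantity(sweep.pop("vds", study.vds), "voltage", "sweep.vds")
            curve = study.replace(vds=vds).transfer(_grid(sweep.pop("vlg", None)))
            path = out / f"{tag}.csv"
            curve.to_csv(path)
            written.append(path)
        elif kind == "output":
            vlg = parse_quantity(sweep.pop("vlg"), "voltage", "sweep.vlg")
            curve = study.output(_grid(sweep.pop("vds")), vlg)
            path = out / f"{tag}.csv"
            curve.to_csv(path)
            written.append(path)
        elif kind == "ph":
            values = list(sweep.pop("values"))
            vlg = _grid(sweep.pop("vlg", None))
            frames = []
            for ph in values:
                curve = study.at_ph(float(ph)).transfer(vlg)
                f = curve.frame.copy()
                f.insert(0, "ph", float(ph))
                frames.append(f)
            path = out / f"{tag}.csv"
            _write_concat(frames, study, path)
            written.append(path)
        elif kind == "nm":
            values = [parse_quantity(v, "volumetric_density", "sweep.values")
                      for v in sweep.pop("values")]
            ref = study.with_fixed_charge(0.0).transfer()
            rows = []
            for nm in values:
                cur = study.with_fixed_charge(nm).transfer()
                rows.append({"nm": nm, "dvth": threshold_shift(
                    ref, cur, method=cfg.vth_method)})
            path = out / f"{tag}.csv"
            _write_rows(rows, path, "# nm [1/m^3], dvth [V]\n")
            written.append(path)
        elif kind == "salt":
            nm = parse_quantity(sweep.pop("nm"), "volumetric_density", "sweep.nm")
            values = [parse_quantity(v, "molar", "sweep.values")
                      for v in sweep.pop("values")]
            rows = []
            for i0 in values:
                s = study.with_salt(i0)
                ref = s.with_fixed_charge(0.0).transfer()
                cur = s.with_fixed_charge(nm).transfer()
                rows.append({"i0": i0, "dvth": threshold_shift(
                    ref, cur, method=cfg.vth_method)})
            path = out / f"{tag}.csv"
            _write_rows(rows, path, "# i0 [mol/L], dvth [V]\n")
            written.append(path)
        elif kind == "titration":
            values = [parse_quantity(v, "molar", "sweep.values")
                      for v in sweep.pop("values")]
            vlg = _grid(sweep.pop("vlg", None))
            frames = []
            for nt in values:
                curve = study.with_target(nt).transfer(vlg)
                f = curve.frame.copy()
                f.insert(0, "nt", nt)
                frames.append(f)
            path = out / f"{tag}.csv"
            _write_concat(frames, study, path)
            written.append(path)
        elif kind == "sensitivity":
            nt = parse_quantity(sweep.pop("nt"), "molar", "sweep.nt")
            report = sensitivity_report(study, nt, vth_method=cfg.vth_method)
            path = out / f"{tag}.json"
            report.to_json(path)
            written.append(path)
        else:
            raise ConfigError(f"unknown sweep type {kind!r}")
        if sweep:
            log.info("sweep %s: ignored keys %s", tag, sorted(sweep))
    return written


def _write_rows(rows, path, header):
    import pandas as pd
    with open(path, "w") as fh:
        fh.write(header)
        pd.DataFrame(rows).to_csv(fh, index=False, float_format="%.17g")


def _write_concat(frames, study, path):
    import pandas as pd
    combined = pd.concat(frames, ignore_index=True)
    with open(path, "w") as fh:
        fh.write(f"# aspect = {study.device.aspect!r}\n")
        combined.to_csv(fh, index=False, float_format="%.17g")


def sensitivity_report(study: Study, nt: float, subthreshold_offset: float = -0.2,
                       vth_method: str = "constant_current") -> SensingReport:
    """Before/after comparison: buffer (Nt = 0) versus target at ``nt``.

    Computes the threshold shift and the current sensitivity at one
    representative bias per operating region (subthreshold bias
    Vth_ref + ``subthreshold_offset``).
    """
    before = study.with_target(0.0)
    after = study.with_target(nt)
    sol_b = _log_interface(before)
    sol_a = _log_interface(after)
    curve_b = before.transfer()
    curve_a = after.transfer(curve_b.vlg)
    vth_b = threshold_voltage(curve_b, method=vth_method)
    vth_a = threshold_voltage(curve_a, method=vth_method)
    s_regions = region_sensitivities(study.device, sol_b.psi0, sol_a.psi0,
                                     vth_ref=vth_b, vds_on=study.vds, vb=study.vb)
    vlg_sub = vth_b + subthreshold_offset
    s_sub_curve = current_sensitivity(curve_b, curve_a, vlg_sub)
    return SensingReport(
        vth_ref=vth_b, vth_analyte=vth_a, method=vth_method,
        s_by_region=s_regions,
        eval_biases={"subthreshold": vlg_sub},
        meta={"nt_mol_per_L": nt, "psi0_ref_V": sol_b.psi0,
              "psi0_analyte_V": sol_a.psi0,
              "s_subthreshold_from_curves": s_sub_curve},
    )
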