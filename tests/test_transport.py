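"""Channel electrostatics and closed-form drain current."""

import dataclasses

import numpy as np
import pytest

from biofet2d import (BiasPoint, DeviceParams, SheetChargeModel, drain_current,
                      output_sweep, oxide_capacitances, sheet_charge,
                      solve_channel_potential, transfer_sweep)
from biofet2d.constants import EPS_0

LN10 = np.log(10.0)


@pytest.fixture(scope="module")
def dev(baseline):
    return baseline.device


@pytest.fixture(scope="module")
def psi0(baseline):
    return baseline.interface().psi0


class TestCapacitances:
    def test_values(self, dev):
        c_tox, c_box, c_tb = oxide_capacitances(dev)
        assert c_tox == pytest.approx(25.0 * EPS_0 / 30e-9, rel=1e-12)   # ~7.38e-3 F/m^2
        assert c_box == pytest.approx(3.9 * EPS_0 / 270e-9, rel=1e-12)   # ~1.28e-4 F/m^2
        assert c_tb == pytest.approx(c_tox + c_box, rel=1e-12)
        assert c_tox == pytest.approx(7.38e-3, rel=1e-2)
        assert c_box == pytest.approx(1.28e-4, rel=1e-2)

    def test_zero_thickness_rejected(self, dev):
        with pytest.raises(ValueError):
            dataclasses.replace(dev, t_tox=0.0)


class TestChannelPotential:
    def test_residual_contract(self, dev, psi0):
        bias = BiasPoint(vlg=0.5, vb=0.0, vs=0.0, vd=1.0)
        phi_ch = solve_channel_potential(bias, 0.0, psi0, dev)
        resid = (sheet_charge(phi_ch, dev.sheet)
                 + dev.c_tox * (bias.vlg + psi0 - dev.vgo - 0.0 + phi_ch)
                 + dev.c_box * (bias.vb - dev.vbo - 0.0 + phi_ch))
        assert abs(resid) <= 1e-12

    def test_subthreshold_linearization(self, dev, psi0):
        """With sigma_2D negligible, phi_ch follows the capacitive divider."""
        bias = BiasPoint(vlg=dev.vgo - psi0 - 0.5, vb=0.0, vs=0.0, vd=1.0)
        phi_ch = solve_channel_potential(bias, 0.0, psi0, dev)
        linear = -(dev.c_tox * (bias.vlg + psi0 - dev.vgo)
                   + dev.c_box * (bias.vb - dev.vbo)) / dev.c_tb
        assert phi_ch == pytest.approx(linear, rel=1e-2)

    def test_translation_invariance(self, dev, psi0):
        bias = BiasPoint(vlg=0.6, vb=0.1, vs=0.2, vd=0.2)
        a = solve_channel_potential(bias, bias.vs, psi0, dev)
        delta = 0.37
        shifted = BiasPoint(vlg=0.6 + delta, vb=0.1 + delta,
                            vs=0.2 + delta, vd=0.2 + delta)
        b = solve_channel_potential(shifted, shifted.vs, psi0, dev)
        assert a == pytest.approx(b, abs=1e-12)


class TestDrainCurrent:
    def test_zero_vds(self, dev, psi0):
        bias = BiasPoint(vlg=0.7, vb=0.0, vs=0.0, vd=0.0)
        assert drain_current(bias, dev, psi0) == 0.0

    def test_monotone_in_vlg(self, dev, psi0):
        curve = transfer_sweep(np.linspace(-0.2, 1.2, 57), 1.0, 0.0, dev, psi0)
        assert np.all(np.diff(curve.ids) > 0)
        assert np.all(curve.ids > 0)

    def test_monotone_in_vds_with_saturation(self, dev, psi0):
        curve = output_sweep(np.linspace(0.0, 2.0, 81), 0.6, 0.0, dev, psi0)
        ids = curve.ids
        assert ids[0] == 0.0
        assert np.all(np.diff(ids) >= 0)
        # plateau: the last 0.5 V of drain bias adds almost nothing
        i_15 = np.interp(1.5, curve.frame["vd"], ids)
        assert ids[-1] == pytest.approx(i_15, rel=1e-3)

    def test_gauge_invariance(self, dev, psi0):
        bias = BiasPoint(vlg=0.6, vb=0.0, vs=0.0, vd=0.8)
        delta = -0.43
        shifted = BiasPoint(vlg=0.6 + delta, vb=delta, vs=delta, vd=0.8 + delta)
        assert drain_current(bias, dev, psi0) == pytest.approx(
            drain_current(shifted, dev, psi0), rel=1e-10)

    def test_pn_mirror(self, dev, psi0):
        """A mirrored p-type device under reversed voltages carries the same |Ids|."""
        p_sheet = SheetChargeModel(
            band=dataclasses.replace(dev.sheet.band, carrier_type="p"),
            thermal=dev.sheet.thermal)
        p_dev = dataclasses.replace(dev, sheet=p_sheet, vgo=-dev.vgo, vbo=-dev.vbo)
        bias_n = BiasPoint(vlg=0.6, vb=0.0, vs=0.0, vd=1.0)
        bias_p = BiasPoint(vlg=-0.6, vb=0.0, vs=0.0, vd=-1.0)
        i_n = drain_current(bias_n, dev, psi0)
        i_p = drain_current(bias_p, p_dev, -psi0)
        assert i_p == pytest.approx(-i_n, rel=1e-10)

    @pytest.mark.parametrize("vlg,vds,tol", [
        # the closed form carries a small intrinsic approximation error that
        # peaks (~0.7% for this device) around threshold and vanishes deep in
        # subthreshold and in strong accumulation
        (0.2, 1.0, 2e-3),
        (0.8, 0.01, 1e-2),
        (0.8, 1.0, 1e-2),
        (1.8, 1.0, 5e-3),
    ])
    def test_closed_form_matches_integral(self, dev, psi0, vlg, vds, tol):
        """Brute-force drift-diffusion: Ids = mu*(W/L)*Int |sigma_2D| dphi."""
        phi_grid = np.linspace(0.0, vds, 2001)
        bias = BiasPoint(vlg=vlg, vb=0.0, vs=0.0, vd=vds)
        sigma = np.array([abs(sheet_charge(
            solve_channel_potential(bias, phi, psi0, dev), dev.sheet))
            for phi in phi_grid])
        integral = dev.mu * dev.aspect * np.trapezoid(sigma, phi_grid)
        closed = drain_current(bias, dev, psi0)
        assert closed == pytest.approx(integral, rel=tol)

    def test_subthreshold_swing_limit(self, dev, psi0):
        """Deep subthreshold: SS -> ln10*phi_th*(1 + Cbox/Ctox)."""
        vth_guess = dev.vgo - psi0
        vlg = np.linspace(vth_guess - 0.40, vth_guess - 0.25, 16)
        curve = transfer_sweep(vlg, 1.0, 0.0, dev, psi0)
        slope = np.polyfit(np.log10(curve.ids), curve.vlg, 1)[0]
        expected = LN10 * dev.sheet.phi_th * (1.0 + dev.c_box / dev.c_tox)
        assert slope == pytest.approx(expected, rel=2e-2)


class TestSweepsAndIO:
    def test_single_point_grid_matches_drain_current(self, dev, psi0):
        curve = transfer_sweep([0.55], 1.0, 0.0, dev, psi0)
        assert len(curve) == 1
        assert curve.ids[0] == pytest.approx(drain_current(
            BiasPoint(vlg=0.55, vb=0.0, vs=0.0, vd=1.0), dev, psi0), rel=1e-12)

    def test_zero_vds_column(self, dev, psi0):
        curve = transfer_sweep(np.linspace(0, 1, 5), 0.0, 0.0, dev, psi0)
        assert np.all(curve.ids == 0.0)

    def test_u_columns_consistent(self, dev, psi0):
        from biofet2d import u_value
        curve = transfer_sweep(np.linspace(0.2, 0.8, 7), 1.0, 0.0, dev, psi0)
        np.testing.assert_allclose(
            curve.frame["u_s"],
            [u_value(p, dev.sheet) for p in curve.frame["phi_ch_s"]], rtol=1e-12)

    def test_csv_roundtrip_exact(self, dev, psi0, tmp_path):
        curve = transfer_sweep(np.linspace(0.0, 1.0, 9), 1.0, 0.0, dev, psi0)
        path = tmp_path / "curve.csv"
        curve.to_csv(path)
        back = curve.from_csv(path)
        assert back.aspect == curve.aspect
        assert back.meta["vds"] == 1.0
        np.testing.assert_array_equal(back.frame.to_numpy(), curve.frame.to_numpy())

    def test_empty_grid_rejected(self, dev, psi0):
        with pytest.raises(ValueError):
            transfer_sweep([], 1.0, 0.0, dev, psi0)
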