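"""Bulk ions, Donnan membrane, diffuse-layer charge and Langmuir binding."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from biofet2d import (MembraneSpec, ThermalState, bulk_ion_concentration,
                      donnan_potential, langmuir_membrane_charge,
                      membrane_diffuse_charge)
from biofet2d.constants import K_B, N_A, Q_E


class TestBulkIons:
    def test_zero(self):
        assert bulk_ion_concentration(0.0) == 0.0

    def test_one_millimolar(self):
        # 1 mM = 1 mol/m^3 -> Avogadro per m^3
        assert bulk_ion_concentration(1e-3) == pytest.approx(N_A, rel=1e-12)

    def test_linearity(self):
        assert bulk_ion_concentration(0.1) == pytest.approx(
            100.0 * bulk_ion_concentration(1e-3), rel=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            bulk_ion_concentration(-1.0)


class TestLangmuir:
    def test_empty_occupancy(self):
        mem = MembraneSpec.langmuir(nr=2.3e17, nt=0.0, kc=1e13, hm=5e-9, kq=22.3)
        assert langmuir_membrane_charge(mem) == 0.0

    def test_half_occupancy_closed_form(self):
        """Kc*Nt = 1 gives exactly half occupancy: Nm = kq*Nr/(2*hm)."""
        mem = MembraneSpec.langmuir(nr=2.3e17, nt=1e-13, kc=1e13, hm=5e-9, kq=22.3)
        assert mem.occupancy == pytest.approx(0.5, rel=1e-12)
        expected = 22.3 * 2.3e17 * 0.5 / 5e-9  # = 5.129e26 m^-3 (5.13e20 cm^-3)
        assert langmuir_membrane_charge(mem) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(5.13e26, rel=2e-3)

    def test_saturation_and_monotonicity(self):
        nts = np.logspace(-16, -4, 25)
        nms = [langmuir_membrane_charge(
            MembraneSpec.langmuir(2.3e17, nt, 1e13, 5e-9, 22.3)) for nt in nts]
        assert np.all(np.diff(nms) > 0)
        assert nms[-1] == pytest.approx(22.3 * 2.3e17 / 5e-9, rel=1e-8)

    def test_sign_follows_kq(self):
        neg = MembraneSpec.langmuir(2.3e17, 1e-13, 1e13, 5e-9, -15.2)
        assert langmuir_membrane_charge(neg) < 0

    def test_degenerate_membrane_rejected(self):
        with pytest.raises(ValueError):
            MembraneSpec.langmuir(2.3e17, 1e-13, 1e13, 0.0, 22.3)


class TestDonnan:
    n0 = bulk_ion_concentration(1e-3)

    def test_neutral_membrane(self, thermal):
        assert donnan_potential(0.0, self.n0, thermal) == 0.0

    def test_closed_form(self, thermal):
        assert donnan_potential(2.0 * self.n0, self.n0, thermal) == pytest.approx(
            thermal.phi_th * np.arcsinh(1.0), rel=1e-12)

    def test_odd(self, thermal):
        for nm in (1e20, 5e23, 3e26):
            assert donnan_potential(-nm, self.n0, thermal) == pytest.approx(
                -donnan_potential(nm, self.n0, thermal), rel=1e-12)

    def test_linearized_small_charge(self, thermal):
        """|Nm| << n0: psi_DP ~ phi_th * Nm/(2 n0) within 1%."""
        for ratio in (0.01, 0.05, 0.1):
            nm = 2.0 * self.n0 * ratio
            assert donnan_potential(nm, self.n0, thermal) == pytest.approx(
                thermal.phi_th * ratio, rel=1e-2)

    def test_unscreened_error(self, thermal):
        with pytest.raises(ValueError):
            donnan_potential(1e20, 0.0, thermal)
        assert donnan_potential(0.0, 0.0, thermal) == 0.0


class TestMembraneDiffuseCharge:
    n0 = bulk_ion_concentration(1e-3)
    eps_m = 80.0 * 8.85418781e-12

    def test_vanishes_at_donnan(self, thermal):
        for psi_dp in (-0.2, 0.0, 0.15):
            assert membrane_diffuse_charge(psi_dp, psi_dp, self.n0,
                                           self.eps_m, thermal) == 0.0

    def test_gouy_chapman_oracle(self, thermal):
        """Nm = 0: exact Gouy-Chapman closed form, rel. err < 1e-10."""
        kt = K_B * thermal.temperature
        for psi in np.linspace(-0.5, 0.5, 41):
            if psi == 0.0:
                continue
            gc = -np.sqrt(8.0 * self.eps_m * kt * self.n0) * np.sinh(
                psi / (2.0 * thermal.phi_th))
            got = membrane_diffuse_charge(psi, 0.0, self.n0, self.eps_m, thermal)
            assert got == pytest.approx(gc, rel=1e-10)

    def test_sign_contract(self, thermal):
        psi_dp = 0.1
        assert membrane_diffuse_charge(0.2, psi_dp, self.n0, self.eps_m, thermal) < 0
        assert membrane_diffuse_charge(0.0, psi_dp, self.n0, self.eps_m, thermal) > 0

    def test_monotone_decreasing(self, thermal):
        psis = np.linspace(-0.6, 0.6, 121)
        smd = membrane_diffuse_charge(psis, 0.17, self.n0, self.eps_m, thermal)
        assert np.all(np.diff(smd) < 0)

    def test_radicand_convexity_grid(self, thermal):
        """cosh(x) - cosh(x0) - (x-x0)*sinh(x0) >= 0 over |psi| <= 1 V."""
        phi_th = thermal.phi_th
        grid = np.linspace(-1.0, 1.0, 81)
        for psi_dp in grid:
            x0 = psi_dp / phi_th
            x = grid / phi_th
            f = np.cosh(x) - np.cosh(x0) - (x - x0) * np.sinh(x0)
            assert f.min() >= -1e-12 * max(1.0, np.cosh(x0))


@settings(deadline=None, max_examples=100)
@given(psi_m=st.floats(min_value=-1.0, max_value=1.0),
       psi_dp=st.floats(min_value=-0.5, max_value=0.5))
def test_diffuse_charge_opposes_excess_potential(psi_m, psi_dp):
    """sigma_md always pulls psi_m back toward the Donnan plateau."""
    thermal = ThermalState(300.0)
    n0 = bulk_ion_concentration(1e-3)
    smd = membrane_diffuse_charge(psi_m, psi_dp, n0, 80 * 8.85418781e-12, thermal)
    if psi_m > psi_dp:
        assert smd <= 0
    elif psi_m < psi_dp:
        assert smd >= 0
    assert np.isfinite(smd)
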