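"""Form factors, Guinier analysis, smearing and curve utilities."""

import math

import numpy as np
import pytest

from surfprot.sas import (
    GeometryParams,
    ScatteringCurve,
    form_factor_intensity,
    gaussian_smear,
    guinier_fit,
    integrated_intensity,
    read_sans,
    smear_matrix,
    write_sans,
)


Q = np.linspace(0.005, 0.5, 200)


class TestFormFactor:
    def test_sphere_forward_intensity_closed_form(self):
        gp = GeometryParams(
            kind="sphere", radius=30.0, sld_core=3e-6, sld_solvent=0.0,
            volume_fraction=0.01,
        )
        v = 4.0 / 3.0 * math.pi * 30.0**3
        expected = 1e8 * 0.01 * (3e-6) ** 2 * v  # = 1.018 cm^-1
        assert form_factor_intensity(gp, np.array([1e-6]))[0] == pytest.approx(
            expected, rel=1e-9
        )
        assert expected == pytest.approx(1.018, abs=2e-3)

    def test_sphere_first_zero_at_qr_4p4934(self):
        R = 30.0
        gp = GeometryParams(kind="sphere", radius=R, sld_core=3e-6, sld_solvent=0.0)
        q = np.linspace(4.0 / R, 5.0 / R, 4000)
        I = form_factor_intensity(gp, q)
        q_zero = q[int(np.argmin(I))]
        assert q_zero * R == pytest.approx(4.4934, abs=2e-3)

    def test_ellipsoid_axial_ratio_one_is_sphere(self):
        sph = GeometryParams(kind="sphere", radius=28.0, sld_core=2e-6, sld_solvent=0.0)
        ell = GeometryParams(
            kind="ellipsoid", radius=28.0, axial_ratio=1.0, sld_core=2e-6, sld_solvent=0.0
        )
        i_s = form_factor_intensity(sph, Q)
        i_e = form_factor_intensity(ell, Q)
        assert np.max(np.abs(i_e - i_s) / i_s) < 1e-6

    def test_core_shell_contrast_degeneracy(self):
        cs = GeometryParams(
            kind="core_shell_ellipsoid", radius=15.0, axial_ratio=1.4,
            shell_thickness=10.0, sld_core=3e-6, sld_shell=3e-6, sld_solvent=1e-6,
        )
        uni = GeometryParams(
            kind="ellipsoid", radius=25.0, axial_ratio=(1.4 * 15.0 + 10.0) / 25.0,
            sld_core=3e-6, sld_solvent=1e-6,
        )
        i_cs = form_factor_intensity(cs, Q)
        i_u = form_factor_intensity(uni, Q) * cs.total_volume / uni.total_volume
        # same outer dimensions and contrast; scale differs only through
        # the phi/V convention, normalized out above
        assert np.allclose(i_cs, i_u, rtol=1e-6)

    def test_quadrature_order_stability(self):
        gp = GeometryParams(
            kind="ellipsoid", radius=30.0, axial_ratio=2.0, sld_core=3e-6, sld_solvent=0.0
        )
        i76 = form_factor_intensity(gp, Q, n_quad=76)
        i152 = form_factor_intensity(gp, Q, n_quad=152)
        assert np.max(np.abs(i152 - i76) / np.maximum(i76, 1e-12)) < 1e-5

    def test_background_floor(self):
        gp = GeometryParams(
            kind="sphere", radius=30.0, sld_core=3e-6, sld_solvent=0.0, background=0.05
        )
        assert np.all(form_factor_intensity(gp, Q) >= 0.05)


class TestGuinier:
    def test_sphere_rg_closed_form(self, sphere_curve_factory):
        curve, gp = sphere_curve_factory(radius=30.0, noise=0.0)
        res = guinier_fit(curve)
        assert res.rg == pytest.approx(math.sqrt(3.0 / 5.0) * 30.0, rel=0.02)
        assert res.i0 == pytest.approx(
            form_factor_intensity(gp, np.array([1e-6]))[0], rel=0.02
        )

    def test_flat_curve_zero_rg(self):
        q = np.linspace(0.01, 0.2, 50)
        curve = ScatteringCurve(q, np.full_like(q, 2.5), np.full_like(q, 0.01))
        res = guinier_fit(curve)
        assert res.rg == 0.0
        assert res.i0 == pytest.approx(2.5, rel=1e-9)

    def test_increasing_curve_rejected(self):
        q = np.linspace(0.01, 0.2, 50)
        curve = ScatteringCurve(q, np.exp(+(q * 30) ** 2 / 3), None)
        with pytest.raises(ValueError, match="Guinier"):
            guinier_fit(curve)

    def test_smearing_bias_is_small(self, sphere_curve_factory):
        curve, _ = sphere_curve_factory(radius=30.0, noise=0.0)
        dq = np.full_like(curve.q, 0.002)
        smeared = gaussian_smear(curve, dq)
        rg_plain = guinier_fit(curve).rg
        rg_smear = guinier_fit(smeared).rg
        assert abs(rg_smear - rg_plain) / rg_plain < 0.02


class TestSmearing:
    def test_zero_dq_is_identity(self):
        q = np.linspace(0.01, 0.3, 60)
        I = np.exp(-(q * 20) ** 2)
        c = ScatteringCurve(q, I, None, dq=np.zeros_like(q))
        assert np.array_equal(gaussian_smear(c).I, I)

    def test_constant_curve_preserved(self):
        q = np.linspace(0.01, 0.3, 60)
        c = ScatteringCurve(q, np.full_like(q, 3.0), None, dq=np.full_like(q, 0.01))
        assert np.allclose(gaussian_smear(c).I, 3.0, rtol=1e-10)

    def test_peak_width_adds_in_quadrature(self):
        # moment check against the Gaussian convolution identity
        q = np.linspace(0.01, 0.6, 1200)
        w0, q0, sig = 0.01, 0.3, 0.02
        I = np.exp(-0.5 * ((q - q0) / w0) ** 2)
        c = ScatteringCurve(q, I, None, dq=np.full_like(q, sig))
        Is = gaussian_smear(c).I
        var = np.sum(Is * (q - np.sum(Is * q) / np.sum(Is)) ** 2) / np.sum(Is)
        assert math.sqrt(var) == pytest.approx(math.hypot(w0, sig), rel=0.02)

    def test_rows_renormalized_at_edges(self):
        q = np.linspace(0.01, 0.1, 20)
        W = smear_matrix(q, np.full_like(q, 0.02))
        assert np.allclose(W.sum(axis=1), 1.0, atol=1e-12)


class TestIntegratedIntensity:
    def test_unit_curve(self):
        q = np.linspace(0.1, 0.6, 51)
        c = ScatteringCurve(q, np.ones_like(q), None)
        assert integrated_intensity(c, 0.1, 0.6) == pytest.approx(0.5, rel=1e-12)

    def test_linear_curve_closed_form(self):
        q = np.linspace(0.01, 1.0, 400)
        c = ScatteringCurve(q, q.copy(), None)
        assert integrated_intensity(c, 0.01, 1.0) == pytest.approx(
            (1.0**2 - 0.01**2) / 2, rel=1e-6
        )

    def test_zero_curve_and_bad_window(self):
        q = np.linspace(0.1, 0.6, 51)
        c = ScatteringCurve(q, np.zeros_like(q), None)
        assert integrated_intensity(c, 0.2, 0.5) == 0.0
        with pytest.raises(ValueError):
            integrated_intensity(c, 0.5, 0.2)
        with pytest.raises(ValueError):
            integrated_intensity(c, 0.0, 0.5)


class TestAsciiIO:
    def test_roundtrip_lossless(self, tmp_path, sphere_curve_factory):
        curve, _ = sphere_curve_factory(noise=0.02, seed=3)
        curve.dq = 0.05 * curve.q
        curve.metadata["contrast"] = "protein"
        path = tmp_path / "curve.dat"
        write_sans(path, curve)
        back = read_sans(path)
        assert np.allclose(back.q, curve.q, rtol=1e-8)
        assert np.allclose(back.I, curve.I, rtol=1e-8)
        assert np.allclose(back.dq, curve.dq, rtol=1e-8)
        assert back.metadata["contrast"] == "protein"

    def test_three_columns_means_no_dq(self, tmp_path):
        path = tmp_path / "c3.dat"
        path.write_text("# q I dI\n0.01 1.0 0.1\n0.02 0.9 0.1\n0.03 0.8 0.1\n")
        assert read_sans(path).dq is None

    def test_descending_q_rejected_with_line(self, tmp_path):
        path = tmp_path / "bad.dat"
        path.write_text("0.02 1.0 0.1\n0.01 0.9 0.1\n0.03 0.8 0.1\n")
        with pytest.raises(ValueError, match="increasing"):
            read_sans(path)

    def test_too_few_columns_rejected(self, tmp_path):
        path = tmp_path / "bad2.dat"
        path.write_text("0.01 1.0\n0.02 0.9\n")
        with pytest.raises(ValueError, match="columns"):
            read_sans(path)
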