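"""Scattering-length-density and contrast-planning checks."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from surfprot import sld
from surfprot.constants import B_EXCHANGE, RESIDUE_TABLE, SLD_D2O, SLD_H2O


class TestSolventSld:
    def test_pure_components(self):
        assert sld.solvent_sld(1.0) == pytest.approx(SLD_H2O)
        assert sld.solvent_sld(0.0) == pytest.approx(SLD_D2O)

    def test_theoretical_match_composition(self):
        # 57.25% H2O mixture sits at 2.41e-6 with the documented constants
        assert sld.solvent_sld(0.5725) == pytest.approx(2.41e-6, abs=0.02e-6)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            sld.solvent_sld(1.2)

    @given(st.floats(0.0, 1.0), st.floats(0.0, 1.0))
    @settings(max_examples=50, deadline=None)
    def test_strictly_decreasing_in_f_h2o(self, f1, f2):
        if abs(f1 - f2) < 1e-9:  # below float resolution of the mix
            return
        lo, hi = sorted((f1, f2))
        assert sld.solvent_sld(lo) > sld.solvent_sld(hi)


class TestMoleculeSld:
    def test_no_deuterium_means_exchange_irrelevant(self):
        for x in (0.0, 0.5, 1.0):
            assert sld.molecule_sld("ACDEFG", 0.0, x) == pytest.approx(
                sld.molecule_sld("ACDEFG", 0.0, 0.9), rel=1e-12
            )

    def test_exchange_disabled_equals_protonated_table(self):
        seq = "G" * 10
        base = sld.molecule_sld(seq, 0.0, 0.0)
        for f in (0.3, 1.0):
            assert sld.molecule_sld(seq, f, 0.0) == pytest.approx(base, rel=1e-12)

    def test_gg_hand_summation(self):
        # independent hand summation of the shipped table entries
        b_g, nx_g, v_g = RESIDUE_TABLE["G"]
        b_w, nx_w, v_w = RESIDUE_TABLE["HOH"]
        deut = 0.9 * 1.0
        b_tot = 2 * (b_g + nx_g * deut * B_EXCHANGE) + (b_w + nx_w * deut * B_EXCHANGE)
        v_tot = 2 * v_g + v_w
        expected = b_tot * 1e-5 / v_tot
        assert sld.molecule_sld("GG", 1.0, 0.9) == pytest.approx(expected, rel=1e-12)

    def test_unknown_residue_reports_position(self):
        with pytest.raises(ValueError, match="position 3"):
            sld.molecule_sld("GGXG", 1.0)

    @given(st.floats(0.0, 1.0), st.floats(0.0, 1.0), st.floats(0.0, 1.0))
    @settings(max_examples=30, deadline=None)
    def test_affine_in_f_d2o(self, f1, f2, x):
        seq = "ACDEFGHIKLMNPQRSTVWY"
        mid = 0.5 * (f1 + f2)
        s_mid = sld.molecule_sld(seq, mid, x)
        s_avg = 0.5 * (sld.molecule_sld(seq, f1, x) + sld.molecule_sld(seq, f2, x))
        assert s_mid == pytest.approx(s_avg, rel=1e-9, abs=1e-18)


class TestTheoreticalMatchPoint:
    def test_constant_sld_molecule_inverts_solvent_line(self):
        mp = sld.theoretical_match_point(
            "G", molecule_sld_fn=lambda f_d2o: 2.41e-6
        )
        assert mp.found
        assert mp.f_h2o == pytest.approx(0.5725, abs=5e-4)
        # defining equality residual
        assert sld.solvent_sld(mp.f_h2o) == pytest.approx(2.41e-6, rel=1e-9)

    def test_boundary_match_at_d2o_sld(self):
        mp = sld.theoretical_match_point("G", molecule_sld_fn=lambda f: SLD_D2O)
        assert mp.found and mp.f_h2o == pytest.approx(0.0, abs=1e-9)

    def test_no_match_above_d2o(self):
        mp = sld.theoretical_match_point("G", molecule_sld_fn=lambda f: 7e-6)
        assert not mp.found
        assert mp.endpoint_residuals is not None

    def test_protein_sequence_match_residual(self):
        seq = "ACDEFGHIKLMNPQRSTVWY" * 5
        mp = sld.theoretical_match_point(seq)
        assert mp.found
        resid = sld.molecule_sld(seq, 1.0 - mp.f_h2o) - sld.solvent_sld(mp.f_h2o)
        assert abs(resid / mp.sld) < 1e-9


class TestExperimentalMatchPoint:
    def test_exact_collinear_construction(self):
        pts = [(0.0, 9.0), (0.3, 2.25), (0.6, 0.0), (0.9, 2.25)]
        x0, err = sld.experimental_match_point(pts)
        assert x0 == pytest.approx(0.6, abs=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            sld.experimental_match_point([(0.5, 1.0), (0.5, 2.0), (0.5, 3.0)])
        with pytest.raises(ValueError):
            sld.experimental_match_point([(0.0, 0.0), (0.5, 0.0), (1.0, 0.0)])

    def test_noisy_recovery_within_three_sigma(self):
        match = 0.601
        rng = np.random.default_rng(42)
        f = np.array([0.0, 0.2, 0.4, 0.8, 1.0])
        amp = 5.0
        i0 = (amp * (f - match)) ** 2
        noise = 0.02 * i0
        pts = [
            (fi, max(ii + rng.normal(0, ni), 0.0), max(ni, 1e-4))
            for fi, ii, ni in zip(f, i0, noise)
        ]
        x0, err = sld.experimental_match_point(pts)
        assert abs(x0 - match) < 3.0 * max(err, 1e-6)


class TestZac:
    def test_equal_volumes_arithmetic_mean(self):
        assert sld.zac_solvent(2e-6, 1.0, 6e-6, 1.0) == pytest.approx(4e-6)

    def test_single_component_limit(self):
        assert sld.zac_solvent(2e-6, 1.0, 6e-6, 0.0) == pytest.approx(2e-6)

    def test_self_consistent_solution_zeroes_mean_contrast(self):
        # protein SLD tracking the solvent through H/D exchange
        seq = "ACDEFGHIKLMNPQRSTVWY" * 3
        phi_p, phi_s = 1.0, 1.3
        sld_sds = 6.45e-6

        def prot(f_h2o):
            return sld.molecule_sld(seq, 1.0 - f_h2o)

        rho_s, f_h2o, ok = sld.zac_composition(prot, phi_p, sld_sds, phi_s)
        assert ok
        mean_contrast = (
            phi_p * (prot(f_h2o) - rho_s) + phi_s * (sld_sds - rho_s)
        ) / (phi_p + phi_s)
        assert abs(mean_contrast) < 1e-12 * max(abs(prot(f_h2o) - rho_s), abs(sld_sds - rho_s))

    def test_unattainable_composition_flagged(self):
        rho, f, ok = sld.zac_composition(lambda f: 7.2e-6, 1.0, 7.4e-6, 1.0)
        assert not ok and math.isnan(f)


def test_fasta_roundtrip(tmp_path):
    p = tmp_path / "seq.fasta"
    p.write_text(">rec1 test protein\nACDEF\nGHIKL\n")
    assert sld.read_fasta(p) == "ACDEFGHIKL"
    p2 = tmp_path / "two.fasta"
    p2.write_text(">a\nAC\n>b\nDE\n")
    with pytest.raises(ValueError):
        sld.read_fasta(p2)
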