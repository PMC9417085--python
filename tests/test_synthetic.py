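"""Generator contracts: determinism, contrast identities, clean limits."""

import numpy as np
import pytest

from surfprot.benchtop import detect_transitions, itc_transition_fit
from surfprot.sld import ContrastScheme
from surfprot.synthetic import (
    default_contrast_scheme,
    default_ground_truth,
    gen_cd,
    gen_fluorescence,
    gen_itc,
    gen_pyrene,
    gen_sans,
)


class TestDeterminism:
    def test_sans_bit_identical_for_fixed_seed(self, ground_truth):
        a = gen_sans(ground_truth, seed=21)
        b = gen_sans(ground_truth, seed=21)
        for label in a:
            assert np.array_equal(a[label].I, b[label].I)
        c = gen_sans(ground_truth, seed=22)
        assert not np.array_equal(a["complex"].I, c["complex"].I)

    def test_other_generators_deterministic(self, ground_truth):
        assert np.array_equal(
            gen_itc(ground_truth, seed=3).heat, gen_itc(ground_truth, seed=3).heat
        )
        assert np.array_equal(
            gen_pyrene(ground_truth, seed=3)[0].intensity,
            gen_pyrene(ground_truth, seed=3)[0].intensity,
        )
        assert np.array_equal(
            gen_cd(ground_truth, seed=3)[0].theta_mr,
            gen_cd(ground_truth, seed=3)[0].theta_mr,
        )
        assert np.array_equal(
            gen_fluorescence(ground_truth, seed=3)[0].intensity,
            gen_fluorescence(ground_truth, seed=3)[0].intensity,
        )


class TestContrastScheme:
    def test_matching_identities_enforced(self):
        scheme = default_contrast_scheme()
        p = scheme["protein"]
        assert p["sld_surfactant"] == p["sld_solvent"]
        c = scheme["complex"]
        assert c["sld_surfactant"] == c["sld_protein"]
        s = scheme["surfactant"]
        assert s["sld_protein"] == s["sld_solvent"]

    def test_violated_identity_rejected(self):
        with pytest.raises(ValueError, match="identity"):
            ContrastScheme(
                {
                    "protein": {
                        "sld_protein": 3.09e-6,
                        "sld_surfactant": 6.37e-6,
                        "sld_solvent": 5.0e-6,
                    }
                }
            )

    def test_protein_contrast_blind_to_surfactant(self, ground_truth):
        # surfactant matched to solvent: core visible only through shell SLDs
        model = ground_truth.model
        rho_core, rho_shell, rho_solv = model.contrast_slds("protein")
        assert rho_core == rho_solv


class TestSansGenerator:
    def test_noise_free_equals_smeared_model(self, ground_truth):
        from surfprot.sas import smear_matrix

        curves = gen_sans(ground_truth, noise=0.0, seed=0)
        lab = "complex"
        c = curves[lab]
        clean = ground_truth.model.intensity(lab, c.q) + ground_truth.backgrounds[lab]
        expected = smear_matrix(c.q, c.dq) @ clean
        assert np.allclose(c.I, expected, rtol=1e-12)

    def test_zac_curve_forward_intensity_is_background(self, ground_truth):
        c = gen_sans(ground_truth, noise=0.0, seed=0)["zac"]
        bkg = ground_truth.backgrounds["zac"]
        assert c.I[0] == pytest.approx(bkg, rel=0.001)
        # internal-correlation feature at finite q dwarfs the forward leak
        assert np.max(c.I) - bkg > 100.0 * (c.I[0] - bkg)
        assert np.max(c.I) - bkg > 1e-3

    def test_error_model_scales_with_noise(self, ground_truth):
        lo = gen_sans(ground_truth, noise=0.01, seed=1)["complex"]
        hi = gen_sans(ground_truth, noise=0.04, seed=1)["complex"]
        assert np.all(hi.dI > lo.dI)


class TestItcGenerator:
    def test_boundaries_collinear_in_protein_by_construction(self, ground_truth):
        pts = {
            P: gen_itc(ground_truth, protein_um=P, noise=0.0).metadata["boundaries_mm"]
            for P in (20.0, 40.0, 80.0)
        }
        for t, (nagg, unbound) in enumerate(
            zip(ground_truth.itc.nagg, ground_truth.itc.unbound_mm)
        ):
            for P, bounds in pts.items():
                assert bounds[t] == pytest.approx(unbound + nagg * P / 1000.0, rel=1e-12)

    def test_signal_zero_after_last_stage(self, ground_truth):
        e = gen_itc(ground_truth, protein_um=50.0, noise=0.0)
        last = e.metadata["boundaries_mm"][-1]
        tail = e.heat[e.sds_mm > last]
        assert tail.size > 3
        assert np.allclose(tail, 0.0, atol=1e-12)

    def test_noise_free_round_trip_recovers_stage_parameters(self, ground_truth):
        concs = (25.0, 50.0, 75.0)
        dets = {
            P: detect_transitions(gen_itc(ground_truth, protein_um=P, noise=0.0), n_max=6)
            for P in concs
        }
        assert all(len(d.boundaries) == 5 for d in dets.values())
        for t in range(5):
            fit = itc_transition_fit([(P, dets[P].boundaries[t]) for P in concs])
            assert fit.nagg == pytest.approx(ground_truth.itc.nagg[t], abs=0.5)
            assert fit.sds_unbound_mm == pytest.approx(
                ground_truth.itc.unbound_mm[t], abs=0.05
            )


class TestSpectralGenerators:
    def test_mixing_endpoints_return_pure_bases(self, ground_truth):
        specs = gen_fluorescence(ground_truth, ratios=[1e9], noise=0.0)
        spec = specs[0]
        assert spec.metadata["mix"] == pytest.approx(1.0, abs=1e-9)
        # fully denatured limit equals the red-shifted basis exactly
        wl = spec.wavelength
        denat = 0.55 * np.exp(-0.5 * ((wl - 352.0) / 29.0) ** 2)
        assert np.allclose(spec.intensity, denat, atol=1e-12)
        # the mixing fraction itself interpolates the two bases linearly
        mid = gen_fluorescence(ground_truth, ratios=[38.0], noise=0.0)[0]
        assert mid.metadata["mix"] == pytest.approx(0.5, abs=1e-12)

    def test_pyrene_plateau_levels(self, ground_truth):
        from surfprot.benchtop import pyrene_ratio

        lo = gen_pyrene(ground_truth, sds_mm=[0.01], noise=0.0)[0]
        hi = gen_pyrene(
            ground_truth,
            sds_mm=[ground_truth.pyrene_cac_mm + 5 * ground_truth.pyrene_rise_mm],
            noise=0.0,
        )[0]
        assert pyrene_ratio(lo) == pytest.approx(ground_truth.pyrene_low, abs=0.01)
        assert pyrene_ratio(hi) == pytest.approx(ground_truth.pyrene_high, abs=0.01)

    def test_protein_free_mode_uses_buffer_cmc(self, ground_truth):
        from surfprot.benchtop import breakpoint_intersection, pyrene_ratio

        cmc = 4.1
        sds = np.linspace(0.2, cmc + 1.0, 20)
        specs = gen_pyrene(ground_truth, sds_mm=sds, cac_mm=cmc, noise=0.0)
        x = [s.metadata["sds_mm"] for s in specs]
        y = [pyrene_ratio(s) for s in specs]
        res = breakpoint_intersection(x, y)
        assert res.breakpoint == pytest.approx(cmc, abs=0.1)
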