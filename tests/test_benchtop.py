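"""Titration analytics: CM, pyrene ratio, breakpoints, ITC, CD, A280."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from surfprot.benchtop import (
    EmissionSpectrum,
    Enthalpogram,
    breakpoint_intersection,
    cac_ratio,
    center_of_mass,
    conc_from_a280,
    detect_transitions,
    ellipticity_descriptors,
    itc_transition_fit,
    mean_residue_ellipticity,
    predict_total_sds,
    pyrene_ratio,
)
from surfprot.synthetic import gen_cd, gen_fluorescence, gen_pyrene


class TestCenterOfMass:
    def test_symmetric_band_center(self):
        # narrow band, symmetric window: truncation plays no role
        wl = np.arange(310.0, 450.5, 0.5)
        spec = EmissionSpectrum(wl, np.exp(-0.5 * ((wl - 338) / 6) ** 2))
        assert center_of_mass(spec, window=(318.0, 358.0)) == pytest.approx(338.0, abs=0.01)

    def test_two_point_arithmetic(self):
        spec = EmissionSpectrum([300.0, 400.0], [1.0, 3.0])
        assert center_of_mass(spec, window=(300, 400)) == pytest.approx(375.0)

    def test_monotone_in_red_state_fraction(self):
        wl = np.arange(305.0, 455.0, 1.0)
        native = np.exp(-0.5 * ((wl - 338) / 24) ** 2)
        red = 0.55 * np.exp(-0.5 * ((wl - 352) / 29) ** 2)
        cms = [
            center_of_mass(EmissionSpectrum(wl, (1 - f) * native + f * red))
            for f in np.linspace(0, 1, 9)
        ]
        assert all(np.diff(cms) > 0)

    @given(st.floats(0.1, 100.0))
    @settings(max_examples=25, deadline=None)
    def test_invariant_under_intensity_scaling(self, scale):
        wl = np.arange(310.0, 451.0, 1.0)
        inten = np.exp(-0.5 * ((wl - 345) / 18) ** 2) + 0.01
        a = center_of_mass(EmissionSpectrum(wl, inten))
        b = center_of_mass(EmissionSpectrum(wl, scale * inten))
        assert a == pytest.approx(b, rel=1e-12)
        assert 310.0 <= a <= 450.0

    def test_zero_intensity_rejected(self):
        wl = np.arange(310.0, 451.0, 1.0)
        with pytest.raises(ValueError):
            center_of_mass(EmissionSpectrum(wl, np.zeros_like(wl)))


class TestPyreneRatio:
    def test_equal_peaks_give_unity(self):
        wl = np.arange(360.0, 400.5, 0.5)
        inten = np.exp(-0.5 * ((wl - 373) / 2) ** 2) + np.exp(
            -0.5 * ((wl - 384) / 2) ** 2
        )
        assert pyrene_ratio(EmissionSpectrum(wl, inten)) == pytest.approx(1.0, abs=1e-6)

    def test_linearity_in_band3(self):
        wl = np.arange(360.0, 400.5, 0.5)
        b1 = np.exp(-0.5 * ((wl - 373) / 2) ** 2)
        b3 = np.exp(-0.5 * ((wl - 384) / 2) ** 2)
        r1 = pyrene_ratio(EmissionSpectrum(wl, b1 + 0.4 * b3))
        r2 = pyrene_ratio(EmissionSpectrum(wl, b1 + 0.8 * b3))
        assert r2 == pytest.approx(2 * r1, rel=1e-6)

    def test_missing_band_window_rejected(self):
        wl = np.arange(360.0, 375.0, 0.5)
        with pytest.raises(ValueError):
            pyrene_ratio(EmissionSpectrum(wl, np.ones_like(wl)))

    def test_generator_ratio_recovered(self, ground_truth):
        specs = gen_pyrene(ground_truth, sds_mm=[5.0], noise=0.0)
        true_r = specs[0].metadata["ratio_true"]
        assert pyrene_ratio(specs[0]) == pytest.approx(true_r, abs=0.01)


class TestBreakpoint:
    def test_exact_two_line_construction(self):
        x = np.array([0.0, 0.25, 0.5, 0.75, 1.25, 1.5, 1.75, 2.0])
        y = np.where(x < 1.0, 1.0, 2 * x - 1.0)
        res = breakpoint_intersection(x, y)
        assert res.has_breakpoint
        assert res.breakpoint == pytest.approx(1.0, abs=1e-9)

    def test_collinear_data_flagged(self):
        x = np.linspace(0, 2, 10)
        res = breakpoint_intersection(x, 3 * x + 0.5)
        assert not res.has_breakpoint

    def test_pyrene_cac_recovery(self, ground_truth):
        specs = gen_pyrene(ground_truth, seed=13)
        x = [s.metadata["sds_mm"] for s in specs]
        y = [pyrene_ratio(s) for s in specs]
        sel = [xi <= ground_truth.pyrene_cac_mm + ground_truth.pyrene_rise_mm for xi in x]
        res = breakpoint_intersection(
            [xi for xi, s in zip(x, sel) if s], [yi for yi, s in zip(y, sel) if s]
        )
        assert res.has_breakpoint
        assert abs(res.breakpoint - ground_truth.pyrene_cac_mm) < max(
            3 * res.breakpoint_err, 0.06
        )

    @given(st.floats(0.1, 10.0), st.floats(-5.0, 5.0))
    @settings(max_examples=20, deadline=None)
    def test_equivariance_under_affine_x(self, a, b):
        x = np.array([0.0, 0.3, 0.6, 0.9, 1.3, 1.6, 1.9, 2.2])
        y = np.where(x < 1.0, 1.0, 2 * x - 1.0)
        base = breakpoint_intersection(x, y).breakpoint
        scaled = breakpoint_intersection(a * x + b, y).breakpoint
        assert scaled == pytest.approx(a * base + b, rel=1e-6, abs=1e-9)


class TestItcStoichiometry:
    def test_collinear_table_row(self):
        fit = itc_transition_fit([(25.0, 2.1), (50.0, 2.9), (75.0, 3.7)])
        assert fit.nagg == pytest.approx(32.0, abs=1e-9)
        assert fit.sds_unbound_mm == pytest.approx(1.3, abs=1e-12)
        assert fit.nagg_err == pytest.approx(0.0, abs=1e-9)
        assert fit.sds_unbound_err == pytest.approx(0.0, abs=1e-9)

    def test_zero_slope_data(self):
        fit = itc_transition_fit([(25.0, 1.5), (50.0, 1.5), (75.0, 1.5)])
        assert fit.nagg == pytest.approx(0.0, abs=1e-12)
        assert fit.sds_unbound_mm == pytest.approx(1.5)

    def test_single_concentration_rejected(self):
        with pytest.raises(ValueError):
            itc_transition_fit([(50.0, 2.9), (50.0, 3.0)])

    def test_predictions_reproduce_fitted_line(self):
        fit = itc_transition_fit([(25.0, 2.1), (50.0, 2.9), (75.0, 3.7)])
        total, ratio = predict_total_sds(fit, 50.0)
        assert total == pytest.approx(2.9, abs=1e-9)
        assert round(ratio) == 58
        total0, ratio0 = predict_total_sds(fit, 0.0)
        assert total0 == pytest.approx(1.3)
        assert math.isnan(ratio0)

    def test_cac_ratio_units(self):
        assert round(cac_ratio(0.43, 10.3)) == 42
        assert cac_ratio(4.1, 10.3) == pytest.approx(398.06, abs=0.01)
        assert cac_ratio(2.0, 2000.0) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            cac_ratio(1.0, 0.0)


class TestDetectTransitions:
    def test_straight_line_has_no_interior_transitions(self):
        x = np.linspace(0.1, 10, 30)
        e = Enthalpogram(x, -0.5 * x + 1.0, 50.0)
        det = detect_transitions(e, n_max=4)
        assert det.boundaries == []
        assert not det.complete

    def test_single_kink_located(self):
        x = np.linspace(0.1, 10, 40)
        y = np.where(x < 4.0, -1.0, -1.0 + 0.8 * (x - 4.0))
        det = detect_transitions(Enthalpogram(x, y, 50.0), n_max=3)
        assert len(det.boundaries) == 1
        assert det.boundaries[0] == pytest.approx(4.0, abs=np.diff(x)[0])

    def test_too_few_injections_rejected(self):
        x = np.linspace(0.1, 2, 10)
        with pytest.raises(ValueError):
            detect_transitions(Enthalpogram(x, -x, 50.0))


class TestCdDescriptors:
    def test_equal_bands_unit_ratio(self):
        from surfprot.benchtop import CDSpectrum

        wl = np.arange(190.0, 310.0, 1.0)
        theta = -1000.0 * np.ones_like(wl)
        d = ellipticity_descriptors(CDSpectrum(wl, theta))
        assert d["ratio_220_209"] == pytest.approx(1.0)

    def test_pure_bases_are_trajectory_endpoints(self, ground_truth):
        specs = gen_cd(ground_truth, ratios=[1e-6, 1e6], noise=0.0)
        d0 = ellipticity_descriptors(specs[0])
        d1 = ellipticity_descriptors(specs[1])
        assert abs(d0["theta292"]) > abs(d1["theta292"])  # tertiary band collapses
        assert d0["ratio_220_209"] != pytest.approx(d1["ratio_220_209"], rel=0.01)

    def test_near_transition_precedes_far_transition(self, ground_truth):
        ratios = np.geomspace(1.0, 400.0, 31)
        specs = gen_cd(ground_truth, ratios=ratios, noise=0.0)
        t292 = np.array([ellipticity_descriptors(s)["theta292"] for s in specs])
        r220 = np.array([ellipticity_descriptors(s)["ratio_220_209"] for s in specs])
        mid292 = ratios[np.argmin(np.abs(t292 - 0.5 * (t292[0] + t292[-1])))]
        mid220 = ratios[np.argmin(np.abs(r220 - 0.5 * (r220[0] + r220[-1])))]
        assert mid292 < mid220  # tertiary structure goes first

    def test_out_of_range_wavelength_rejected(self):
        from surfprot.benchtop import CDSpectrum

        wl = np.arange(200.0, 250.0, 1.0)
        with pytest.raises(ValueError):
            ellipticity_descriptors(CDSpectrum(wl, -np.ones_like(wl)))


class TestConversions:
    def test_mean_residue_ellipticity_formula(self):
        # theta * MRW / (10 * path * conc): 10 * 110 / (10 * 0.1 * 1)
        assert mean_residue_ellipticity(10.0, 110.0, 0.1, 1.0) == pytest.approx(1100.0)
        assert mean_residue_ellipticity(0.0, 110.0, 0.1, 1.0) == 0.0
        half = mean_residue_ellipticity(10.0, 110.0, 0.2, 1.0)
        assert half == pytest.approx(550.0)
        with pytest.raises(ValueError):
            mean_residue_ellipticity(10.0, 110.0, 0.0, 1.0)

    def test_beer_lambert_with_study_constants(self):
        molar, gl = conc_from_a280(1.767, 17670.0, 1.0, 22124.0)
        assert molar == pytest.approx(1.0e-4, rel=1e-9)
        assert gl == pytest.approx(1.0e-4 * 22124.0, rel=1e-9)
        assert conc_from_a280(0.0, 17670.0, 1.0, 22124.0)[0] == 0.0

    def test_fluorescence_cm_tracks_titration(self, ground_truth):
        specs = gen_fluorescence(ground_truth, ratios=np.geomspace(1, 400, 15), noise=0.0)
        cms = [center_of_mass(s) for s in specs]
        assert all(np.diff(cms) >= -1e-9)
        assert cms[-1] - cms[0] > 2.0  # clear red shift across the titration
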