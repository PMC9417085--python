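"""Seeded synthetic-data generators for every modality the package analyses.

No raw beamline or instrument data ship with the package, so each
analysis route is exercised against generated data with known ground
truth. The generators encode the statistical structure the analysis
assumes:

* SANS — four-contrast curves of a core-shell ellipsoid complex
  (surfactant core, partially covering protein shell), structure factor
  of charged spheres, Gaussian resolution smearing, counting-like noise
  dI = a sqrt(I) + b;
* ITC — five-stage piecewise-linear enthalpograms whose stage
  boundaries obey [SDS] = [SDS]_unbound + N_agg [protein], signal
  decaying to zero after the last stage;
* fluorescence — two-state mixing of native/denatured tryptophan
  emission bases with a logistic transition in the mixing fraction;
* pyrene — two-plateau I3/I1 ramp with its lower kink at the
  generating CAC/CMC;
* CD — two-basis titrations with separate near-UV (tertiary) and
  far-UV (secondary) transition midpoints.

All generators are pure functions of (ground truth, seed): a fixed
seed reproduces outputs bit for bit. Defaults mirror the end-state
decorated-micelle complex of the hGH-SDS study conditions (coverage
0.66, net charge -29, 0.135 mM protein).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .benchtop import EmissionSpectrum, CDSpectrum, Enthalpogram
from .cofit import ComplexModel
from .constants import N_A, V_SDS
from .sas import GeometryParams, ScatteringCurve, smear_matrix
from .sld import ContrastScheme, zac_solvent

__all__ = [
    "GroundTruth",
    "default_ground_truth",
    "default_contrast_scheme",
    "gen_sans",
    "gen_itc",
    "gen_fluorescence",
    "gen_pyrene",
    "gen_cd",
]


# Table-2-style contrast scheme of the four isotopic conditions
# (SLDs in A^-2). The ZAC solvent entry is filled in by
# default_contrast_scheme from the ZAC condition itself.
_SLD_PROTEIN_D2O = 3.09e-6
_SLD_PROTEIN_75D = 2.79e-6
_SLD_PROTEIN_MATCH = 2.31e-6
_SLD_SDS_H = 6.37e-6  # d-SDS in the protonated-solvent sense of the scheme
_SLD_SDS_ZAC = 6.45e-6


def default_contrast_scheme(
    geometry: GeometryParams | None = None, coverage: float = 0.66
) -> ContrastScheme:
    """The four-contrast labelling scheme used throughout the package.

    protein: surfactant matched to solvent; complex: surfactant matched
    to protein; surfactant: protein matched to solvent; zac: solvent at
    the zero-average-contrast composition of the core+protein-shell
    complex (computed from the geometry, so the ZAC prediction I(0)=0
    holds exactly for the default model).
    """
    if geometry is None:
        geometry = default_ground_truth().model.geometry
    v_core = geometry.core_volume
    v_shell = geometry.total_volume - v_core
    sld_zac = zac_solvent(
        _SLD_SDS_ZAC, v_core, _SLD_PROTEIN_75D, coverage * v_shell
    )
    return ContrastScheme(
        {
            "protein": {
                "sld_protein": _SLD_PROTEIN_D2O,
                "sld_surfactant": _SLD_SDS_H,
                "sld_solvent": _SLD_SDS_H,
            },
            "complex": {
                "sld_protein": _SLD_PROTEIN_D2O,
                "sld_surfactant": _SLD_PROTEIN_D2O,
                "sld_solvent": 6.37e-6,
            },
            "surfactant": {
                "sld_protein": _SLD_PROTEIN_MATCH,
                "sld_surfactant": _SLD_SDS_H,
                "sld_solvent": _SLD_PROTEIN_MATCH,
            },
            "zac": {
                "sld_protein": _SLD_PROTEIN_75D,
                "sld_surfactant": _SLD_SDS_ZAC,
                "sld_solvent": sld_zac,
            },
        }
    )


@dataclass
class ItcTruth:
    """Five-stage binding decomposition (per-transition N_agg, unbound mM)."""

    nagg: tuple[float, ...] = (6.0, 23.0, 32.0, 61.0, 61.0)
    unbound_mm: tuple[float, ...] = (0.51, 0.81, 1.3, 4.1, 5.4)
    # molar heat (kcal/mol injectant) at the start and at each boundary
    heat_nodes: tuple[float, ...] = (-0.8, -2.2, -1.0, -3.0, -1.2, 0.0)
    noise_kcal: float = 0.05

    def __post_init__(self) -> None:
        if list(self.unbound_mm) != sorted(self.unbound_mm):
            raise ValueError("stage boundaries must be ordered")
        if len(self.heat_nodes) != len(self.nagg) + 1:
            raise ValueError("need one heat node per boundary plus the start")


@dataclass
class TwoStateTruth:
    """Two-state titration: logistic mixing vs surfactant/protein ratio."""

    midpoint: float
    width: float


@dataclass
class GroundTruth:
    """Everything the generators need, with per-modality noise levels."""

    model: ComplexModel
    protein_mm: float = 0.135  # protein concentration, mM
    itc: ItcTruth = field(default_factory=ItcTruth)
    fluor: TwoStateTruth = field(default_factory=lambda: TwoStateTruth(38.0, 10.0))
    cd_near: TwoStateTruth = field(default_factory=lambda: TwoStateTruth(16.0, 8.0))
    cd_far: TwoStateTruth = field(default_factory=lambda: TwoStateTruth(59.0, 15.0))
    pyrene_cac_mm: float = 0.43
    pyrene_rise_mm: float = 1.0
    pyrene_low: float = 0.65
    pyrene_high: float = 0.95
    sans_noise_a: float = 0.01  # dI = a sqrt(I) + b
    sans_noise_b: float = 1e-3
    spectrum_noise: float = 0.002  # relative to basis amplitude
    backgrounds: dict = field(
        default_factory=lambda: {
            "protein": 0.01,
            "complex": 0.01,
            "surfactant": 0.05,
            "zac": 0.02,
        }
    )


def default_ground_truth() -> GroundTruth:
    """The end-state decorated-micelle complex as generator default.

    Core: SDS cluster of N_agg = 26 molecules (v_core = 26 x 412 A^3)
    as a prolate ellipsoid of axial ratio 1.5; shell: 12 A protein
    layer at coverage 0.66; net charge -29; volume fraction from
    0.135 mM complexes.
    """
    v_core = 26.0 * V_SDS
    ax = 1.5
    a = (v_core / (4.0 / 3.0 * math.pi * ax)) ** (1.0 / 3.0)
    shell = 12.0
    protein_mm = 0.135
    n_dens = protein_mm * 1e-3 * N_A / 1e27  # complexes per A^3
    a_t = a + shell
    c_t = ax * a + shell
    v_tot = 4.0 / 3.0 * math.pi * a_t * a_t * c_t
    geometry = GeometryParams(
        kind="core_shell_ellipsoid",
        radius=a,
        axial_ratio=ax,
        shell_thickness=shell,
        volume_fraction=n_dens * v_tot,
        background=0.0,
    )
    scheme = default_contrast_scheme(geometry, coverage=0.66)
    model = ComplexModel(
        geometry=geometry,
        scheme=scheme,
        coverage=0.66,
        charge=-29.0,
        salt_molar=0.010,
    )
    return GroundTruth(model=model, protein_mm=protein_mm)


def gen_sans(
    truth: GroundTruth | None = None,
    q: np.ndarray | None = None,
    dq_frac: float = 0.05,
    noise: float | None = None,
    seed: int = 0,
) -> dict[str, ScatteringCurve]:
    """Four labelled contrast curves of the ground-truth complex.

    ``dq_frac`` sets the Gaussian resolution width dq = dq_frac * q;
    ``noise`` scales the counting-noise amplitude (None = the truth's
    default, 0 = noise-free model curves). The contrast-matching
    identities of the scheme are enforced by construction.
    """
    truth = truth or default_ground_truth()
    if q is None:
        q = np.geomspace(0.008, 0.45, 80)
    q = np.asarray(q, dtype=float)
    dq = dq_frac * q
    a = truth.sans_noise_a if noise is None else noise
    rng = np.random.default_rng(seed)
    W = smear_matrix(q, dq)

    curves: dict[str, ScatteringCurve] = {}
    for label in truth.model.scheme.labels():
        bkg = truth.backgrounds.get(label, 0.0)
        i_clean = truth.model.intensity(label, q) + bkg
        i_smeared = W @ i_clean
        dI = a * np.sqrt(np.abs(i_smeared)) + truth.sans_noise_b * (a > 0)
        i_noisy = i_smeared + rng.normal(0.0, 1.0, q.size) * dI
        curves[label] = ScatteringCurve(
            q=q,
            I=i_noisy,
            dI=np.where(dI > 0, dI, 1e-6),
            dq=dq,
            metadata={
                "contrast": label,
                "background": bkg,
                "seed": seed,
                "noise_a": a,
            },
        )
    return curves


def gen_itc(
    truth: GroundTruth | None = None,
    protein_um: float = 50.0,
    syringe_mm: float = 60.0,
    cell_ml: float = 1.4,
    inj_ul=None,
    noise: float | None = None,
    seed: int = 0,
) -> Enthalpogram:
    """One synthetic enthalpogram at a given cell protein concentration.

    SDS accumulates in the cell according to the standard perfusion-
    cell displacement model, [SDS]_k = C_syr (1 - exp(-V_k / V_cell));
    the molar heat per injection is piecewise linear in [SDS] between
    the stage boundaries [SDS]_unbound,t + N_agg,t [protein], reaching
    zero at the last boundary and staying there (with noise).

    ``inj_ul`` is the per-injection volume schedule (uL); the default
    uses small early injections to resolve the low-concentration
    transitions, as in routine ITC practice (25 x 2 uL, then 30 x 10).
    """
    truth = truth or default_ground_truth()
    itc = truth.itc
    rng = np.random.default_rng(seed)
    if inj_ul is None:
        inj_ul = np.concatenate([np.full(25, 2.0), np.full(30, 10.0)])
    inj_ul = np.atleast_1d(np.asarray(inj_ul, dtype=float))
    n_inj = inj_ul.size
    v_cum = np.cumsum(inj_ul) * 1e-3  # mL
    sds_mm = syringe_mm * (1.0 - np.exp(-v_cum / cell_ml))
    bounds = np.array(itc.unbound_mm) + np.array(itc.nagg) * protein_um / 1000.0
    nodes_x = np.concatenate([[0.0], bounds])
    nodes_y = np.asarray(itc.heat_nodes, dtype=float)
    heat = np.interp(sds_mm, nodes_x, nodes_y, right=nodes_y[-1])
    s = itc.noise_kcal if noise is None else noise
    heat = heat + rng.normal(0.0, 1.0, n_inj) * s
    return Enthalpogram(
        sds_mm=sds_mm,
        heat=heat,
        protein_um=protein_um,
        metadata={
            "seed": seed,
            "syringe_mm": syringe_mm,
            "boundaries_mm": bounds.tolist(),
            "noise_kcal": s,
        },
    )


def _logistic(x: np.ndarray | float, midpoint: float, width: float):
    return 1.0 / (1.0 + np.exp(-(np.asarray(x, dtype=float) - midpoint) / width))


def _gauss(x: np.ndarray, mu: float, sig: float) -> np.ndarray:
    return np.exp(-0.5 * ((x - mu) / sig) ** 2)


def gen_fluorescence(
    truth: GroundTruth | None = None,
    ratios=None,
    wavelength: np.ndarray | None = None,
    noise: float | None = None,
    seed: int = 0,
) -> list[EmissionSpectrum]:
    """Tryptophan emission spectra along an SDS/protein titration.

    Two-state mixing of a native basis (band at 338 nm) and a red-
    shifted, weaker denatured basis (352 nm); the denatured fraction
    follows a logistic in the surfactant-to-protein ratio.
    """
    truth = truth or default_ground_truth()
    if ratios is None:
        ratios = np.geomspace(1.0, 400.0, 25)
    if wavelength is None:
        wavelength = np.arange(305.0, 455.0, 1.0)
    s = truth.spectrum_noise if noise is None else noise
    rng = np.random.default_rng(seed)
    native = _gauss(wavelength, 338.0, 24.0)
    denat = 0.55 * _gauss(wavelength, 352.0, 29.0)
    out = []
    for ratio in np.asarray(ratios, dtype=float):
        f = float(_logistic(ratio, truth.fluor.midpoint, truth.fluor.width))
        inten = (1.0 - f) * native + f * denat
        inten = np.clip(inten + rng.normal(0.0, s, wavelength.size), 0.0, None)
        out.append(
            EmissionSpectrum(
                wavelength, inten, metadata={"sds_per_protein": float(ratio), "mix": f}
            )
        )
    return out


def gen_pyrene(
    truth: GroundTruth | None = None,
    sds_mm=None,
    cac_mm: float | None = None,
    wavelength: np.ndarray | None = None,
    noise: float | None = None,
    seed: int = 0,
) -> list[EmissionSpectrum]:
    """Pyrene emission series whose I3/I1 ramps up at the CAC/CMC.

    The generating ratio is a two-plateau piecewise-linear sigmoid with
    its lower kink exactly at ``cac_mm`` (the truth's CAC by default;
    pass the buffer CMC for protein-free series). Spectra are two
    vibronic bands at 373 and 384 nm with the prescribed ratio.
    """
    truth = truth or default_ground_truth()
    cac = truth.pyrene_cac_mm if cac_mm is None else cac_mm
    if sds_mm is None:
        sds_mm = np.linspace(0.05, cac + 3.0 * truth.pyrene_rise_mm, 24)
    if wavelength is None:
        wavelength = np.arange(360.0, 400.5, 0.5)
    s = truth.spectrum_noise if noise is None else noise
    rng = np.random.default_rng(seed)
    band1 = _gauss(wavelength, 373.0, 2.0)
    band3 = _gauss(wavelength, 384.0, 2.0)
    out = []
    for c in np.asarray(sds_mm, dtype=float):
        frac = np.clip((c - cac) / truth.pyrene_rise_mm, 0.0, 1.0)
        ratio = truth.pyrene_low + (truth.pyrene_high - truth.pyrene_low) * frac
        inten = band1 + ratio * band3
        inten = np.clip(inten + rng.normal(0.0, s, wavelength.size), 0.0, None)
        out.append(
            EmissionSpectrum(
                wavelength,
                inten,
                metadata={"sds_mm": float(c), "ratio_true": float(ratio)},
            )
        )
    return out


# far-UV alpha-helix-like and partially unfolded basis spectra, plus a
# near-UV tertiary-structure band at 292 nm
def _cd_basis(wavelength: np.ndarray, native: bool) -> np.ndarray:
    wl = wavelength
    if native:
        far = (
            60000.0 * _gauss(wl, 192.0, 6.5)
            - 11000.0 * _gauss(wl, 209.0, 8.0)
            - 11000.0 * _gauss(wl, 221.5, 10.0)
        )
        near = -150.0 * _gauss(wl, 292.0, 5.0) - 80.0 * _gauss(wl, 265.0, 8.0)
    else:
        far = (
            30000.0 * _gauss(wl, 190.0, 6.0)
            - 9000.0 * _gauss(wl, 207.0, 9.0)
            - 5500.0 * _gauss(wl, 222.0, 11.0)
        )
        near = -25.0 * _gauss(wl, 292.0, 5.0) - 60.0 * _gauss(wl, 265.0, 8.0)
    return far + near


def gen_cd(
    truth: GroundTruth | None = None,
    ratios=None,
    wavelength: np.ndarray | None = None,
    noise: float | None = None,
    seed: int = 0,
) -> list[CDSpectrum]:
    """CD titration with separate near- and far-UV transitions.

    The near-UV (tertiary, 292 nm) and far-UV (secondary, 220/209)
    regions mix between native and denatured bases with their own
    logistic midpoints, reproducing the two-stage denaturation pattern.
    """
    truth = truth or default_ground_truth()
    if ratios is None:
        ratios = np.geomspace(1.0, 400.0, 25)
    if wavelength is None:
        wavelength = np.arange(185.0, 310.5, 0.5)
    s = truth.spectrum_noise if noise is None else noise
    rng = np.random.default_rng(seed)
    nat = _cd_basis(wavelength, True)
    den = _cd_basis(wavelength, False)
    # split the mixing at 250 nm: far-UV below, near-UV above
    far_sel = wavelength <= 250.0
    out = []
    for ratio in np.asarray(ratios, dtype=float):
        f_far = float(_logistic(ratio, truth.cd_far.midpoint, truth.cd_far.width))
        f_near = float(_logistic(ratio, truth.cd_near.midpoint, truth.cd_near.width))
        theta = np.where(
            far_sel,
            (1.0 - f_far) * nat + f_far * den,
            (1.0 - f_near) * nat + f_near * den,
        )
        theta = theta + rng.normal(0.0, s * 1000.0, wavelength.size)
        out.append(
            CDSpectrum(
                wavelength,
                theta,
                metadata={
                    "sds_per_protein": float(ratio),
                    "mix_far": f_far,
                    "mix_near": f_near,
                },
            )
        )
    return out
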