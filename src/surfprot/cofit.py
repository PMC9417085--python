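"""Simultaneous co-refinement of multi-contrast SANS curves.

A single structural model of a surfactant-protein complex — a
core-shell ellipsoid whose core is the surfactant cluster and whose
shell is protein covering a fraction ``coverage`` of the surface — is
refined against several SANS curves measured under different isotopic
contrast conditions at once. The geometry, coverage and net charge are
shared across contrasts; an intensity scale and flat background are
per-contrast. From the fitted geometry follow the surfactant
aggregation number (core volume over the molecular volume of one
surfactant) and, from the shell SLD, the protein surface coverage.

The shell SLD under contrast ``k`` is the two-component mix

    rho_shell(k) = coverage * rho_protein(k) + (1 - coverage) * rho_solvent(k)

so a partially covered micelle is handled without extra parameters per
contrast. Interparticle interference enters as I = P(q) S(q) with the
rescaled-MSA structure factor of charged spheres at the equal-volume
sphere diameter of the complex.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from .constants import V_SDS
from .sas import (
    GeometryParams,
    ScatteringCurve,
    form_factor_intensity,
    smear_matrix,
)
from .sld import ContrastScheme, zac_solvent
from .structure_factor import ColloidParams, rmsa_sq

__all__ = [
    "ComplexModel",
    "FitResult",
    "ZacCheckResult",
    "simultaneous_fit",
    "nagg_from_core",
    "coverage_from_shell",
    "zac_forward_check",
]


@dataclass
class ComplexModel:
    """Core-shell complex + interaction parameters + contrast bindings."""

    geometry: GeometryParams
    scheme: ContrastScheme
    coverage: float = 0.66
    charge: float = 0.0
    v_sds: float = V_SDS
    temperature: float = 298.15
    dielectric: float = 78.3
    salt_molar: float = 0.010
    sq_dr: float = 0.002  # radial resolution of the RMSA solver

    def __post_init__(self) -> None:
        if not 0.0 <= self.coverage <= 1.0:
            raise ValueError("coverage must be in [0, 1]")
        if self.v_sds <= 0:
            raise ValueError("v_sds must be positive")

    def contrast_slds(self, label: str) -> tuple[float, float, float]:
        """(sld_core, sld_shell, sld_solvent) under a contrast label."""
        entry = self.scheme[label]
        rho_p = entry["sld_protein"]
        rho_s = entry["sld_solvent"]
        rho_core = entry["sld_surfactant"]
        rho_shell = self.coverage * rho_p + (1.0 - self.coverage) * rho_s
        return rho_core, rho_shell, rho_s

    def geometry_for(self, label: str) -> GeometryParams:
        rho_core, rho_shell, rho_s = self.contrast_slds(label)
        return replace(
            self.geometry,
            sld_core=rho_core,
            sld_shell=rho_shell,
            sld_solvent=rho_s,
        )

    def structure_factor(self, q: np.ndarray) -> np.ndarray:
        if self.charge == 0:
            return np.ones_like(q)
        colloid = ColloidParams(
            volume_fraction=self.geometry.volume_fraction,
            sigma_eff=self.geometry.equivalent_sphere_diameter,
            charge=self.charge,
            temperature=self.temperature,
            dielectric=self.dielectric,
            salt_molar=self.salt_molar,
        )
        return rmsa_sq(q, colloid, dr=self.sq_dr)

    def intensity(
        self,
        label: str,
        q: np.ndarray,
        dq: np.ndarray | None = None,
        scale: float = 1.0,
        background: float = 0.0,
    ) -> np.ndarray:
        """Absolute-scale model intensity for one contrast, cm^-1."""
        geo = self.geometry_for(label)
        p_q = form_factor_intensity(geo, q)
        i_q = scale * p_q * self.structure_factor(q) + background
        if dq is not None:
            i_q = smear_matrix(q, dq) @ i_q
        return i_q

    @property
    def nagg(self) -> float:
        return self.geometry.core_volume / self.v_sds


@dataclass
class FitResult:
    """Co-refinement result: parameters, uncertainties and derived values."""

    params: dict[str, float]
    errors: dict[str, float]
    chi2_red: dict[str, float]
    chi2_red_global: float
    nagg: float
    nagg_err: float
    coverage: float
    coverage_err: float
    charge: float
    charge_err: float
    model: ComplexModel
    scales: dict[str, float]
    backgrounds: dict[str, float]
    nfev: int
    cost: float
    n_starts: int = 1

    @property
    def nagg_int(self) -> int:
        return int(round(self.nagg))

    def to_dict(self) -> dict:
        return {
            "parameters": self.params,
            "uncertainties": self.errors,
            "chi2_red_per_contrast": self.chi2_red,
            "chi2_red_global": self.chi2_red_global,
            "derived": {
                "nagg": self.nagg,
                "nagg_err": self.nagg_err,
                "nagg_int": self.nagg_int,
                "coverage": self.coverage,
                "coverage_err": self.coverage_err,
                "charge": self.charge,
                "charge_err": self.charge_err,
            },
            "scales": self.scales,
            "backgrounds": self.backgrounds,
        }


_SHARED_NAMES = ("radius", "axial_ratio", "shell_thickness", "coverage", "charge")
_BOUNDS = {
    "radius": (2.0, 500.0),
    "axial_ratio": (0.2, 5.0),
    "shell_thickness": (0.0, 200.0),
    "coverage": (0.0, 1.0),
    "charge": (-300.0, 300.0),
    "scale": (1e-3, 1e3),
    "background": (-1.0, 1.0),
}


def simultaneous_fit(
    curves: dict[str, ScatteringCurve],
    model: ComplexModel,
    free: tuple[str, ...] = ("radius", "axial_ratio", "shell_thickness", "coverage", "charge"),
    fit_scale: bool = True,
    fit_background: bool = True,
    multistart: int = 1,
    max_nfev: int | None = None,
) -> FitResult:
    """Co-refine one structural model against labelled contrast curves.

    Parameters named in ``free`` (a subset of radius, axial_ratio,
    shell_thickness, coverage, charge) are shared across all curves and
    refined by trust-region least squares on the concatenated weighted
    residuals. The per-contrast intensity scale and flat background
    enter the model linearly, so they are profiled out (variable
    projection): at every trial of the shared parameters the optimal
    (scale, background) of each contrast is solved in closed form.
    ``multistart`` > 1 adds deterministic perturbed starts (geometry
    scaled by a fixed grid) to guard against local minima.

    Raises RuntimeError with diagnostics when the optimizer fails to
    converge from every start.
    """
    if len(curves) < 1:
        raise ValueError("need at least one labelled curve")
    unknown = [lab for lab in curves if lab not in model.scheme.labels()]
    if unknown:
        raise ValueError(f"curve labels {unknown} missing from the contrast scheme")
    bad = [name for name in free if name not in _SHARED_NAMES]
    if bad:
        raise ValueError(f"unknown free parameters: {bad}")

    labels = sorted(curves)
    names: list[str] = list(free)
    x0: list[float] = []
    for name in free:
        if name == "coverage":
            x0.append(model.coverage)
        elif name == "charge":
            x0.append(model.charge)
        else:
            x0.append(getattr(model.geometry, name))
    x0 = np.asarray(x0, dtype=float)
    lo = np.array([_BOUNDS[n][0] for n in names])
    hi = np.array([_BOUNDS[n][1] for n in names])
    x0 = np.clip(x0, lo, hi)

    def build(x: np.ndarray) -> ComplexModel:
        geo_kw = {}
        cov = model.coverage
        charge = model.charge
        for name, val in zip(free, x):
            if name == "coverage":
                cov = float(val)
            elif name == "charge":
                charge = float(val)
            else:
                geo_kw[name] = float(val)
        return replace(
            model,
            geometry=replace(model.geometry, **geo_kw),
            coverage=min(max(cov, 0.0), 1.0),
            charge=charge,
        )

    sigmas = {
        lab: (c.dI if c.dI is not None and np.all(c.dI > 0) else np.ones_like(c.I))
        for lab, c in curves.items()
    }
    smearers = {
        lab: (smear_matrix(c.q, c.dq) if c.dq is not None else None)
        for lab, c in curves.items()
    }

    def profile_linear(a: np.ndarray, y: np.ndarray, sig: np.ndarray):
        """Optimal (scale, background) of I = s*a + b for one contrast."""
        if fit_scale and fit_background:
            M = np.column_stack([a, np.ones_like(a)]) / sig[:, None]
            beta, *_ = np.linalg.lstsq(M, y / sig, rcond=None)
            s, b = float(beta[0]), float(beta[1])
        elif fit_scale:
            b = model.geometry.background
            w = 1.0 / sig**2
            denom = float(np.sum(w * a * a))
            s = float(np.sum(w * a * (y - b)) / denom) if denom > 0 else 1.0
        elif fit_background:
            s = 1.0
            w = 1.0 / sig**2
            b = float(np.sum(w * (y - a)) / np.sum(w))
        else:
            s, b = 1.0, model.geometry.background
        if fit_scale and s <= 0:
            s = 1e-6
        return s, b

    def per_contrast(x: np.ndarray):
        m = build(x)
        out = {}
        for lab in labels:
            c = curves[lab]
            base = m.intensity(lab, c.q)  # scale 1, zero background
            if smearers[lab] is not None:
                base = smearers[lab] @ base
            s, b = profile_linear(base, c.I, sigmas[lab])
            out[lab] = (s, b, s * base + b)
        return m, out

    def residuals(x: np.ndarray) -> np.ndarray:
        _, per = per_contrast(x)
        return np.concatenate(
            [(per[lab][2] - curves[lab].I) / sigmas[lab] for lab in labels]
        )

    # deterministic multi-start grid: perturb the geometric seed
    factors = [1.0, 0.8, 1.25, 0.6, 1.6]
    starts = [x0]
    for f in factors[1 : max(multistart, 1)]:
        xs = x0.copy()
        for i, name in enumerate(free):
            if name in ("radius", "shell_thickness"):
                xs[i] = np.clip(x0[i] * f, lo[i], hi[i])
        starts.append(xs)

    best = None
    last_exc: Exception | None = None
    for xs in starts:
        try:
            sol = least_squares(
                residuals,
                xs,
                bounds=(lo, hi),
                method="trf",
                diff_step=1e-3,
                max_nfev=max_nfev,
            )
        except Exception as exc:  # keep trying other starts
            last_exc = exc
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError(f"co-refinement failed from every start: {last_exc}")
    if not best.success:
        raise RuntimeError(
            "co-refinement did not converge: "
            f"status={best.status}, |grad|={np.max(np.abs(best.grad)):.3e}, "
            f"last x={dict(zip(names, best.x))}"
        )

    # two linear parameters per contrast are profiled out but still count
    n_lin = (int(fit_scale) + int(fit_background)) * len(labels)
    n_data = sum(len(c) for c in curves.values())
    dof = max(n_data - len(names) - n_lin, 1)
    s2 = 2.0 * best.cost / dof
    jac = best.jac
    try:
        cov_mat = np.linalg.inv(jac.T @ jac) * s2
    except np.linalg.LinAlgError:
        cov_mat = np.linalg.pinv(jac.T @ jac) * s2
    err = np.sqrt(np.clip(np.diag(cov_mat), 0.0, None))

    m_fit, per = per_contrast(best.x)
    params = dict(zip(names, map(float, best.x)))
    errors = dict(zip(names, map(float, err)))
    scales = {lab: per[lab][0] for lab in labels}
    bkgs = {lab: per[lab][1] for lab in labels}

    chi2 = {}
    res_all = residuals(best.x)
    off = 0
    for lab in labels:
        n = len(curves[lab])
        r = res_all[off : off + n]
        off += n
        n_par_share = (len(names) + n_lin) / len(labels)
        chi2[lab] = float(r @ r) / max(n - n_par_share, 1)
    chi2_global = float(res_all @ res_all) / dof

    # delta-method propagation to N_agg = v_core / v_SDS
    nagg = m_fit.geometry.core_volume / m_fit.v_sds
    grad = np.zeros(len(names))
    for i, name in enumerate(names):
        if name == "radius":
            grad[i] = 2.0 * nagg / m_fit.geometry.radius
        elif name == "axial_ratio":
            grad[i] = nagg / m_fit.geometry.axial_ratio
    nagg_err = float(math.sqrt(max(grad @ cov_mat @ grad, 0.0)))

    return FitResult(
        params=params,
        errors=errors,
        chi2_red=chi2,
        chi2_red_global=chi2_global,
        nagg=float(nagg),
        nagg_err=nagg_err,
        coverage=m_fit.coverage,
        coverage_err=errors.get("coverage", 0.0),
        charge=m_fit.charge,
        charge_err=errors.get("charge", 0.0),
        model=m_fit,
        scales=scales,
        backgrounds=bkgs,
        nfev=int(best.nfev),
        cost=float(best.cost),
        n_starts=len(starts),
    )


def nagg_from_core(v_core: float, v_sds: float = V_SDS) -> tuple[float, int]:
    """Aggregation number from core and per-surfactant volumes.

    Returns the real-valued ratio and its nearest integer.
    """
    if v_core <= 0 or v_sds <= 0:
        raise ValueError("volumes must be positive")
    ratio = v_core / v_sds
    return ratio, int(round(ratio))


def coverage_from_shell(
    sld_shell: float, sld_protein: float, sld_solvent: float
) -> float:
    """Protein coverage fraction from the fitted shell SLD.

    Inverts the linear two-component mixing rule
    c = (rho_solvent - rho_shell) / (rho_solvent - rho_protein),
    clipping to [0, 1] with a warning when the input lies outside the
    mixing interval.
    """
    denom = sld_solvent - sld_protein
    if denom == 0:
        raise ValueError("degenerate contrast: sld_solvent equals sld_protein")
    c = (sld_solvent - sld_shell) / denom
    if not 0.0 <= c <= 1.0:
        warnings.warn(
            f"shell SLD implies coverage {c:.3f} outside [0, 1]; clipped",
            stacklevel=2,
        )
        c = min(max(c, 0.0), 1.0)
    return c


@dataclass
class ZacCheckResult:
    zac_sld: float
    i0: float
    i_max: float
    q_at_max: float
    has_internal_feature: bool
    q: np.ndarray = field(repr=False, default=None)
    intensity: np.ndarray = field(repr=False, default=None)


def zac_forward_check(
    model: ComplexModel,
    zac_sld: float | None = None,
    q=None,
    label: str = "zac",
) -> ZacCheckResult:
    """Evaluate the model at the zero-average-contrast solvent.

    With the solvent SLD at the volume-weighted mean of the (effective)
    core and shell SLDs, the forward scattering of the complex vanishes
    while internal core/shell segregation still produces intensity at
    finite q. Background is excluded so the cancellation is visible.

    ``zac_sld`` defaults to the ZAC solvent computed from the model's
    own core SLD and effective shell material (protein at coverage c)
    under ``label``'s contrast entry.
    """
    geo = model.geometry
    v_core = geo.core_volume
    v_shell = geo.total_volume - v_core
    if v_core <= 0 or geo.total_volume <= 0:
        raise ValueError("model volumes must be positive")
    entry = model.scheme[label]
    rho_core = entry["sld_surfactant"]
    rho_protein = entry["sld_protein"]
    if zac_sld is None:
        # shell material is protein occupying `coverage` of the shell volume
        zac_sld = zac_solvent(
            rho_core, v_core, rho_protein, model.coverage * v_shell
        )
    rho_shell = model.coverage * rho_protein + (1.0 - model.coverage) * zac_sld
    geo_zac = replace(
        geo,
        sld_core=rho_core,
        sld_shell=rho_shell,
        sld_solvent=zac_sld,
        background=0.0,
    )
    if q is None:
        d = geo.equivalent_sphere_diameter
        q = np.linspace(1e-5, 12.0 / d * math.pi, 400)
    q = np.asarray(q, dtype=float)
    i_q = form_factor_intensity(geo_zac, q)
    i0 = float(i_q[0])
    imax = float(np.max(i_q))
    qmax = float(q[int(np.argmax(i_q))])
    return ZacCheckResult(
        zac_sld=float(zac_sld),
        i0=i0,
        i_max=imax,
        q_at_max=qmax,
        has_internal_feature=imax > max(1e6 * abs(i0), 1e-12),
        q=q,
        intensity=i_q,
    )
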