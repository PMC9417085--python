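"""Benchtop titration analytics: fluorescence, pyrene probe, CD and ITC.

These are the lab-scale observables used to locate the interaction
stages of a surfactant-protein system before committing beamtime:

* tryptophan emission — the spectral centre of mass (CM) red-shifts as
  the protein core becomes solvent exposed;
* pyrene I3/I1 — the vibronic band ratio of the polarity probe jumps
  when micelle-like aggregates appear (CMC in buffer, CAC with protein);
* circular dichroism — the 220/209 nm mean-residue-ellipticity ratio
  tracks secondary structure, the 292 nm band tertiary structure;
* isothermal titration calorimetry — the surfactant concentration at
  which each enthalpogram transition occurs, measured at several
  protein concentrations, decomposes into bound and free surfactant via

      [SDS] = [SDS]_unbound + N_agg [protein].

Units: protein concentrations in uM, surfactant in mM throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EmissionSpectrum",
    "CDSpectrum",
    "Enthalpogram",
    "TransitionFit",
    "BreakpointResult",
    "center_of_mass",
    "pyrene_ratio",
    "breakpoint_intersection",
    "cac_ratio",
    "itc_transition_fit",
    "predict_total_sds",
    "detect_transitions",
    "mean_residue_ellipticity",
    "ellipticity_descriptors",
    "conc_from_a280",
]


@dataclass
class EmissionSpectrum:
    """Fluorescence emission spectrum (wavelength nm, intensity a.u.)."""

    wavelength: np.ndarray
    intensity: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelength = np.asarray(self.wavelength, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.wavelength.shape != self.intensity.shape:
            raise ValueError("wavelength and intensity must have equal length")
        if np.any(np.diff(self.wavelength) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")


@dataclass
class CDSpectrum:
    """CD spectrum in mean residue ellipticity units (deg cm^2 dmol^-1)."""

    wavelength: np.ndarray
    theta_mr: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelength = np.asarray(self.wavelength, dtype=float)
        self.theta_mr = np.asarray(self.theta_mr, dtype=float)
        if self.wavelength.shape != self.theta_mr.shape:
            raise ValueError("wavelength and theta must have equal length")
        if np.any(np.diff(self.wavelength) <= 0):
            raise ValueError("wavelengths must be strictly increasing")


@dataclass
class Enthalpogram:
    """Integrated ITC titration: molar heat vs titrant concentration.

    ``sds_mm``: cumulative, dilution-corrected SDS concentration in the
    cell after each injection (mM, strictly increasing); ``heat``:
    molar heat per injection (kcal per mol of injectant);
    ``protein_um``: cell protein concentration (uM).
    """

    sds_mm: np.ndarray
    heat: np.ndarray
    protein_um: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sds_mm = np.asarray(self.sds_mm, dtype=float)
        self.heat = np.asarray(self.heat, dtype=float)
        if self.sds_mm.shape != self.heat.shape:
            raise ValueError("concentration and heat must have equal length")
        if np.any(np.diff(self.sds_mm) <= 0):
            raise ValueError("cumulative concentration must be strictly increasing")


@dataclass(frozen=True)
class TransitionFit:
    """Binding decomposition of one enthalpogram transition.

    slope of [SDS] vs [protein] -> N_agg (bound surfactant per protein),
    intercept -> [SDS]_unbound in mM.
    """

    nagg: float
    nagg_err: float
    sds_unbound_mm: float
    sds_unbound_err: float
    label: str = ""
    n_points: int = 0


@dataclass(frozen=True)
class BreakpointResult:
    breakpoint: float
    breakpoint_err: float
    slope_pre: float
    slope_post: float
    intercept_pre: float
    intercept_post: float
    has_breakpoint: bool
    split_index: int


def center_of_mass(
    spectrum: EmissionSpectrum, window: tuple[float, float] = (310.0, 450.0)
) -> float:
    """Intensity-weighted spectral centre of mass over a window, nm."""
    lo, hi = window
    wl, inten = spectrum.wavelength, spectrum.intensity
    if lo < wl[0] or hi > wl[-1]:
        raise ValueError("window outside the measured wavelength range")
    sel = (wl >= lo) & (wl <= hi)
    tot = float(np.sum(inten[sel]))
    if tot <= 0:
        raise ValueError("zero total intensity in the window")
    return float(np.sum(wl[sel] * inten[sel]) / tot)


def pyrene_ratio(
    spectrum: EmissionSpectrum,
    band1: float = 373.0,
    band3: float = 384.0,
    search_nm: float = 3.0,
) -> float:
    """Pyrene I3/I1 vibronic band ratio.

    Each band intensity is the maximum within +/- ``search_nm`` of the
    nominal band centre (373 nm for I1, 384 nm for I3).
    """
    wl, inten = spectrum.wavelength, spectrum.intensity

    def band_max(center: float) -> float:
        sel = (wl >= center - search_nm) & (wl <= center + search_nm)
        if not np.any(sel):
            raise ValueError(f"spectrum does not cover the {center:g} nm band")
        return float(np.max(inten[sel]))

    i1 = band_max(band1)
    i3 = band_max(band3)
    if i1 <= 0:
        raise ValueError("I1 band has no intensity")
    return i3 / i1


def _wfit(x: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Weighted straight-line fit; returns (slope, intercept, cov)."""
    A = np.column_stack([x, np.ones_like(x)])
    Aw = A * np.sqrt(w)[:, None]
    cov = np.linalg.inv(Aw.T @ Aw)
    beta = cov @ (Aw.T @ (y * np.sqrt(w)))
    return float(beta[0]), float(beta[1]), cov


def breakpoint_intersection(x, y, dy=None, min_seg: int = 3) -> BreakpointResult:
    """Two-segment linear fit; the segments' intersection is the breakpoint.

    The split point is chosen by grid search over interior positions
    minimizing the total weighted residual; the reported breakpoint is
    the intersection abscissa of the two fitted lines with first-order
    propagated error. Data that a single line explains essentially as
    well (within 5% residual improvement) or whose fitted slopes are
    indistinguishable are flagged ``has_breakpoint=False``; the best
    split is still reported.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 6:
        raise ValueError("need at least 6 points for a breakpoint fit")
    order = np.argsort(x)
    x, y = x[order], y[order]
    if dy is None:
        w = np.ones(n)
    else:
        dy = np.asarray(dy, dtype=float)[order]
        w = 1.0 / np.where(dy > 0, dy, np.min(dy[dy > 0]) if np.any(dy > 0) else 1.0) ** 2

    _, _, _ = _wfit(x, y, w)  # raises on degenerate x
    res1 = _segment_rss(x, y, w)

    best = None
    for k in range(min_seg, n - min_seg + 1):
        rss = _segment_rss(x[:k], y[:k], w[:k]) + _segment_rss(x[k:], y[k:], w[k:])
        if best is None or rss < best[0]:
            best = (rss, k)
    rss2, k = best
    m1, b1, c1 = _wfit(x[:k], y[:k], w[:k])
    m2, b2, c2 = _wfit(x[k:], y[k:], w[k:])

    dm = m1 - m2
    has_break = rss2 < 0.95 * res1 and abs(dm) > 1e-12
    if abs(dm) < 1e-12:
        xb, xb_err = math.nan, math.nan
    else:
        xb = (b2 - b1) / dm
        # scale segment covariances by their reduced chi^2 for honest errors
        c1s = c1 * _chi2_scale(x[:k], y[:k], w[:k], m1, b1)
        c2s = c2 * _chi2_scale(x[k:], y[k:], w[k:], m2, b2)
        # xb = (b2-b1)/(m1-m2): gradient wrt (m1,b1,m2,b2)
        g = np.array([-xb / dm, -1.0 / dm, xb / dm, 1.0 / dm])
        big = np.zeros((4, 4))
        big[:2, :2] = c1s
        big[2:, 2:] = c2s
        xb_err = float(math.sqrt(max(g @ big @ g, 0.0)))
        if not x[0] <= xb <= x[-1]:
            has_break = False
    return BreakpointResult(
        breakpoint=float(xb),
        breakpoint_err=xb_err,
        slope_pre=m1,
        slope_post=m2,
        intercept_pre=b1,
        intercept_post=b2,
        has_breakpoint=bool(has_break),
        split_index=int(k),
    )


def _segment_rss(x, y, w) -> float:
    if len(np.unique(x)) < 2:
        return math.inf
    m, b, _ = _wfit(x, y, w)
    r = (y - m * x - b) * np.sqrt(w)
    return float(r @ r)


def _chi2_scale(x, y, w, m, b) -> float:
    dof = max(len(x) - 2, 1)
    r = (y - m * x - b) * np.sqrt(w)
    return max(float(r @ r) / dof, 1e-30)


def cac_ratio(cac_mm: float, protein_um: float) -> float:
    """Surfactant-to-protein molar ratio at an aggregation concentration.

    cac in mM, protein in uM; the ratio is dimensionless.
    """
    if protein_um <= 0:
        raise ValueError("protein concentration must be positive")
    return cac_mm * 1000.0 / protein_um


def itc_transition_fit(points, weights=None, label: str = "") -> TransitionFit:
    """Binding decomposition from transition concentrations.

    ``points``: iterable of ([protein] uM, [SDS] at transition mM)
    pairs across protein concentrations. Weighted linear regression of
    [SDS] on [protein] gives N_agg (slope, dimensionless after unit
    harmonisation) and [SDS]_unbound (intercept, mM).

    With ``weights=None`` the parameter errors are scaled by the
    reduced chi^2 of the fit (zero for exactly collinear input). When
    weights are supplied they are taken as inverse variances of the
    transition concentrations and the errors use the formal covariance,
    inflated by the reduced chi^2 when that exceeds one.
    """
    pts = [tuple(p) for p in points]
    prot_mm = np.array([p[0] for p in pts], dtype=float) / 1000.0  # uM -> mM
    sds = np.array([p[1] for p in pts], dtype=float)
    if len(np.unique(prot_mm)) < 2:
        raise ValueError("need at least two distinct protein concentrations")
    w = np.ones_like(sds) if weights is None else np.asarray(weights, dtype=float)
    m, b, cov = _wfit(prot_mm, sds, w)
    dof = max(len(pts) - 2, 1)
    r = (sds - m * prot_mm - b) * np.sqrt(w)
    s2 = float(r @ r) / dof
    if weights is not None:
        s2 = max(s2, 1.0)
    return TransitionFit(
        nagg=m,
        nagg_err=float(math.sqrt(cov[0, 0] * s2)),
        sds_unbound_mm=b,
        sds_unbound_err=float(math.sqrt(cov[1, 1] * s2)),
        label=label,
        n_points=len(pts),
    )


def predict_total_sds(fit: TransitionFit, protein_um: float) -> tuple[float, float]:
    """Total SDS (mM) and SDS/protein ratio at a protein concentration.

    total = [SDS]_unbound + N_agg [protein]; the ratio is total SDS per
    protein molecule (NaN at zero protein).
    """
    if protein_um < 0:
        raise ValueError("protein concentration must be non-negative")
    total = fit.sds_unbound_mm + fit.nagg * protein_um / 1000.0
    ratio = math.nan if protein_um == 0 else total * 1000.0 / protein_um
    return total, ratio


@dataclass(frozen=True)
class TransitionDetection:
    """Proposed enthalpogram transitions with per-boundary uncertainties."""

    boundaries: list[float]
    errors: list[float]
    complete: bool
    n_segments: int

    def __iter__(self):
        # (boundaries, complete) unpacking for quick interactive use
        return iter((self.boundaries, self.complete))


def detect_transitions(
    enthalpogram: Enthalpogram,
    n_max: int = 6,
    penalty: float | None = None,
    min_seg: int = 3,
) -> TransitionDetection:
    """Segment an enthalpogram into linear stages; boundaries = transitions.

    Dynamic programming over split points of a piecewise-linear model
    of molar heat vs cumulative surfactant concentration, penalized per
    extra segment (the penalty defaults to a BIC-like cost scaled by
    the noise variance estimated from second differences). Boundaries
    are refined to the intersections of adjacent fitted segment lines,
    with first-order propagated uncertainties. ``complete`` is False
    when fewer boundaries than ``n_max - 1`` were found.

    The segmentation is a proposal: transition identification remains
    semi-automatic and boundaries may be pinned manually downstream.
    """
    x, y = enthalpogram.sds_mm, enthalpogram.heat
    n = x.size
    if n < 15:
        raise ValueError("need at least 15 injections to segment")
    w = np.ones(n)

    # cost[i][j] = RSS of one line on points i..j-1
    cost = np.full((n + 1, n + 1), np.inf)
    for i in range(n):
        for j in range(i + min_seg, n + 1):
            cost[i, j] = _segment_rss(x[i:j], y[i:j], w[i:j])
    if penalty is None:
        # noise variance from second differences (insensitive to the
        # piecewise-linear trend); BIC-like cost per extra segment
        d2 = np.diff(y, 2)
        sigma2 = float(np.median(d2**2)) / 6.0 if d2.size else 0.0
        penalty = 3.0 * max(sigma2, 1e-12) * math.log(n)

    # dp over number of segments
    best_cost = {0: np.full(n + 1, np.inf)}
    best_cost[0][0] = 0.0
    back: dict[tuple[int, int], int] = {}
    for seg in range(1, n_max + 1):
        prev = best_cost[seg - 1]
        cur = np.full(n + 1, np.inf)
        for j in range(min_seg, n + 1):
            cands = prev[: j - min_seg + 1] + cost[: j - min_seg + 1, j]
            i = int(np.argmin(cands))
            if np.isfinite(cands[i]):
                cur[j] = cands[i]
                back[(seg, j)] = i
        best_cost[seg] = cur

    totals = {
        seg: best_cost[seg][n] + penalty * (seg - 1)
        for seg in range(1, n_max + 1)
        if np.isfinite(best_cost[seg][n])
    }
    n_seg = min(totals, key=totals.get)
    bounds_idx: list[int] = []
    j = n
    for seg in range(n_seg, 0, -1):
        i = back[(seg, j)]
        if i > 0:
            bounds_idx.append(i)
        j = i
    bounds_idx.reverse()

    # refine each boundary to the intersection of the two fitted
    # segment lines (exact for piecewise-linear data, independent of
    # the injection grid); fall back to the flanking-injection midpoint
    edges = [0] + bounds_idx + [n]
    lines = []
    for a, b in zip(edges[:-1], edges[1:]):
        m, c, cov = _wfit(x[a:b], y[a:b], w[a:b])
        cov = cov * _chi2_scale(x[a:b], y[a:b], w[a:b], m, c)
        lines.append((m, c, cov))
    boundaries: list[float] = []
    errors: list[float] = []
    half_step = float(np.median(np.diff(x))) / 2.0
    for t, i in enumerate(bounds_idx):
        (m1, c1, s1), (m2, c2, s2) = lines[t], lines[t + 1]
        mid = float(0.5 * (x[i - 1] + x[i]))
        dm = m1 - m2
        if abs(dm) > 1e-12:
            xb = (c2 - c1) / dm
            g = np.array([-xb / dm, -1.0 / dm, xb / dm, 1.0 / dm])
            big = np.zeros((4, 4))
            big[:2, :2] = s1
            big[2:, 2:] = s2
            err = float(math.sqrt(max(g @ big @ g, 0.0)))
            lo = x[max(i - 2, 0)]
            hi = x[min(i + 1, n - 1)]
            if lo <= xb <= hi:
                boundaries.append(float(xb))
                errors.append(err)
            else:
                boundaries.append(mid)
                errors.append(half_step)
        else:
            boundaries.append(mid)
            errors.append(half_step)
    complete = len(boundaries) >= n_max - 1
    return TransitionDetection(boundaries, errors, complete, n_seg)


def mean_residue_ellipticity(
    theta_mdeg, mrw: float, path_cm: float, conc_g_per_l: float
):
    """Convert observed ellipticity (mdeg) to theta_MR (deg cm^2 dmol^-1).

    theta_MR = theta_mdeg * MRW / (10 * path * concentration) with the
    mean residue weight MRW in Da, path in cm and concentration in g/L.
    """
    if mrw <= 0 or path_cm <= 0 or conc_g_per_l <= 0:
        raise ValueError("conversion inputs must be positive")
    return np.asarray(theta_mdeg, dtype=float) * mrw / (10.0 * path_cm * conc_g_per_l)


def ellipticity_descriptors(
    spectrum: CDSpectrum,
    far_pair: tuple[float, float] = (220.0, 209.0),
    near_band: float = 292.0,
) -> dict[str, float]:
    """Secondary/tertiary structure descriptors of one CD spectrum.

    Returns theta at 209, 220 and 292 nm (linear interpolation), the
    ratio theta220/theta209, and the parametric tuples used for
    denaturation-trajectory plots.
    """
    wl, th = spectrum.wavelength, spectrum.theta_mr
    needed = [far_pair[0], far_pair[1], near_band]
    for lam in needed:
        if lam < wl[0] or lam > wl[-1]:
            raise ValueError(f"{lam:g} nm outside the measured range")
    t220 = float(np.interp(far_pair[0], wl, th))
    t209 = float(np.interp(far_pair[1], wl, th))
    t292 = float(np.interp(near_band, wl, th))
    if t209 == 0:
        raise ValueError("theta at 209 nm is zero; ratio undefined")
    return {
        "theta220": t220,
        "theta209": t209,
        "theta292": t292,
        "ratio_220_209": t220 / t209,
        "parametric_far": (t220, t209),
        "parametric_near": (t292, t209),
    }


def conc_from_a280(
    absorbance: float, extinction: float, path_cm: float, mw: float
) -> tuple[float, float]:
    """Protein concentration from A280 by Beer-Lambert.

    Returns (molar concentration in M, mass concentration in g/L) given
    the molar extinction coefficient (M^-1 cm^-1), path length (cm) and
    molecular weight (Da).
    """
    if extinction <= 0 or path_cm <= 0 or mw <= 0:
        raise ValueError("extinction, path and molecular weight must be positive")
    if absorbance < 0:
        raise ValueError("absorbance must be non-negative")
    molar = absorbance / (extinction * path_cm)
    return molar, molar * mw
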