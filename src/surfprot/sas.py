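"""Small-angle scattering curves, analytic form factors and curve utilities.

Absolute-scale convention
-------------------------
Model intensities are returned in cm^-1 using

    I(q) = 1e8 * phi * <|F(q, theta)|^2> / V_particle + background

where ``F`` is the orientation-dependent scattering amplitude in A
(contrast [A^-2] x volume [A^3]), ``<.>`` the orientational average by
Gauss-Legendre quadrature over cos(theta), ``V_particle`` the total
particle volume in A^3 and ``phi`` the particle volume fraction. The
factor 1e8 converts A^-1 to cm^-1.

Resolution smearing follows the reduced-data convention in which the
optional ``dq`` column holds the 1-sigma width of a Gaussian resolution
kernel at each q point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ScatteringCurve",
    "GeometryParams",
    "read_sans",
    "write_sans",
    "form_factor_intensity",
    "form_factor_amplitude_sq",
    "guinier_fit",
    "GuinierResult",
    "gaussian_smear",
    "smear_matrix",
    "integrated_intensity",
]


@dataclass
class ScatteringCurve:
    """One reduced SANS dataset.

    q in A^-1 (strictly increasing, positive), I and dI in cm^-1,
    optional dq column = 1-sigma Gaussian resolution width in A^-1.
    """

    q: np.ndarray
    I: np.ndarray
    dI: np.ndarray | None = None
    dq: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        if self.q.ndim != 1 or self.q.size < 2:
            raise ValueError("q must be a 1-D array with at least 2 points")
        if self.I.shape != self.q.shape:
            raise ValueError("I and q must have equal length")
        if np.any(self.q <= 0):
            raise ValueError("q values must be positive")
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be strictly increasing")
        if self.dI is not None:
            self.dI = np.asarray(self.dI, dtype=float)
            if self.dI.shape != self.q.shape:
                raise ValueError("dI and q must have equal length")
            if np.any(self.dI < 0):
                raise ValueError("dI must be non-negative")
        if self.dq is not None:
            self.dq = np.asarray(self.dq, dtype=float)
            if self.dq.shape != self.q.shape:
                raise ValueError("dq and q must have equal length")
            if np.any(self.dq < 0):
                raise ValueError("dq must be non-negative")

    def __len__(self) -> int:
        return self.q.size

    def with_intensity(self, I, dI=None) -> "ScatteringCurve":
        return replace(self, I=np.asarray(I, dtype=float), dI=dI)


def read_sans(path) -> ScatteringCurve:
    """Read an ASCII SANS file: '#' comments, 3-4 whitespace columns.

    Columns are q [A^-1], I [cm^-1], dI [cm^-1] and optionally dq
    [A^-1]. Header comments of the form ``# key: value`` are collected
    into metadata.
    """
    meta: dict = {"source": str(path)}
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, val = body.partition(":")
                    meta[key.strip()] = val.strip()
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{lineno}: expected at least 3 columns, got {len(parts)}"
                )
            try:
                rows.append([float(p) for p in parts[:4]])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-numeric data") from None
    if not rows:
        raise ValueError(f"{path}: no data rows")
    ncol = min(len(r) for r in rows)
    arr = np.array([r[:ncol] for r in rows], dtype=float)
    dq = arr[:, 3] if ncol >= 4 else None
    if np.any(np.diff(arr[:, 0]) <= 0):
        bad = int(np.argmax(np.diff(arr[:, 0]) <= 0)) + 2
        raise ValueError(f"{path}: q not strictly increasing at data row {bad}")
    return ScatteringCurve(arr[:, 0], arr[:, 1], arr[:, 2], dq, metadata=meta)


def write_sans(path, curve: ScatteringCurve) -> None:
    """Write a curve in the ASCII format accepted by :func:`read_sans`."""
    with open(path, "w") as fh:
        fh.write("# columns: q[1/A] I[1/cm] dI[1/cm]")
        if curve.dq is not None:
            fh.write(" dq[1/A]")
        fh.write("\n")
        for key, val in curve.metadata.items():
            if key == "source":
                continue
            fh.write(f"# {key}: {val}\n")
        dI = curve.dI if curve.dI is not None else np.zeros_like(curve.q)
        for i in range(len(curve)):
            fh.write(f"{curve.q[i]:.8e} {curve.I[i]:.8e} {dI[i]:.8e}")
            if curve.dq is not None:
                fh.write(f" {curve.dq[i]:.8e}")
            fh.write("\n")


@dataclass
class GeometryParams:
    """Geometry + contrast of a monodisperse scatterer.

    kind: 'sphere' | 'ellipsoid' | 'core_shell_ellipsoid'.
    ``radius`` is the core equatorial radius (sphere radius for kind
    'sphere'); ``axial_ratio`` the polar/equatorial core ratio; the
    shell thickness (equal on polar and equatorial axes by default)
    applies to the core-shell kind only.
    """

    kind: str = "sphere"
    radius: float = 30.0
    axial_ratio: float = 1.0
    shell_thickness: float = 0.0
    sld_core: float = 1e-6
    sld_shell: float = 1e-6
    sld_solvent: float = 0.0
    volume_fraction: float = 0.01
    background: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("sphere", "ellipsoid", "core_shell_ellipsoid"):
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.radius < 0 or self.shell_thickness < 0:
            raise ValueError("radii and thickness must be >= 0")
        if self.axial_ratio <= 0:
            raise ValueError("axial_ratio must be positive")
        if not 0 < self.volume_fraction < 1:
            raise ValueError("volume fraction must be in (0, 1)")

    @property
    def core_volume(self) -> float:
        """Core volume (total volume for uniform kinds), A^3."""
        a = self.radius
        c = self.axial_ratio * self.radius
        return 4.0 / 3.0 * math.pi * a * a * c

    @property
    def total_volume(self) -> float:
        """Outer particle volume, A^3."""
        if self.kind != "core_shell_ellipsoid":
            return self.core_volume
        a = self.radius + self.shell_thickness
        c = self.axial_ratio * self.radius + self.shell_thickness
        return 4.0 / 3.0 * math.pi * a * a * c

    @property
    def equivalent_sphere_diameter(self) -> float:
        """Diameter of the equal-volume sphere, A."""
        return 2.0 * (self.total_volume / (4.0 / 3.0 * math.pi)) ** (1.0 / 3.0)


def _sphere_shape(x: np.ndarray) -> np.ndarray:
    """Normalized sphere amplitude 3[sin x - x cos x]/x^3, -> 1 as x -> 0."""
    x = np.asarray(x, dtype=float)
    out = np.ones_like(x)
    small = np.abs(x) < 1e-4
    xs = x[~small]
    out[~small] = 3.0 * (np.sin(xs) - xs * np.cos(xs)) / xs**3
    xs2 = x[small] ** 2
    out[small] = 1.0 - xs2 / 10.0 + xs2**2 / 280.0
    return out


def form_factor_amplitude_sq(
    params: GeometryParams, q: np.ndarray, n_quad: int = 76
) -> np.ndarray:
    """Orientationally averaged squared amplitude <|F(q)|^2>, A^2.

    F has units of contrast x volume; the average is over particle
    orientation via Gauss-Legendre quadrature in cos(theta).
    """
    q = np.asarray(q, dtype=float)
    if params.total_volume <= 0:
        raise ValueError("particle volume must be positive")

    if params.kind == "sphere":
        drho = params.sld_core - params.sld_solvent
        v = params.core_volume
        amp = drho * v * _sphere_shape(q * params.radius)
        return amp**2

    # ellipsoidal kinds: average over u = cos(theta) in [0, 1]
    nodes, weights = np.polynomial.legendre.leggauss(n_quad)
    u = 0.5 * (nodes + 1.0)  # map [-1,1] -> [0,1]
    w = 0.5 * weights

    a_c = params.radius
    c_c = params.axial_ratio * params.radius
    r_core = np.sqrt(a_c**2 * (1.0 - u**2) + c_c**2 * u**2)

    if params.kind == "ellipsoid":
        drho = params.sld_core - params.sld_solvent
        v = params.core_volume
        amp = drho * v * _sphere_shape(np.outer(q, r_core))
        return (amp**2) @ w

    # core-shell ellipsoid, equal shell thickness on both axes
    a_t = a_c + params.shell_thickness
    c_t = c_c + params.shell_thickness
    r_tot = np.sqrt(a_t**2 * (1.0 - u**2) + c_t**2 * u**2)
    v_core = params.core_volume
    v_tot = params.total_volume
    amp = (params.sld_core - params.sld_shell) * v_core * _sphere_shape(
        np.outer(q, r_core)
    ) + (params.sld_shell - params.sld_solvent) * v_tot * _sphere_shape(
        np.outer(q, r_tot)
    )
    return (amp**2) @ w


def form_factor_intensity(
    params: GeometryParams, q: np.ndarray, n_quad: int = 76
) -> np.ndarray:
    """Absolute-scale model intensity I(q) in cm^-1 (see module docstring)."""
    f2 = form_factor_amplitude_sq(params, q, n_quad=n_quad)
    return 1e8 * params.volume_fraction * f2 / params.total_volume + params.background


@dataclass(frozen=True)
class GuinierResult:
    rg: float
    rg_err: float
    i0: float
    i0_err: float
    q_window: tuple[float, float]
    n_points: int
    qrg_max: float


def guinier_fit(
    curve: ScatteringCurve,
    qrg_max: float = 1.3,
    min_points: int = 5,
    max_iter: int = 50,
) -> GuinierResult:
    """Guinier analysis: weighted fit of ln I vs q^2 at low q.

    ln I(q) = ln I(0) - q^2 Rg^2 / 3 for q*Rg below ``qrg_max``. The
    fit window is iterated until the Rg estimate is self-consistent
    with the window (stable to 1%).
    """
    q, I = curve.q, curve.I
    pos = I > 0
    if pos.sum() < min_points:
        raise ValueError("not enough positive intensities for a Guinier fit")
    q, I = q[pos], I[pos]
    dI = curve.dI[pos] if curve.dI is not None else None

    n_sel = len(q)
    rg_prev = None
    for _ in range(max_iter):
        qs, Is = q[:n_sel], I[:n_sel]
        y = np.log(Is)
        x = qs**2
        if dI is not None and np.all(dI[:n_sel] > 0):
            w = (Is / dI[:n_sel]) ** 2  # d(ln I) = dI / I
        else:
            w = np.ones_like(x)
        A = np.column_stack([x, np.ones_like(x)])
        Aw = A * np.sqrt(w)[:, None]
        cov = np.linalg.inv(Aw.T @ Aw)
        slope, icpt = cov @ (Aw.T @ (y * np.sqrt(w)))
        if slope > 0:
            # numerically flat data clamps to zero slope; a genuinely
            # rising low-q curve has no Guinier regime
            if slope * x.max() > 1e-8 * (abs(icpt) + 1.0):
                raise ValueError("no Guinier regime: positive low-q slope")
            slope = 0.0
        rg = math.sqrt(-3.0 * slope)
        if rg == 0.0:
            break
        n_new = int(np.searchsorted(q * rg, qrg_max, side="right"))
        n_new = max(n_new, min_points)
        n_new = min(n_new, len(q))
        if rg_prev is not None and abs(rg - rg_prev) <= 0.01 * rg and n_new == n_sel:
            break
        if n_new == n_sel:
            break
        rg_prev = rg
        n_sel = n_new
    if n_sel < min_points:
        raise ValueError("fewer than the minimum number of points in Guinier window")

    # scale covariance by reduced chi^2 for honest errors on noisy data
    resid = (y - A @ np.array([slope, icpt])) * np.sqrt(w)
    dof = max(len(y) - 2, 1)
    s2 = float(resid @ resid) / dof
    cov_s = cov * max(s2, 1e-30)
    # d(rg)/d(slope) = -3/(2 rg)
    rg_err = 0.0 if slope == 0 else (3.0 / (2.0 * rg)) * math.sqrt(cov_s[0, 0])
    i0 = math.exp(icpt)
    i0_err = i0 * math.sqrt(cov_s[1, 1])
    return GuinierResult(
        rg=rg,
        rg_err=rg_err,
        i0=i0,
        i0_err=i0_err,
        q_window=(float(q[0]), float(q[n_sel - 1])),
        n_points=n_sel,
        qrg_max=qrg_max,
    )


def smear_matrix(
    q: np.ndarray, dq: np.ndarray, n_sigma: float = 3.0, n_nodes: int = 25
) -> np.ndarray:
    """Resolution-smearing matrix W so that I_smeared = W @ I(q).

    Each row holds Gaussian weights (sigma = dq_i) over the q grid,
    evaluated on ``n_nodes`` equally spaced quadrature nodes within
    +/- n_sigma, mapped back to grid values by linear interpolation;
    nodes outside the grid support are truncated and the remaining
    weights renormalized. Rows with dq = 0 are identity rows.
    """
    q = np.asarray(q, dtype=float)
    dq = np.asarray(dq, dtype=float)
    n = q.size
    W = np.zeros((n, n))
    for i in range(n):
        s = dq[i]
        if s <= 0:
            W[i, i] = 1.0
            continue
        nodes = np.linspace(q[i] - n_sigma * s, q[i] + n_sigma * s, n_nodes)
        wts = np.exp(-0.5 * ((nodes - q[i]) / s) ** 2)
        keep = (nodes >= q[0]) & (nodes <= q[-1])
        nodes, wts = nodes[keep], wts[keep]
        if nodes.size == 0:
            W[i, i] = 1.0
            continue
        wts = wts / wts.sum()
        # distribute each node's weight onto its bracketing grid points
        idx = np.clip(np.searchsorted(q, nodes) - 1, 0, n - 2)
        frac = (nodes - q[idx]) / (q[idx + 1] - q[idx])
        np.add.at(W[i], idx, wts * (1.0 - frac))
        np.add.at(W[i], idx + 1, wts * frac)
    return W


def gaussian_smear(curve: ScatteringCurve, dq: np.ndarray | None = None) -> ScatteringCurve:
    """Smear a curve with its Gaussian resolution column.

    Uses ``curve.dq`` unless an explicit ``dq`` array is given; rows
    with dq = 0 are returned unchanged.
    """
    sig = curve.dq if dq is None else np.asarray(dq, dtype=float)
    if sig is None:
        return curve
    W = smear_matrix(curve.q, sig)
    out = replace(curve, I=W @ curve.I)
    if out.dq is None:
        out.dq = sig
    return out


def integrated_intensity(curve: ScatteringCurve, qmin: float, qmax: float) -> float:
    """Trapezoidal integral of I(q) over [qmin, qmax], cm^-1 A^-1."""
    if qmax <= qmin:
        raise ValueError("empty integration window")
    if qmin < curve.q[0] - 1e-12 or qmax > curve.q[-1] + 1e-12:
        raise ValueError("integration window outside curve support")
    grid = np.unique(np.concatenate([[qmin, qmax], curve.q[(curve.q > qmin) & (curve.q < qmax)]]))
    vals = np.interp(grid, curve.q, curve.I)
    return float(np.trapezoid(vals, grid))
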