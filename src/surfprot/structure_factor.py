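"""Structure factors for charged spheroidal colloids.

Two routes are provided:

* :func:`py_hardsphere_sq` — the analytic Percus-Yevick structure
  factor of hard spheres, used as the zero-charge oracle.
* :func:`rmsa_sq` — the mean spherical approximation (MSA) for the
  hard-core screened-Coulomb (Yukawa) potential, with the Hansen-Hayter
  rescaling applied whenever the MSA contact value of g(r) is negative
  (the rescaled MSA, RMSA). The Ornstein-Zernike equation with the MSA
  closure is solved numerically by Fourier (sine-transform) Picard
  iteration on a fine radial grid; at Z = 0 this reduces to the PY
  hard-sphere solution and is validated against the analytic oracle.

The interaction model is the effective one-component macroion fluid:
spheres of effective diameter sigma_eff carrying net charge Z in a
dielectric continuum with monovalent salt. The inverse Debye length
includes the counterions released by the macroions themselves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.fft import dst

from .constants import E_CHARGE, EPS0, K_B, N_A

__all__ = [
    "ColloidParams",
    "MSAConvergenceError",
    "py_hardsphere_sq",
    "rmsa_sq",
    "combine_ps",
    "bjerrum_length",
    "debye_kappa",
]


class MSAConvergenceError(RuntimeError):
    """The MSA solve failed to converge to a physical solution.

    At strong coupling the unrescaled MSA has no physical solution;
    :func:`rmsa_sq` interprets this as a negative contact value and
    proceeds with the Hansen-Hayter rescaling.
    """


@dataclass
class ColloidParams:
    """Parameters of the effective one-component macroion model.

    volume_fraction: hard-core packing fraction (0 < phi < 0.74)
    sigma_eff:       effective hard-sphere diameter, A
    charge:          net charge Z in elementary charges (sign ignored)
    temperature:     K
    dielectric:      relative solvent permittivity
    salt_molar:      monovalent 1:1 salt concentration, mol/L
    """

    volume_fraction: float
    sigma_eff: float
    charge: float = 0.0
    temperature: float = 298.15
    dielectric: float = 78.3
    salt_molar: float = 0.010

    def __post_init__(self) -> None:
        if not 0 < self.volume_fraction < 0.74:
            raise ValueError("volume fraction must be in (0, 0.74)")
        if self.sigma_eff <= 0:
            raise ValueError("sigma_eff must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def number_density(self) -> float:
        """Macroion number density, A^-3."""
        v = math.pi / 6.0 * self.sigma_eff**3
        return self.volume_fraction / v


def bjerrum_length(temperature: float = 298.15, dielectric: float = 78.3) -> float:
    """Bjerrum length e^2/(4 pi eps0 eps kT), in A."""
    lb_m = E_CHARGE**2 / (4.0 * math.pi * EPS0 * dielectric * K_B * temperature)
    return lb_m * 1e10


def debye_kappa(params: ColloidParams) -> float:
    """Inverse Debye screening length kappa, A^-1.

    kappa^2 = 4 pi lB * (2 n_salt + |Z| n_macroion): monovalent salt
    plus the counterions released by the macroions.
    """
    lb = bjerrum_length(params.temperature, params.dielectric)
    n_salt = params.salt_molar * N_A / 1e27  # per A^3
    n_counter = abs(params.charge) * params.number_density
    return math.sqrt(4.0 * math.pi * lb * (2.0 * n_salt + n_counter))


def py_hardsphere_sq(q, volume_fraction: float, sigma_eff: float) -> np.ndarray:
    """Analytic Percus-Yevick hard-sphere structure factor.

    Closed form via the PY direct correlation function; S(0) equals
    (1-phi)^4 / (1+2 phi)^2.
    """
    phi = volume_fraction
    if not 0 <= phi < 0.74:
        raise ValueError("volume fraction must be in [0, 0.74)")
    q = np.asarray(q, dtype=float)
    if phi == 0:
        return np.ones_like(q)
    x = q * sigma_eff
    alpha = (1.0 + 2.0 * phi) ** 2 / (1.0 - phi) ** 4
    beta = -6.0 * phi * (1.0 + phi / 2.0) ** 2 / (1.0 - phi) ** 4
    gamma = phi * alpha / 2.0

    out = np.empty_like(x)
    small = x < 1e-3
    xs = x[~small]
    sx, cx = np.sin(xs), np.cos(xs)
    # n c(q) for the PY closure (Ashcroft-Lekner form)
    ncq = -24.0 * phi * (
        alpha * (sx - xs * cx) / xs**3
        + beta * (2.0 * xs * sx - (xs**2 - 2.0) * cx - 2.0) / xs**4
        + gamma
        * (
            (4.0 * xs**3 - 24.0 * xs) * sx
            - (xs**4 - 12.0 * xs**2 + 24.0) * cx
            + 24.0
        )
        / xs**6
    )
    out[~small] = 1.0 / (1.0 - ncq)
    # q -> 0 limit from the compressibility equation
    s0 = (1.0 - phi) ** 4 / (1.0 + 2.0 * phi) ** 2
    out[small] = s0
    return out


def _yukawa_beta_u(r: np.ndarray, params: ColloidParams) -> np.ndarray:
    """Dimensionless screened-Coulomb (DLVO) pair potential beta*u(r).

    beta u(r) = Z^2 lB [exp(kappa sigma/2)/(1 + kappa sigma/2)]^2
                * exp(-kappa r)/r,   r > sigma.
    """
    lb = bjerrum_length(params.temperature, params.dielectric)
    kap = debye_kappa(params)
    s = params.sigma_eff
    pref = params.charge**2 * lb * (math.exp(kap * s / 2.0) / (1.0 + kap * s / 2.0)) ** 2
    return pref * np.exp(-kap * r) / r


class _OZGrid:
    """Radial grid + sine-transform pair for the OZ solver (sigma = 1 units)."""

    def __init__(self, n: int, dr: float):
        self.n = n
        self.dr = dr
        self.r = dr * np.arange(1, n + 1)
        self.dk = math.pi / ((n + 1) * dr)
        self.k = self.dk * np.arange(1, n + 1)

    def fourier(self, f: np.ndarray) -> np.ndarray:
        """3-D Fourier transform of a radial function via DST-I."""
        return 4.0 * math.pi * self.dr * dst(f * self.r, type=1) / (2.0 * self.k)

    def inverse(self, fk: np.ndarray) -> np.ndarray:
        """Inverse 3-D Fourier transform of a radial function."""
        pref = self.dk / (2.0 * math.pi**2)
        return pref * dst(fk * self.k, type=1) / (2.0 * self.r)


def _picard_msa(
    rho_star: float,
    c_tail: np.ndarray,
    grid: _OZGrid,
    gamma0: np.ndarray | None = None,
    tol: float = 1e-6,
    max_iter: int = 5000,
) -> np.ndarray:
    """Ng-accelerated Picard iteration for gamma = h - c at one fixed tail.

    The fixed-point map is gamma -> F(gamma) obtained by closing the OZ
    equation in Fourier space; every third step an Ng extrapolation over
    the last three iterates is attempted (falling back to the damped
    Picard step whenever it would violate S(q) > 0).
    """
    r = grid.r
    core = r < 1.0
    tail = ~core
    clamp = 1e-3

    def step(g: np.ndarray) -> tuple[np.ndarray, bool]:
        """One application of the fixed-point map.

        Away from the solution 1 - rho c(k) can transiently go
        non-positive; it is clamped from below so the map stays
        defined, and the flag reports whether clamping was active
        (the converged solution must be clamp-free).
        """
        c = np.empty_like(r)
        c[core] = -1.0 - g[core]
        c[tail] = c_tail
        ck = grid.fourier(c)
        denom = 1.0 - rho_star * ck
        clamped = bool(np.any(denom < clamp))
        denom = np.maximum(denom, clamp)
        with np.errstate(over="ignore", invalid="ignore"):
            out = grid.inverse(rho_star * ck**2 / denom)
        return out, clamped

    gamma = np.zeros_like(r) if gamma0 is None else gamma0.copy()
    mix = 0.5
    err = math.inf
    prev_err = math.inf
    resets = 0
    hist_g: list[np.ndarray] = []  # previous iterates
    hist_f: list[np.ndarray] = []  # their images under the map
    for it in range(max_iter):
        f, clamped = step(gamma)
        if not np.all(np.isfinite(f)):
            # runaway iterate: restart heavily damped before giving up
            resets += 1
            if resets > 5:
                raise MSAConvergenceError(
                    "MSA iteration diverged; parameters are outside the "
                    "physical MSA branch"
                )
            gamma = np.zeros_like(r)
            mix = 0.05
            prev_err = math.inf
            hist_g.clear()
            hist_f.clear()
            continue
        err = float(np.max(np.abs(f - gamma)))
        if err < tol and clamped:
            raise MSAConvergenceError(
                "MSA iteration converged onto a state with non-positive "
                "S(q); parameters are outside the physical MSA branch"
            )
        if err < tol:
            return f
        # trust-region cap: the clamped map can produce huge spikes when
        # 1 - rho c(k) grazes zero; a capped step walks back into the
        # physical region instead of diverging
        step_cap = 2.0
        if err > step_cap:
            f = gamma + (f - gamma) * (step_cap / err)
            hist_g.clear()
            hist_f.clear()
        hist_g.append(gamma)
        hist_f.append(f)
        if len(hist_g) > 3:
            hist_g.pop(0)
            hist_f.pop(0)

        nxt = None
        # Ng 1974 extrapolation over the last three residuals; skipped
        # while the positivity clamp is active (map unreliable there)
        if len(hist_g) == 3 and it % 3 == 2 and not clamped:
            d = [hf - hg for hf, hg in zip(hist_f, hist_g)]
            scale_d = max(float(np.max(np.abs(d[2]))), 1e-300)
            d = [di / scale_d for di in d]
            d01 = d[2] - d[1]
            d02 = d[2] - d[0]
            a11, a12 = d01 @ d01, d01 @ d02
            a22 = d02 @ d02
            b1, b2 = d01 @ d[2], d02 @ d[2]
            det = a11 * a22 - a12 * a12
            if np.isfinite(det) and det > 1e-30 * max(a11 * a22, 1e-300):
                c1 = (b1 * a22 - b2 * a12) / det
                c2 = (a11 * b2 - a12 * b1) / det
                cand = (
                    (1.0 - c1 - c2) * hist_f[2]
                    + c1 * hist_f[1]
                    + c2 * hist_f[0]
                )
                # reject runaway extrapolations
                if np.max(np.abs(cand)) < 3.0 * (np.max(np.abs(f)) + 3.0):
                    nxt = cand
        if nxt is None:
            if clamped:
                mix = 0.1
            elif err > prev_err:
                mix = max(mix * 0.5, 0.02)
            else:
                mix = min(mix * 1.1, 0.5)
            nxt = (1.0 - mix) * gamma + mix * f
        gamma = nxt
        prev_err = err
    raise MSAConvergenceError(
        f"MSA iteration did not converge (residual {err:.2e}, mixing {mix})"
    )


def _solve_msa(rho_star: float, beta_u_of_r, grid: _OZGrid, gamma0=None):
    """Solve OZ + MSA closure for a hard core (sigma = 1) plus Yukawa tail.

    Closure: h(r) = -1 for r < 1 (core condition), c(r) = -beta u(r)
    for r > 1. For strongly coupled tails (|beta u| at contact above a
    few kT) the solve is warm-started by continuation in the potential
    strength, which keeps the damped Picard iteration convergent.
    ``gamma0`` warm-starts from a previous solve at nearby parameters.
    Returns (h_k on the transform grid, contact value g(1+), gamma).
    """
    r = grid.r
    core = r < 1.0
    tail = ~core
    c_tail_full = -beta_u_of_r(r[tail])

    coupling = float(np.max(np.abs(c_tail_full[:1]))) if c_tail_full.size else 0.0
    target = 8.0  # continuation step size in units of kT at contact
    if coupling > target and gamma0 is None:
        n_steps = int(math.ceil(math.log2(coupling / target))) + 1
        lambdas = [2.0 ** (i - n_steps + 1) for i in range(n_steps)]  # ... 1/4,1/2,1
    else:
        lambdas = [1.0]
    gamma = gamma0
    for lam in lambdas:
        gamma = _picard_msa(rho_star, lam * c_tail_full, grid, gamma0=gamma)

    c = np.empty_like(r)
    c[core] = -1.0 - gamma[core]
    c[tail] = c_tail_full
    h = gamma + c  # h = -1 exactly inside the core
    # contact value g(1+): linear extrapolation from first nodes outside core
    out_idx = np.nonzero(tail)[0]
    i0, i1 = out_idx[0], out_idx[1]
    g0, g1 = 1.0 + h[i0], 1.0 + h[i1]
    slope = (g1 - g0) / (r[i1] - r[i0])
    contact = g0 + slope * (1.0 - r[i0])
    hk = grid.fourier(h)
    return hk, contact, gamma


def _msa_structure_factor(
    params: ColloidParams,
    q: np.ndarray,
    scale: float = 1.0,
    dr: float = 0.001,
    gamma0: np.ndarray | None = None,
):
    """S(q) from one MSA solve with hard core scaled by ``scale`` >= 1.

    ``scale`` implements the Hansen-Hayter rescaling: the hard-core
    diameter becomes scale*sigma_eff at fixed number density, the tail
    potential is unchanged in physical space. ``dr`` is the radial grid
    step in units of the (scaled) diameter; the default resolves the
    core to 0.1%, adequate for ~5e-4 absolute accuracy in S(q).
    """
    sigma = params.sigma_eff * scale
    rho_star = params.number_density * sigma**3
    phi_star = math.pi / 6.0 * rho_star
    if phi_star >= 0.74:
        raise ValueError("rescaled packing fraction exceeds the physical range")

    qs = np.asarray(q, dtype=float) * sigma
    q_min_needed = max(float(np.min(qs[qs > 0])) if np.any(qs > 0) else 0.5, 1e-3)
    # grid: resolve the core and span far enough that the smallest
    # requested q is on the transform grid
    span = max(16.0, 1.2 * math.pi / q_min_needed)
    n = int(2 ** math.ceil(math.log2(span / dr)))
    n = min(max(n, 8192), 2**18)
    grid = _OZGrid(n, dr)

    def beta_u(r_red: np.ndarray) -> np.ndarray:
        if params.charge == 0:
            return np.zeros_like(r_red)
        return _yukawa_beta_u(r_red * sigma, params)

    if gamma0 is not None and gamma0.shape != grid.r.shape:
        gamma0 = None
    hk, contact, gamma = _solve_msa(rho_star, beta_u, grid, gamma0=gamma0)
    s_grid = 1.0 + rho_star * hk
    s_q = np.interp(qs, grid.k, s_grid, left=s_grid[0], right=1.0)
    return s_q, contact, gamma


_RMSA_CACHE: dict[tuple, np.ndarray] = {}
_RMSA_CACHE_MAX = 128


def rmsa_sq(q, params: ColloidParams, dr: float = 0.001) -> np.ndarray:
    """Rescaled-MSA structure factor of charged spheres on the q grid.

    Solves the MSA for the hard-core Yukawa potential; if the contact
    value of g(r) is negative (unphysical — the signature that the
    physical hard core is irrelevant at this coupling), the Hansen-
    Hayter rescaling maps the system onto a larger effective hard core
    at fixed number density such that g(sigma'+) = 0. ``dr`` trades
    grid resolution for speed (see :func:`_msa_structure_factor`).
    """
    q = np.asarray(q, dtype=float)
    # exact-key memoisation: repeated identical calls (common during
    # finite-difference Jacobians over parameters that do not touch the
    # structure factor) are returned bit-identically from cache
    key = (
        q.tobytes(),
        params.volume_fraction,
        params.sigma_eff,
        params.charge,
        params.temperature,
        params.dielectric,
        params.salt_molar,
        dr,
    )
    hit = _RMSA_CACHE.get(key)
    if hit is not None:
        return hit.copy()

    def _store(s: np.ndarray) -> np.ndarray:
        if len(_RMSA_CACHE) >= _RMSA_CACHE_MAX:
            _RMSA_CACHE.pop(next(iter(_RMSA_CACHE)))
        _RMSA_CACHE[key] = s.copy()
        return s

    if params.charge == 0:
        return _store(_msa_structure_factor(params, q, scale=1.0, dr=dr)[0])
    warm: dict[str, np.ndarray | None] = {"gamma": None}
    try:
        s_q, contact, warm["gamma"] = _msa_structure_factor(
            params, q, scale=1.0, dr=dr
        )
        if contact >= -1e-3:
            return _store(s_q)
    except MSAConvergenceError:
        contact = -1.0  # beyond the MSA branch: rescaling required

    # rescaling: find scale s > 1 with zero contact value; each solve
    # warm-starts from the previous one (nearby scale => nearby gamma)
    def contact_at(scale: float) -> float:
        try:
            _, c, warm["gamma"] = _msa_structure_factor(
                params, q[:1], scale=scale, dr=dr, gamma0=warm["gamma"]
            )
            return c
        except MSAConvergenceError:
            warm["gamma"] = None
            return -1.0  # push the bracket outward
    s_max_phi = (0.73 / params.volume_fraction) ** (1.0 / 3.0)
    lo, hi = 1.0, min(1.05, s_max_phi)
    c_hi = contact_at(hi)
    while c_hi < 0 and hi < s_max_phi:
        lo = hi
        hi = min(hi * 1.25, s_max_phi)
        c_hi = contact_at(hi)
    if c_hi < 0:
        raise RuntimeError(
            "RMSA rescaling failed: contact value still negative at the "
            f"maximum physical diameter scale {hi:.3f} (g(s+)={c_hi:.3e})"
        )
    scale = optimize.brentq(contact_at, lo, hi, xtol=1e-5)
    s_q, _, _ = _msa_structure_factor(
        params, q, scale=scale, dr=dr, gamma0=warm["gamma"]
    )
    return _store(s_q)


def combine_ps(
    form_curve,
    s_q: np.ndarray,
    q: np.ndarray | None = None,
) -> np.ndarray:
    """Combine form and structure factor: I(q) = P(q) * S(q).

    ``form_curve`` may be a :class:`~surfprot.sas.ScatteringCurve` or a
    plain intensity array on the same grid as ``s_q``. For anisotropic
    particles this direct multiplication (with sigma_eff from the
    equal-volume sphere) is the usual monodisperse approximation; no
    beta(q) decoupling correction is applied.
    """
    s_q = np.asarray(s_q, dtype=float)
    if hasattr(form_curve, "I"):
        p = np.asarray(form_curve.I, dtype=float)
        qp = form_curve.q
        if q is not None and (len(q) != len(qp) or not np.allclose(q, qp)):
            raise ValueError("form factor and structure factor grids differ")
    else:
        p = np.asarray(form_curve, dtype=float)
    if p.shape != s_q.shape:
        raise ValueError("form factor and structure factor grids differ")
    return p * s_q
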