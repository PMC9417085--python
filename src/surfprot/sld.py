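"""Neutron scattering-length densities and contrast planning.

Contrast-variation SANS relies on tuning the H2O/D2O composition of the
solvent so that chosen components of a multi-component particle become
invisible (contrast matching) or so that the volume-weighted mean
contrast of the whole complex vanishes (the zero-average-contrast, ZAC,
condition). This module computes SLDs of solvents and of molecules from
sequence, locates match points theoretically and from experimental
forward-scattering series, and solves the ZAC composition.

Conventions
-----------
* SLDs are in A^-2 throughout; solvent compositions are volume
  fractions of H2O (``f_h2o``) or of D2O (``f_d2o = 1 - f_h2o``).
* A molecule's SLD in a mixed solvent accounts for H/D exchange of its
  labile hydrogens: each labile H contributes a scattering length
  interpolated between H and D by ``exchange_fraction * f_d2o``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .constants import (
    B_EXCHANGE,
    DEFAULT_EXCHANGE_FRACTION,
    RESIDUE_TABLE,
    SLD_D2O,
    SLD_H2O,
)

__all__ = [
    "SolventComposition",
    "ContrastScheme",
    "MatchPointResult",
    "load_residue_table",
    "read_fasta",
    "solvent_sld",
    "molecule_sld",
    "molecule_sum",
    "theoretical_match_point",
    "experimental_match_point",
    "zac_solvent",
    "zac_composition",
]

# fm / A^3 -> A^-2
_FM_PER_A3_TO_SLD = 1.0e-5


@dataclass(frozen=True)
class SolventComposition:
    """An H2O/D2O mixture and its SLD (A^-2)."""

    f_h2o: float
    sld: float

    def __post_init__(self) -> None:
        if not -1e-12 <= self.f_h2o <= 1 + 1e-12:
            raise ValueError(f"f_h2o must be in [0, 1], got {self.f_h2o}")


@dataclass(frozen=True)
class MatchPointResult:
    """Outcome of a match-point determination.

    ``f_h2o`` is NaN when no crossing exists in the water range; the
    end-point SLD mismatch is then reported via ``endpoint_residuals``.
    """

    f_h2o: float
    f_h2o_err: float
    sld: float
    found: bool
    endpoint_residuals: tuple[float, float] | None = None


@dataclass(frozen=True)
class ContrastScheme:
    """Per-contrast SLDs of protein, surfactant and solvent (A^-2).

    The four canonical labelling schemes of a contrast-variation
    experiment on a two-component complex:

    * ``protein``    - surfactant matched to solvent (protein visible)
    * ``complex``    - surfactant matched to protein (complex visible)
    * ``surfactant`` - protein matched to solvent (surfactant visible)
    * ``zac``        - zero-average-contrast solvent
    """

    entries: dict[str, dict[str, float]] = field(default_factory=dict)

    IDENTITIES = {
        "protein": ("sld_surfactant", "sld_solvent"),
        "complex": ("sld_surfactant", "sld_protein"),
        "surfactant": ("sld_protein", "sld_solvent"),
    }

    def __post_init__(self) -> None:
        for label, entry in self.entries.items():
            missing = {"sld_protein", "sld_surfactant", "sld_solvent"} - set(entry)
            if missing:
                raise ValueError(f"contrast {label!r} missing fields {sorted(missing)}")
            ident = self.IDENTITIES.get(label)
            if ident is not None:
                a, b = entry[ident[0]], entry[ident[1]]
                scale = max(abs(a), abs(b), 1e-10)
                if abs(a - b) / scale > 1e-6:
                    raise ValueError(
                        f"contrast {label!r} violates its matching identity "
                        f"{ident[0]} == {ident[1]} ({a:g} != {b:g})"
                    )

    def __getitem__(self, label: str) -> dict[str, float]:
        return self.entries[label]

    def labels(self) -> list[str]:
        return list(self.entries)


def load_residue_table(path) -> dict[str, tuple[float, int, float]]:
    """Load a residue scattering table from CSV.

    Columns: ``residue, b_fm, n_exchangeable, volume_A3``.
    """
    import pandas as pd

    df = pd.read_csv(path)
    table: dict[str, tuple[float, int, float]] = {}
    for _, row in df.iterrows():
        code = str(row["residue"]).strip()
        vol = float(row["volume_A3"])
        nx = int(row["n_exchangeable"])
        if vol <= 0:
            raise ValueError(f"residue {code!r}: volume must be positive")
        if nx < 0:
            raise ValueError(f"residue {code!r}: exchangeable-H count must be >= 0")
        table[code] = (float(row["b_fm"]), nx, vol)
    return table


def read_fasta(path) -> str:
    """Read a single-record FASTA file and return the sequence string."""
    seq_lines: list[str] = []
    n_records = 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                n_records += 1
                if n_records > 1:
                    raise ValueError("expected a single-record FASTA file")
                continue
            seq_lines.append(line)
    seq = "".join(seq_lines).upper()
    if not seq:
        raise ValueError("no sequence found in FASTA file")
    return seq


def solvent_sld(
    f_h2o: float,
    sld_h2o: float = SLD_H2O,
    sld_d2o: float = SLD_D2O,
) -> float:
    """SLD of an H2O/D2O mixture by ideal volume-fraction mixing (A^-2)."""
    if not 0.0 <= f_h2o <= 1.0:
        raise ValueError(f"f_h2o must be in [0, 1], got {f_h2o}")
    return f_h2o * sld_h2o + (1.0 - f_h2o) * sld_d2o


def _sum_b_and_v(
    sequence: str,
    f_d2o: float,
    exchange_fraction: float,
    table: dict[str, tuple[float, int, float]],
    n_condensation_water: int,
) -> tuple[float, float]:
    b_tot = 0.0
    v_tot = 0.0
    deut = exchange_fraction * f_d2o
    for pos, code in enumerate(sequence):
        try:
            b, n_ex, vol = table[code]
        except KeyError:
            raise ValueError(
                f"unknown residue code {code!r} at position {pos + 1}"
            ) from None
        b_tot += b + n_ex * deut * B_EXCHANGE
        v_tot += vol
    if n_condensation_water and "HOH" in table:
        b, n_ex, vol = table["HOH"]
        b_tot += n_condensation_water * (b + n_ex * deut * B_EXCHANGE)
        v_tot += n_condensation_water * vol
    return b_tot, v_tot


def molecule_sum(
    sequence: str,
    f_d2o: float = 1.0,
    exchange_fraction: float = DEFAULT_EXCHANGE_FRACTION,
    table: dict[str, tuple[float, int, float]] | None = None,
    n_condensation_water: int = 1,
) -> tuple[float, float]:
    """Total scattering length (fm) and volume (A^3) of a sequence."""
    if not sequence:
        raise ValueError("sequence must be non-empty")
    if not 0.0 <= exchange_fraction <= 1.0:
        raise ValueError("exchange_fraction must be in [0, 1]")
    if not 0.0 <= f_d2o <= 1.0:
        raise ValueError("f_d2o must be in [0, 1]")
    return _sum_b_and_v(
        sequence, f_d2o, exchange_fraction, table or RESIDUE_TABLE, n_condensation_water
    )


def molecule_sld(
    sequence: str,
    f_d2o: float,
    exchange_fraction: float = DEFAULT_EXCHANGE_FRACTION,
    table: dict[str, tuple[float, int, float]] | None = None,
    n_condensation_water: int = 1,
) -> float:
    """SLD of a molecule given by residue sequence, in a mixed solvent.

    Each labile hydrogen's scattering length is interpolated between H
    and D by ``exchange_fraction * f_d2o``; the result is the summed
    scattering length divided by the summed residue volume. One water
    of condensation is added by default so that the sum corresponds to
    the intact molecule.
    """
    b_tot, v_tot = molecule_sum(
        sequence, f_d2o, exchange_fraction, table, n_condensation_water
    )
    return b_tot * _FM_PER_A3_TO_SLD / v_tot


def theoretical_match_point(
    sequence: str,
    exchange_fraction: float = DEFAULT_EXCHANGE_FRACTION,
    sld_h2o: float = SLD_H2O,
    sld_d2o: float = SLD_D2O,
    table: dict[str, tuple[float, int, float]] | None = None,
    molecule_sld_fn=None,
) -> MatchPointResult:
    """Solvent composition at which the molecule is contrast matched.

    Solves ``molecule_sld(seq, 1 - f_h2o) == solvent_sld(f_h2o)`` as a
    1-D root of a monotone function. ``molecule_sld_fn`` may supply an
    arbitrary ``f(f_d2o) -> sld`` (e.g. a constant), bypassing the
    sequence.
    """
    if molecule_sld_fn is None:
        def molecule_sld_fn(f_d2o: float) -> float:  # noqa: E731 style
            return molecule_sld(sequence, f_d2o, exchange_fraction, table)

    def resid(f_h2o: float) -> float:
        return molecule_sld_fn(1.0 - f_h2o) - solvent_sld(f_h2o, sld_h2o, sld_d2o)

    r0, r1 = resid(0.0), resid(1.0)
    if r0 == 0.0:
        return MatchPointResult(0.0, 0.0, sld_d2o, True)
    if r1 == 0.0:
        return MatchPointResult(1.0, 0.0, sld_h2o, True)
    if r0 * r1 > 0:
        return MatchPointResult(
            math.nan, math.nan, math.nan, False, endpoint_residuals=(r0, r1)
        )
    f = optimize.brentq(resid, 0.0, 1.0, xtol=1e-12)
    return MatchPointResult(f, 0.0, solvent_sld(f, sld_h2o, sld_d2o), True)


def experimental_match_point(points) -> tuple[float, float]:
    """Match point from a contrast-variation forward-scattering series.

    ``points`` is a sequence of ``(f_h2o, I0)`` or ``(f_h2o, I0, dI0)``
    tuples. Since I(0) is proportional to contrast squared, sqrt(I(0))
    is linear in f_h2o up to a sign that flips at the match point. The
    sign pattern (a single flip along the sorted f_h2o axis) is chosen
    to minimize the weighted linear-fit residual; the fitted line's
    x-intercept and its propagated standard error are returned.
    """
    pts = [tuple(p) for p in points]
    if len(pts) < 3:
        raise ValueError("need at least 3 contrast points")
    f = np.array([p[0] for p in pts], dtype=float)
    i0 = np.array([p[1] for p in pts], dtype=float)
    if np.any(i0 < 0):
        raise ValueError("I(0) values must be non-negative")
    if np.all(i0 == 0):
        raise ValueError("degenerate fit: all I(0) are zero")
    if len(np.unique(f)) < 2:
        raise ValueError("degenerate fit: need at least two distinct f_h2o")
    di0 = np.array([p[2] if len(p) > 2 else 0.0 for p in pts], dtype=float)

    order = np.argsort(f)
    f, i0, di0 = f[order], i0[order], di0[order]
    y = np.sqrt(i0)
    # d(sqrt I)/dI = 1/(2 sqrt I); fall back to unit weights where dI or I is 0
    with np.errstate(divide="ignore", invalid="ignore"):
        dy = np.where((di0 > 0) & (i0 > 0), di0 / (2.0 * np.sqrt(i0)), 0.0)
    if np.any(dy <= 0):
        dy = np.where(dy > 0, dy, np.max(dy[dy > 0]) if np.any(dy > 0) else 1.0)
    w = 1.0 / dy**2

    best = None
    n = len(f)
    for flip in range(0, n + 1):
        sign = np.where(np.arange(n) < flip, 1.0, -1.0)
        ys = sign * y
        try:
            (slope, icpt), cov, chi2 = _weighted_linfit(f, ys, w)
        except np.linalg.LinAlgError:
            continue
        if best is None or chi2 < best[0]:
            best = (chi2, slope, icpt, cov)
    if best is None or abs(best[1]) < 1e-300:
        raise ValueError("degenerate fit: no usable sign assignment")
    _, slope, icpt, cov = best
    x0 = -icpt / slope
    # var(x0) by first-order propagation through x0 = -a/b
    var = (
        cov[1, 1] / slope**2
        + icpt**2 * cov[0, 0] / slope**4
        - 2.0 * icpt * cov[0, 1] / slope**3
    )
    return float(x0), float(math.sqrt(max(var, 0.0)))


def _weighted_linfit(x, y, w):
    """Weighted least squares y = slope*x + intercept.

    Returns ((slope, intercept), covariance, chi2). Covariance is the
    formal (chi2-unscaled) covariance from the weights.
    """
    A = np.column_stack([x, np.ones_like(x)])
    Aw = A * np.sqrt(w)[:, None]
    yw = y * np.sqrt(w)
    ata = Aw.T @ Aw
    cov = np.linalg.inv(ata)
    beta = cov @ (Aw.T @ yw)
    resid = yw - Aw @ beta
    chi2 = float(resid @ resid)
    return (float(beta[0]), float(beta[1])), cov, chi2


def zac_solvent(sld_a: float, phi_a: float, sld_b: float, phi_b: float) -> float:
    """Solvent SLD satisfying the zero-average-contrast condition.

    rho_s = (phi_a rho_a + phi_b rho_b) / (phi_a + phi_b): the volume-
    weighted mean SLD of the two components, at which the average
    contrast of the complex vanishes.
    """
    if phi_a < 0 or phi_b < 0 or phi_a + phi_b <= 0:
        raise ValueError("volume fractions must be non-negative with positive sum")
    return (phi_a * sld_a + phi_b * sld_b) / (phi_a + phi_b)


def zac_composition(
    protein_sld_fn,
    phi_protein: float,
    sld_surfactant: float,
    phi_surfactant: float,
    sld_h2o: float = SLD_H2O,
    sld_d2o: float = SLD_D2O,
) -> tuple[float, float, bool]:
    """Self-consistent ZAC solvent when the protein SLD tracks the solvent.

    ``protein_sld_fn(f_h2o) -> sld``; returns ``(sld_solvent, f_h2o,
    attainable)``. When the required solvent SLD lies outside the pure-
    water range, ``attainable`` is False and ``f_h2o`` is NaN (the SLD
    returned is the fixed point of the defining equation regardless).
    """

    def resid(f_h2o: float) -> float:
        target = zac_solvent(
            protein_sld_fn(f_h2o), phi_protein, sld_surfactant, phi_surfactant
        )
        return solvent_sld(f_h2o, sld_h2o, sld_d2o) - target

    r0, r1 = resid(0.0), resid(1.0)
    if r0 * r1 > 0:
        # unattainable inside the water range; report the closer endpoint SLD
        f_best = 0.0 if abs(r0) < abs(r1) else 1.0
        sld = zac_solvent(
            protein_sld_fn(f_best), phi_protein, sld_surfactant, phi_surfactant
        )
        return sld, math.nan, False
    f = optimize.brentq(resid, 0.0, 1.0, xtol=1e-14)
    sld = solvent_sld(f, sld_h2o, sld_d2o)
    return sld, f, True
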