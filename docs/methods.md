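# Methods

`surfprot` analyses the complexation of a globular protein with an
ionic surfactant by combining contrast-variation small-angle neutron
scattering (SANS) modelling with benchtop titration analytics. This
note records the models, the numerical choices behind them, and what
the synthetic-data tests do and do not demonstrate.

## Scattering length densities and contrast planning (`surfprot.sld`)

Solvent SLDs follow ideal volume-fraction mixing of the pure-water
values, H₂O = −0.56×10⁻⁶ Å⁻² and D₂O = 6.39×10⁻⁶ Å⁻² (both
overridable). A molecule's SLD is Σb/ΣV over its residues using a
shipped per-residue table of coherent scattering lengths (protonated),
labile-hydrogen counts and dry volumes, following the standard
biomolecular compilations used for neutron contrast work (Jacrot-type
tables). The chain sum adds one water of condensation so that an
n-residue chain reconstitutes the intact molecule; users may override
the table via CSV. Each labile hydrogen's scattering length is
interpolated between H and D by `exchange_fraction × f_D2O`; the
default exchange fraction is 0.90, the value commonly assumed for
folded proteins in which a fraction of backbone amides exchanges
slowly. Buffer salts at the 10 mM level shift the solvent SLD by well
under 1% and are neglected.

The theoretical match point solves `molecule_sld(1−f_H2O) ==
solvent_sld(f_H2O)` by bracketed root finding; the function is affine
in the composition on both sides, so the root is unique when it exists.
The experimental match point fits sign-adjusted √I(0) against f_H₂O;
since the measured I(0) loses the sign of the contrast, the sign
pattern (one flip along the sorted composition axis) is chosen to
minimize the weighted residual. Note that a 191-residue growth-hormone
sequence evaluated with the shipped table matches at 58.7% H₂O
(solvent SLD 2.31×10⁻⁶ Å⁻²) — between the commonly quoted theoretical
(57.25% H₂O, 2.41×10⁻⁶ Å⁻²) and experimental (60.1% H₂O) values for
this protein. Those two published numbers are not mutually consistent
under ideal water mixing with the standard constants (60.1% H₂O mixes
to 2.22×10⁻⁶, not 2.31×10⁻⁶); the discrepancy presumably reflects the
experimental definition of the SLD at the measured intercept, and this
package does not attempt to reconcile it.

The zero-average-contrast (ZAC) solvent is the volume-weighted mean
SLD of the two components, ρ_s = (φ_A ρ_A + φ_B ρ_B)/(φ_A + φ_B).
When the protein SLD itself depends on the solvent through H/D
exchange, the composition is solved self-consistently by 1-D root
finding on f_H₂O.

## Form factors and curve utilities (`surfprot.sas`)

Analytic form factors: sphere, uniform ellipsoid of revolution, and
core–shell ellipsoid with equal shell thickness on the polar and
equatorial axes (whether unequal thickness is ever warranted is an open
modelling choice; the equal-thickness convention is the default and the
axes can be generalized later without interface changes). Orientational
averaging uses Gauss–Legendre quadrature over cos θ with 76 points by
default; doubling the order changes the curves by <10⁻⁵ relative.
Intensities are absolute: I(q) = 10⁸ φ ⟨|F|²⟩ / V + background, with F
in contrast × volume (Å), V the outer particle volume (Å³) and the 10⁸
converting Å⁻¹ to cm⁻¹. The same convention is used by the
co-refinement module, so fitted scale factors are dimensionless numbers
of order one.

Resolution smearing interprets the optional `dq` column of a reduced
dataset as the 1-σ width of a Gaussian kernel at each q. Smearing is a
banded matrix built from 25 equally spaced quadrature nodes within
±3σ, mapped onto the measurement grid by linear interpolation;
truncated rows at the edges are renormalized so a constant curve is
preserved exactly.

The Guinier fit iterates the window q·Rg ≤ 1.3 until the Rg estimate is
stable to 1%, with at least five points; exactly flat data return
Rg = 0 and I(0) equal to the plateau, while a genuinely rising low-q
slope is an error ("no Guinier regime").

## Structure factor of charged complexes (`surfprot.structure_factor`)

Interparticle interference is modelled as an effective one-component
macroion fluid: spheres of diameter σ_eff carrying net charge Z
interacting through a hard core plus screened-Coulomb (DLVO/Yukawa)
tail, βu(r) = Z² λ_B [e^{κσ/2}/(1+κσ/2)]² e^{−κr}/r. The inverse Debye
length includes both the added monovalent salt and the counterions
released by the macroions, κ² = 4π λ_B (2 n_salt + |Z| n_p). Defaults:
water at 25 °C (ε = 78.3) and 10 mM salt; the study buffer's ionic
composition beyond this is an assumption, stated here once.

The mean spherical approximation (MSA) for this potential is solved
numerically: the Ornstein–Zernike equation is closed with the MSA
conditions (h = −1 inside the core, c = −βu outside) and iterated in
Fourier space on a radial grid of 0.001 σ steps (configurable) using
Ng-accelerated, adaptively damped Picard iteration; strong couplings
are reached by continuation in the potential strength, and transient
violations of S(q) > 0 are handled with a clamped, step-capped map
(the converged solution is required to be clamp-free). At Z = 0 this
reduces to the Percus–Yevick hard-sphere problem and matches the
analytic PY structure factor to better than 10⁻³ absolute up to
packing fraction 0.2 — the oracle test shipped with the package.
When the MSA contact value g(σ⁺) is negative (or the MSA has no
physical solution at all, which the solver reports), the Hansen–Hayter
rescaling is applied: the hard core is enlarged at fixed number density
until g(σ'⁺) = 0, found by bracketed root solving. Note the packing
fraction grows with the cube of the rescaled diameter — the physical
particle volume fraction is unchanged.

P(q)·S(q) multiplication uses the equal-volume-sphere diameter of the
(possibly anisotropic) particle, the common monodisperse approximation;
no β(q) decoupling correction is applied, matching the modelling level
of a typical spheroid-with-RMSA analysis. Results for identical
parameters are memoised by exact key, which keeps repeated evaluations
(finite-difference Jacobians) cheap and bit-reproducible.

## Indirect Fourier transform (`surfprot.ift`)

p(r) is expanded in `n_basis = 30` sine functions vanishing at 0 and
D_max and fitted to I(q) (through the smearing matrix when dq is
present) with a second-difference smoothness penalty on a 101-point r
grid. The regularization weight α is placed at the maximum-curvature
corner of the discrete L-curve over a fixed 31-point logarithmic grid
anchored to the spectral norms of the problem — a deterministic,
seed-free rule with manual override. Negative p(r) is permitted by
default, which is appropriate whenever the contrast profile can change
sign; `nonnegative=True` switches to a grid-space NNLS solve under the
same penalty for uniform-sign particles. Derived quantities follow
from the fitted p(r): I(0) = 4π∫p dr and R_g² = ∫r²p dr / (2∫p dr).

`dmax_scan` fits a grid of D_max candidates and selects the smallest
one at which (a) R_g changes by <2% on the next grid step and (b) the
total χ² is within Δχ² = 9 (a 3σ-like criterion) of the scan minimum —
a too-small D_max truncates the p(r) support and registers as a
significant misfit. With no such plateau the best-χ² point is returned
flagged "unstable". Known limitation: for core–shell profiles whose
shell is weakly contrasted, the p(r) mass near the geometric maximum
dimension is tiny, and any χ²-based selection reads the *effective*
support, 10–20% below the geometric outer diameter even on noise-free
data; the sphere benchmark recovers its diameter to better than 10% at
2% noise. This mirrors the behaviour of standard IFT software, where
the final D_max is partly an expert judgement.

## Multi-contrast co-refinement (`surfprot.cofit`)

One structural model — a core–shell ellipsoid whose core is the
surfactant cluster and whose shell is protein covering a fraction c of
the shell volume — is refined simultaneously against all contrasts.
Under contrast k the shell SLD is the two-component mix
ρ_shell = c·ρ_protein(k) + (1−c)·ρ_solvent(k), so partial coverage
needs no per-contrast parameters; inverting this mix is also how a
fitted shell SLD is converted to a coverage (`coverage_from_shell`).
Applied to shell SLD 3.43×10⁻⁶ with protein 2.79×10⁻⁶ and solvent
6.37×10⁻⁶ Å⁻², the formula gives c = 0.82; published analyses of this
system quote ca. 66% for those numbers, an arithmetic that no stated
linear mixing reproduces — the package implements the transparent
formula and leaves the discrepancy documented rather than forced.

Geometry, coverage and charge are shared; the per-contrast intensity
scale and flat background enter linearly and are profiled out at every
trial point (variable projection), which shrinks the nonlinear problem
to the five shared parameters and removes most local-minimum traps.
The trust-region least-squares refinement uses a relative
finite-difference step of 10⁻³ (larger than the structure-factor
solver's numerical noise) and an optional deterministic multi-start
grid scaling the starting radius and shell thickness by fixed factors.
Uncertainties come from the Jacobian at the optimum scaled by the
reduced χ²; N_agg = v_core/v_SDS errors are first-order (delta-method)
propagated. The default surfactant molecular volume is v_SDS = 412 Å³
(whole molecule), configurable. With all per-contrast scales free
there is a genuine soft direction linking the overall size, coverage
and scales; the reported uncertainties widen accordingly, and the
4-contrast scheme still recovers all shared parameters of the
synthetic ground truth within 3σ at 2% noise. One contrast alone
leaves core and shell nearly inseparable — its shell-thickness
uncertainty is an order of magnitude larger, which is the quantitative
case for contrast variation.

`zac_forward_check` evaluates the model at the ZAC solvent computed
from its own core volume and effective shell material (protein at
coverage c): the forward amplitude cancels identically, F(0) = 0, while
core/shell segregation keeps I at finite q — the decorated-micelle
signature. The forward intensity grows quadratically with solvent-SLD
detuning from the ZAC value, which the tests verify.

## Benchtop analytics (`surfprot.benchtop`)

Units are µM for protein and mM for surfactant throughout.

* **Centre of mass** of tryptophan emission over a 310–450 nm window
  (configurable): Σλ·I/ΣI. Window truncation biases the CM of broad
  bands; comparisons should use a fixed window.
* **Pyrene I₃/I₁**: band maxima within ±3 nm of 373 and 384 nm.
* **Breakpoints**: two-segment weighted linear fit with the split
  chosen by grid search (minimum 3 points per segment); the breakpoint
  is the intersection of the two lines with first-order propagated
  error. Data that a single line fits within 5% of the two-segment
  residual are flagged "no breakpoint".
* **ITC decomposition**: transition concentrations at several protein
  concentrations are regressed as [SDS] = [SDS]_unbound + N_agg·[hGH];
  exactly collinear input returns zero standard errors. When boundary
  uncertainties are passed as weights, parameter errors use the formal
  covariance inflated by reduced χ² when that exceeds one.
* **`detect_transitions`**: dynamic-programming piecewise-linear
  segmentation of molar heat vs cumulative concentration, penalized per
  extra segment by a BIC-like cost scaled with the noise variance
  estimated from second differences (trend-insensitive). Boundaries
  are refined to the intersections of adjacent segment lines — exact
  for piecewise-linear truth and independent of the injection grid —
  with propagated uncertainties. Segmentation is a proposal; expert
  pinning of transitions remains possible downstream.
* **CD**: mean residue ellipticity θ_MR = θ_mdeg·MRW/(10·l·c) with
  path in cm and concentration in g/L; descriptors are θ at 209, 220,
  292 nm by linear interpolation, the 220/209 ratio (secondary
  structure) and parametric pairs for denaturation-trajectory plots.
* **A280**: Beer–Lambert with user-supplied ε and MW.

## Synthetic data (`surfprot.synthetic`)

All generators are pure functions of a `GroundTruth` and a seed; fixed
seed means bit-identical output. The default ground truth is the
end-state decorated micelle of the study conditions: a surfactant core
of N_agg = 26 molecules (v_core = 26×412 Å³) as a prolate ellipsoid of
axial ratio 1.5, a 12 Å protein shell at coverage 0.66, net charge
−29, at 0.135 mM complexes (volume fraction ≈ 0.006), with the
four-contrast SLD scheme (protein/complex/surfactant/ZAC) whose
matching identities are enforced by construction and whose ZAC solvent
is computed from the model itself. SANS curves are smeared with
dq = 0.05 q and carry counting-like noise dI = a√I + b (defaults
a = 0.01, b = 10⁻³ cm⁻¹). ITC enthalpograms are piecewise linear in
the cumulative, perfusion-corrected cell concentration
C_syr(1 − e^{−V/V₀}) with stage boundaries at unbound + N_agg·[protein]
(per-transition values 6/23/32/61/61 and 0.51/0.81/1.3/4.1/5.4 mM) and
signal decaying to zero after the last stage; the default injection
schedule (25×2 µL then 30×10 µL) resolves the early transitions, as in
routine ITC practice. Spectral titrations are two-basis mixtures with
logistic transitions (fluorescence midpoint 38 SDS/protein; CD near-UV
16, far-UV 59); the pyrene ratio is a two-plateau ramp with its lower
kink exactly at the generating CAC (0.43 mM with protein; pass the
buffer CMC 4.1 mM for protein-free series).

What the generators do *not* emulate: event-mode instrument effects,
wavelength-dependent smearing, multiple scattering, concentration-
dependent backgrounds, exo/endothermic overlap within single ITC
injections, and aromatic fine structure in CD. Passing recovery tests
therefore demonstrates the correctness of the estimators under the
assumed statistical model, not robustness to every instrumental
artefact of real data.

## Reported reference values

The package's tests reproduce self-contained published numbers of the
hGH–SDS system where they are pure arithmetic: total-SDS predictions
from per-transition parameters (ratio 58 at 50 µM; 3.9 mM and 13.6 mM
at 0.135 mM protein), the CAC-to-protein ratio 42, and the solvent SLD
2.41×10⁻⁶ Å⁻² at 57.25% H₂O. Experimentally fitted quantities of the
original study (D_max = 51.7 Å, R_g = 18.4 Å, N_agg = 26, shell SLD
3.43×10⁻⁶, Z = −29) are used only as generator settings or
documentation context: the underlying beamline data are not deposited,
so they are not reproduction targets.
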