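"""Real-space analysis of a SANS curve: Guinier fit and p(r) inversion.

Builds a noisy synthetic curve of the surfactant-protein complex
(complex contrast, dilute limit), runs the Guinier approximation, scans
D_max with the regularized indirect Fourier transform and reports the
pair distance-distribution function's derived quantities.
"""

from dataclasses import replace

import numpy as np

from surfprot.ift import dmax_scan
from surfprot.sas import guinier_fit
from surfprot.synthetic import default_ground_truth, gen_sans

truth = default_ground_truth()
# dilute limit: switch off interparticle interference for the IFT route
truth0 = replace(truth, model=replace(truth.model, charge=0.0))
curve = gen_sans(truth0, noise=0.01, seed=4)["complex"]
# subtract the known flat background before inversion
i_sub = curve.I - truth0.backgrounds["complex"]
curve = curve.with_intensity(i_sub, curve.dI)

g = guinier_fit(curve)
print(f"Guinier: Rg = {g.rg:.2f} +- {g.rg_err:.2f} A, I(0) = {g.i0:.3f} cm^-1")
print(f"  ({g.n_points} points, q window {g.q_window[0]:.4f}-{g.q_window[1]:.4f} A^-1)")

res = dmax_scan(curve, np.arange(30.0, 92.0, 2.5))
pddf = res.fits[res.dmax]
geo = truth.model.geometry
d_true = 2.0 * (geo.axial_ratio * geo.radius + geo.shell_thickness)
print(f"\nIFT D_max scan: selected D_max = {res.dmax:.1f} A (stable: {res.stable})")
print(f"  p(r)-derived Rg = {pddf.rg:.2f} A, I(0) = {pddf.i0:.3f} cm^-1")
print(f"  chi^2_red = {pddf.chi2_red:.2f}, regularization alpha = {pddf.alpha:.3g}")
print(f"  generator outer diameter: {d_true:.1f} A")
print("\nRg from p(r) should agree with the Guinier value within their")
print("uncertainties. The selected D_max is the effective support of p(r):")
print("for a core-shell profile the weakly contrasted shell edge carries")
print("little p(r) mass, so it reads 10-20% below the geometric diameter.")
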