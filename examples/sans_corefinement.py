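"""Simultaneous co-refinement of four neutron contrasts.

Generates the four-contrast SANS dataset of a decorated-micelle complex
(surfactant core, partially covering protein shell, net charge) and
refines one shared structural model against all curves at once. Derived
quantities: surfactant aggregation number from the core volume, protein
coverage from the shell SLD, net charge from the structure factor, and
the zero-average-contrast consistency check.
"""

from dataclasses import replace

from surfprot.cofit import simultaneous_fit, zac_forward_check
from surfprot.synthetic import default_ground_truth, gen_sans

truth = default_ground_truth()
curves = gen_sans(truth, noise=0.02, seed=5)
print("contrasts:", ", ".join(sorted(curves)))

# start displaced from the generating model
start = replace(
    truth.model,
    geometry=replace(
        truth.model.geometry, radius=15.0, axial_ratio=1.2, shell_thickness=9.0
    ),
    coverage=0.5,
    charge=-15.0,
)
fit = simultaneous_fit(curves, start, multistart=1)

geo = truth.model.geometry
true_vals = {
    "radius": geo.radius,
    "axial_ratio": geo.axial_ratio,
    "shell_thickness": geo.shell_thickness,
    "coverage": truth.model.coverage,
    "charge": truth.model.charge,
}
print("\nshared parameters (fit vs generator):")
for name, true in true_vals.items():
    print(
        f"  {name:16s} {fit.params[name]:8.3f} +- {fit.errors[name]:6.3f}"
        f"   (true {true:8.3f})"
    )
print("\nper-contrast reduced chi^2:",
      {k: round(v, 2) for k, v in fit.chi2_red.items()})
print(f"N_agg = v_core / v_SDS = {fit.nagg:.1f} +- {fit.nagg_err:.1f}"
      f" (generator {truth.model.nagg:.0f})")

zac = zac_forward_check(fit.model)
print(
    f"\nZAC check on the fitted model: I(0) = {zac.i0:.2e} cm^-1, "
    f"internal feature {zac.i_max:.2e} cm^-1 at q = {zac.q_at_max:.3f} A^-1"
)
print("forward scattering cancels at the ZAC solvent while the core/shell")
print("segregation still scatters at finite q — the decorated-micelle signature")
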