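import numpy as np
import pytest

from surfprot.sas import GeometryParams, ScatteringCurve, form_factor_intensity
from surfprot.synthetic import default_ground_truth


@pytest.fixture(scope="session")
def ground_truth():
    return default_ground_truth()


@pytest.fixture(scope="session")
def sphere_curve_factory():
    """Analytic sphere curves with optional seeded relative noise."""

    def make(radius=25.0, noise=0.0, seed=0, qmax=0.45, n=120, contrast=3e-6, phi=0.01):
        gp = GeometryParams(
            kind="sphere",
            radius=radius,
            sld_core=contrast,
            sld_solvent=0.0,
            volume_fraction=phi,
        )
        q = np.linspace(0.008, qmax, n)
        I = form_factor_intensity(gp, q)
        dI = np.maximum(noise, 0.005) * I + 1e-4
        if noise > 0:
            rng = np.random.default_rng(seed)
            I = I + rng.normal(0.0, dI)
        return ScatteringCurve(q, I, dI), gp

    return make
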