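"""Shared fixtures: small generated packings and calibration curves."""

from __future__ import annotations

import numpy as np
import pytest

from photoglass.glass import GlassRecipe, generate_packing
from photoglass.inference import calibration_curve


@pytest.fixture(scope="session")
def small_packing():
    """Desk-scale glass: N=216, 10% polydispersity, phi=0.50."""
    recipe = GlassRecipe(n_particles=216, quench_steps=4000, seed=42)
    return generate_packing(recipe)


@pytest.fixture(scope="session")
def small_recipe():
    return GlassRecipe(n_particles=216, quench_steps=4000, seed=42)


@pytest.fixture(scope="session")
def te_calibration():
    """TE2/TE3 calibration curves at the default dry-particle geometry."""
    return {
        label: calibration_curve(label=label, smooth_window=31, refine_half_window=10)
        for label in [("TE", 2), ("TE", 3)]
    }


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
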