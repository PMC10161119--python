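import numpy as np
import pytest

from protonspot.dose import SpotOpticsModel
from protonspot.pipeline import PipelineConfig, default_phantom_spec
from protonspot.synthetic import (ErrorModelTruth, generate_phantom, generate_plan,
                                  plan_spec_preset)

SMOKE_PLAN_OVERRIDES = dict(
    spot_spacing_mm=10.0, layer_spacing_mm=6.0, target_margin_mm=12.0,
    lateral_margin_mm=12.0, aperture_margin_mm=14.0,
    distal_margin_mm=12.0, proximal_margin_mm=12.0,
)


@pytest.fixture(scope="session")
def optics():
    return SpotOpticsModel()


@pytest.fixture(scope="session")
def small_phantom():
    """Fast phantom: 8 mm CTV sphere + OAR + upstream bone-like slab."""
    cfg = PipelineConfig(ctv_radius_mm=8.0)
    grid, structures = generate_phantom(default_phantom_spec(cfg))
    return grid, structures


@pytest.fixture(scope="session")
def small_plan(small_phantom):
    """Conformally weighted two-beam plan on the small phantom."""
    import dataclasses

    grid, structures = small_phantom
    spec = dataclasses.replace(plan_spec_preset("two_beam"), **SMOKE_PLAN_OVERRIDES)
    return generate_plan(grid, structures, spec, seed=11)


@pytest.fixture
def zero_truth():
    return ErrorModelTruth(systematic_x_mm=0.0, systematic_y_mm=0.0,
                           random_sigma_x_mm=0.0, random_sigma_y_mm=0.0,
                           mu_noise_frac=0.0, pulse_jitter_sigma_mm=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
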