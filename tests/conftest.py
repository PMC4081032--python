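import numpy as np
import pytest

import firescape as fs
from firescape.types import VegClass


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    return fs.DomainConfig(n_rows=30, n_cols=30, seed=7)


@pytest.fixture
def small_landscape(small_config):
    return fs.generate_landscape(small_config)


def uniform_landscape(n_rows, n_cols, veg_class, age=100, pixel_area=1.0):
    """Single-class landscape with a constant stand age."""
    veg = np.full((n_rows, n_cols), int(veg_class), dtype=np.int8)
    if veg_class == VegClass.ROCK_ICE:
        ages = np.full((n_rows, n_cols), -1, dtype=np.int32)
    else:
        ages = np.full((n_rows, n_cols), age, dtype=np.int32)
    return fs.LandscapeState(veg=veg, age=ages, pixel_area=pixel_area)


def toy_ensemble(burn, veg=None, age=None, pixel_area=1.0, label=""):
    """RunEnsemble from explicit arrays (fires left empty)."""
    burn = np.asarray(burn, dtype=bool)
    n_runs, n_years, n_rows, n_cols = burn.shape
    if veg is None:
        veg = np.full(burn.shape, int(VegClass.TUNDRA), dtype=np.int8)
    if age is None:
        age = np.full(burn.shape, 100, dtype=np.int32)
    fires = [[[] for _ in range(n_years)] for _ in range(n_runs)]
    return fs.RunEnsemble(burn=burn, veg=veg, age=age, fires=fires,
                          pixel_area=pixel_area, label=label)


@pytest.fixture
def constant_hazard_params():
    """Flammability setup with no fuel ramp, no spread, uniform scalars:
    every fuel pixel burns independently with the same probability."""
    from scipy.special import logit

    p = 0.01
    beta0 = float(logit(p) - 0.09 * 11 + 0.002 * 300)
    scalars = {c: (0.0 if c == VegClass.ROCK_ICE else 1.0) for c in VegClass}
    return fs.FlammabilityParams(
        beta0=beta0, veg_scalar=scalars, fuel_age_scale=0.0, spread_factor=0.0
    ), p
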