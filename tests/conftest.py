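"""Shared fixtures.

The expensive stochastic-Liouville field sweeps are session scoped and
shared between the feature, single-extremum and model-ranking tests; the
radial and field grids are the package defaults (81 radial nodes from the
contact distance 0.49 nm to 1.6 nm; logarithmic field grids over
0.1 mT - 9.4 T).
"""

import warnings

import numpy as np
import pytest

import fadcidnp as fc
from fadcidnp.distributions import PRESETS, default_grid


@pytest.fixture(scope="session")
def model():
    """Published parameter set with the package's calibrated exchange law."""
    return fc.BiradicalModel()


@pytest.fixture(scope="session")
def grid():
    return default_grid()


@pytest.fixture(scope="session")
def sim1_weights(grid):
    return fc.distribution_weights(PRESETS["sim1"], grid)


@pytest.fixture(scope="session")
def sim1_curve(model, grid):
    """Default 61-point sweep for the best-fit (normal) distance distribution."""
    return fc.field_sweep(fc.default_field_grid(), model, grid, PRESETS["sim1"])


@pytest.fixture(scope="session")
def preset_curves(model, grid):
    """31-point sweeps for all four candidate distance distributions."""
    fields = fc.default_field_grid(n=31)
    out = {}
    for name, dist in PRESETS.items():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # sim4's off-grid centre warns
            out[name] = fc.field_sweep(fields, model, grid, dist)
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(20210413)
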