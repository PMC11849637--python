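"""Shared fixtures: one deterministic phantom, its targets and its plan.

The default phantom (no jitter) is expensive enough to build once per
session; tests that mutate masks must copy them.
"""

import numpy as np
import pytest

import subfrax as sx


@pytest.fixture(scope="session")
def phantom():
    grid, structures = sx.generate_patient(
        sx.PhantomParams(size_jitter_frac=0.0, offset_jitter_mm=0.0)
    )
    return grid, structures


@pytest.fixture(scope="session")
def targets(phantom):
    _, structures = phantom
    return sx.recreate_targets(structures)


@pytest.fixture(scope="session")
def plan(targets):
    return sx.plan_dose(targets["ptv"])


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def small_grid():
    return sx.ImageGrid.centered((24, 24, 24), (2.0, 2.0, 2.0))
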