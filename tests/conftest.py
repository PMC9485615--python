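"""Shared fixtures: reduced-size geometry so unit tests stay fast.

Channel counts and grid refinements below the production defaults are used
wherever the property under test does not depend on problem size.
"""

import numpy as np
import pytest

from vmhsim import (
    HeadModel,
    build_grid,
    gain_matrix,
    helmet_catalog,
    synthetic_helmet,
)
from vmhsim.inverse import LeadfieldSolver


@pytest.fixture(scope="session")
def head():
    return HeadModel()


@pytest.fixture(scope="session")
def base_small():
    """64-channel synthetic helmet: same coverage, fewer sensors."""
    return synthetic_helmet(n_channels=64)


@pytest.fixture(scope="session")
def base_full():
    return synthetic_helmet()


@pytest.fixture(scope="session")
def tiny_grid(head):
    """Coarse grid (icosphere subdivisions=1, ~70 points) for oracles."""
    return build_grid(head, subdivisions=1)


@pytest.fixture(scope="session")
def small_grid(head):
    """Medium grid (subdivisions=2, ~270 points)."""
    return build_grid(head, subdivisions=2)


@pytest.fixture(scope="session")
def catalog_small(base_small, head):
    return {h.serial: h for h in helmet_catalog(base_small, head)}


@pytest.fixture(scope="session")
def gain_small(catalog_small, small_grid, head):
    """Standard-helmet gain on the medium grid (64 x 2P)."""
    return gain_matrix(catalog_small[1], small_grid, head)


@pytest.fixture(scope="session")
def gain_tiny(catalog_small, tiny_grid, head):
    return gain_matrix(catalog_small[1], tiny_grid, head)


@pytest.fixture(scope="session")
def solver_small(gain_small):
    return LeadfieldSolver(gain_small)


@pytest.fixture()
def rng():
    return np.random.default_rng(20261001)
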