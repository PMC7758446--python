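"""Shared fixtures: default parameter sets and cached trees/solves."""

from __future__ import annotations

import numpy as np
import pytest

from asymlung import (
    GasProperties,
    GeometryParams,
    SpeciesParams,
    generate_tree,
    solve_flow,
)
from asymlung.scenarios import fixture_tree


@pytest.fixture(scope="session")
def geom() -> GeometryParams:
    return GeometryParams()


@pytest.fixture(scope="session")
def sp() -> SpeciesParams:
    return SpeciesParams()


@pytest.fixture(scope="session")
def gas() -> GasProperties:
    return GasProperties()


@pytest.fixture(scope="session")
def symmetric_tree():
    return fixture_tree(5, symmetric=True)


@pytest.fixture(scope="session")
def asymmetric_tree():
    return fixture_tree(6, symmetric=False, seed=3)


@pytest.fixture(scope="session")
def reference_tree():
    """One full reference lung geometry (seed 1), reused by slow tests."""
    return generate_tree(GeometryParams(seed=1))


@pytest.fixture(scope="session")
def reference_expiration_flow(reference_tree, gas):
    return solve_flow(reference_tree, gas, tracheal_flow=50e-6,
                      direction="expiration")
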