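"""Shared fixtures: species sets, coefficient matrices, small cycle configs."""

import numpy as np
import pytest

from replinet.core import (
    HOST,
    PARASITE,
    CoefficientMatrix,
    DynamicsConfig,
    Species,
)
from replinet.cycle import CycleConfig


@pytest.fixture
def host1():
    return Species("H1", HOST)


@pytest.fixture
def host2():
    return Species("H2", HOST)


@pytest.fixture
def parasite1():
    return Species("P1", PARASITE)


@pytest.fixture
def hp_matrix(host1, parasite1):
    """Experimental-range HP matrix (host 2.3, parasite 7.0)."""
    return CoefficientMatrix(
        [host1, parasite1], coeffs={("H1", "H1"): 2.3, ("H1", "P1"): 7.0}
    )


@pytest.fixture
def table1_matrix(host1, host2, parasite1):
    """The experimentally estimated HHP coefficient set."""
    return CoefficientMatrix(
        [host1, host2, parasite1],
        coeffs={
            ("H1", "H1"): 2.3,
            ("H2", "H1"): 2.3,
            ("H1", "H2"): 2.3,
            ("H2", "H2"): 2.0,
            ("H1", "P1"): 6.7,
            ("H2", "P1"): 0.0,
        },
    )


@pytest.fixture
def default_cfg():
    return CycleConfig()


@pytest.fixture
def small_cfg():
    """Down-scaled cycle for structural tests (fast, same mechanics)."""
    return CycleConfig(
        compartments=200, fusion_frequency=300, rounds=10, seed=0
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
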