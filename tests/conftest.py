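"""Shared fixtures: baseline parameters, small networks, fast solver settings."""

import numpy as np
import pytest

from lymphnet.model_core import PhysicalParams
from lymphnet.solver import BoundaryConditions, SolverSettings
from lymphnet.topology import build_bifurcating_network, contraction_schedule


@pytest.fixture(scope="session")
def params():
    return PhysicalParams()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20160204)


@pytest.fixture(scope="session")
def small_topology():
    """3 generations, 2 lymphangions per vessel: all segment kinds present."""
    return build_bifurcating_network(3, 2)


@pytest.fixture(scope="session")
def small_schedule(small_topology, params):
    return contraction_schedule(small_topology, 0.5, 0.5, params.Tc, params.tr)


@pytest.fixture(scope="session")
def baseline_bc():
    return BoundaryConditions.from_cmh2o(6.0, 9.0, 2.0)


@pytest.fixture(scope="session")
def fast_settings():
    """Short transient policy for property tests (not for quantitative runs)."""
    return SolverSettings(min_cycles=4, max_cycles=60, samples_per_cycle=48)


def random_diameters(rng, params, n):
    """Diameters spanning collapse to strong distension.

    The upper bound stays at 1.1 c9: beyond that the exponential tube-law
    term reaches >1e10 dyn/cm^2, states the dynamics never visit. Midpoint
    pressures then span ~[3e3, 7e6] dyn/cm^2, exercising open, shut and
    failed (prolapsed) valve regimes across the network.
    """
    return rng.uniform(0.5 * params.c9, 1.1 * params.c9, size=n)
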