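"""Shared fixtures: toy graphs, random-graph generators, and the
session-scoped reference simulations the acceptance tests share."""

from __future__ import annotations

import numpy as np
import pytest

import capflow as cf
from capflow.testing import dense_pressure_oracle, random_tree_graph  # noqa: F401


@pytest.fixture
def toy_y():
    """Symmetric capillary Y: 8 um mother, 6 um daughters, equal outlets."""
    return cf.generate_toy_bifurcation(8.0, 6.0, 6.0, 100.0, 40.0, 10.0, 10.0)


@pytest.fixture(scope="session")
def reference_lattice():
    """The study's reference synthetic network (seed 1 defaults)."""
    return cf.generate_lattice_mvn(cf.SynthConfig(seed=1))


@pytest.fixture(scope="session")
def reference_run_rbc(reference_lattice):
    """Full-model steady-state run on the reference lattice (expensive)."""
    return cf.run_simulation(reference_lattice, cf.SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def reference_run_pps(reference_lattice):
    """Passive-particle steady-state run on the reference lattice."""
    return cf.run_simulation(
        reference_lattice, cf.SimulationConfig(seed=1, variant="passive_particles")
    )
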