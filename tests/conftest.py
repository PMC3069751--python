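import numpy as np
import pytest

from xtalrefine import (
    SimulationSpec,
    default_dictionary,
    make_toy_structure,
    simulate_observations,
)


@pytest.fixture(scope="session")
def dictionary():
    return default_dictionary()


@pytest.fixture(scope="session")
def polyala5():
    """5-residue ideal polyalanine in P1."""
    return make_toy_structure(SimulationSpec(n_residues=5, seed=1))


@pytest.fixture(scope="session")
def p21_fixture():
    """Small P21 structure with noise-free observations to 2.5 A."""
    spec = SimulationSpec(n_residues=4, spacegroup="P 21", d_min=2.5, seed=2)
    st = make_toy_structure(spec)
    rset = simulate_observations(st, spec)
    return st, rset


@pytest.fixture(scope="session")
def p1_refine_fixture():
    """10-residue P1 toy with noise-free data at 2.0 A (refinement tests)."""
    spec = SimulationSpec(n_residues=10, d_min=2.0, seed=7)
    st = make_toy_structure(spec)
    rset = simulate_observations(st, spec)
    return st, rset, spec


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
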