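import numpy as np
import pytest

import mcmca
from mcmca import (
    Participant,
    PathwaySpec,
    Reaction,
    SamplingConfig,
    builtin_proline_pathway,
    builtin_thermo,
    structural_analysis,
)


@pytest.fixture(scope="session")
def proline():
    return builtin_proline_pathway()


@pytest.fixture(scope="session")
def proline_structure(proline):
    return structural_analysis(proline)


@pytest.fixture(scope="session")
def lp_thermo():
    return builtin_thermo("lp")


@pytest.fixture(scope="session")
def ml_thermo():
    return builtin_thermo("ml")


@pytest.fixture(scope="session")
def lp_ensemble(proline, lp_thermo):
    """A moderately sized seeded ensemble reused across tests."""
    return mcmca.run_ensemble(
        proline, lp_thermo, SamplingConfig(n_runs=300, seed=11), condition="lp"
    )


@pytest.fixture()
def two_step_chain():
    """Linear chain X -> S -> Y with one internal metabolite."""
    return PathwaySpec(
        metabolites=["S"],
        externals=["X", "Y"],
        reactions=[
            Reaction("R1", substrates=(Participant("X"),), products=(Participant("S"),)),
            Reaction("R2", substrates=(Participant("S"),), products=(Participant("Y"),)),
        ],
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
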