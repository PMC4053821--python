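import numpy as np
import pytest

import coalscan as cs


@pytest.fixture(scope="session")
def panel():
    """The bundled 10-ingroup + outgroup species tree."""
    return cs.default_panel()


@pytest.fixture(scope="session")
def quartet_model():
    """4-taxon (((P1,P2),P3),O) model with a 1-coalescent-unit internal
    branch (Ne = 10 000, duration 20 000 generations)."""
    nwk = "(((P1:10000,P2:10000):20000,P3:30000):100000,O:130000);"
    return cs.SpeciesTreeModel.from_newick(nwk, ne=10000, mu=2e-8, outgroup="O")


@pytest.fixture(scope="session")
def null_genome(panel):
    """One pulse-free simulated genome shared across read-only tests."""
    cfg = cs.SimulationConfig(panel, n_windows=500, window_length=5000, seed=20)
    return cs.simulate_genome(cfg, return_trees=True)


@pytest.fixture(scope="session")
def pileup_fixture():
    """100-kbp synthetic pileup with injected artifacts and truth labels."""
    return cs.simulate_pileup(length=100_000, coverage=12.0, seed=31)
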