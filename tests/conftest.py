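import numpy as np
import pandas as pd
import pytest

from oilqsar import load_library
from oilqsar.graph import MolecularGraph
from oilqsar.published import descriptor_table


@pytest.fixture(scope="session")
def library():
    return load_library()


@pytest.fixture(scope="session")
def by_id(library):
    return {r.id: r for r in library}


@pytest.fixture(scope="session")
def graphs(library):
    return {r.id: r.graph() for r in library}


@pytest.fixture(scope="session")
def fixtures_pool():
    """Printed-table descriptor pool (with computed nROR)."""
    return descriptor_table()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def pcymene():
    return MolecularGraph.from_smiles("CC(C)c1ccc(C)cc1")


@pytest.fixture(scope="session")
def thymol():
    return MolecularGraph.from_smiles("Cc1ccc(C(C)C)c(O)c1")


@pytest.fixture(scope="session")
def small_regression():
    gen = np.random.default_rng(7)
    X = pd.DataFrame(gen.normal(size=(20, 4)), columns=list("abcd"))
    y = pd.Series(1.5 + 2.0 * X["a"] - X["c"] + gen.normal(0, 0.3, size=20))
    return X, y
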