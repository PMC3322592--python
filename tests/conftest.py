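import numpy as np
import pytest

import fragweaver.fixtures as fx
from fragweaver import build_database


@pytest.fixture(scope="session")
def varied_chain():
    return fx.make_varied_chain(250, seed=11)


@pytest.fixture(scope="session")
def varied_db(varied_chain):
    """A single continuous 250-residue chain of mixed conformation."""
    return fx.make_test_database([varied_chain])


@pytest.fixture(scope="session")
def mixed_db():
    """Helix + strand + varied chain: three continuous fragments."""
    return fx.make_test_database(
        [fx.make_ideal_helix(30), fx.make_ideal_strand(30),
         fx.make_varied_chain(140, seed=5)]
    )


@pytest.fixture(scope="session")
def hairpin_db():
    """Database containing the tidying fixtures' source folds."""
    return fx.make_test_database(
        [fx.make_helix_hairpin(22), fx.make_helix_hairpin(15),
         fx.make_varied_chain(120, seed=5)]
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
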