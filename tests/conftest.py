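import warnings

import pytest

from barrelfold import (BlockFrequencyTable, FixtureSpec, make_barrel_fixture,
                        make_training_set, train_block_table)


@pytest.fixture(scope="session", autouse=True)
def _quiet_nonstandard_warnings():
    warnings.filterwarnings("ignore", message=".*non-standard residue.*")
    yield


@pytest.fixture(scope="session")
def training10():
    """Small labeled training set, mirroring a tiny curated collection."""
    return make_training_set(10, seed=42)


@pytest.fixture(scope="session")
def table10(training10):
    return train_block_table(training10)


@pytest.fixture(scope="session")
def table40():
    """Filter trained at the scale of the real non-redundant training set."""
    return train_block_table(make_training_set(40, seed=42))


@pytest.fixture(scope="session")
def planted():
    """A held-out noiseless 8-strand barrel with known ground truth."""
    return make_barrel_fixture(FixtureSpec(seed=777))


@pytest.fixture
def toy_table():
    """Exact frequencies from the worked toy example (no smoothing):

    f(strand, AAA) = 8, f(other, AAA) = 2, both row totals 10.
    """
    t = BlockFrequencyTable(3, pseudocount=0.0)
    t.add("strand", "AAA", 8)
    t.add("strand", "CCC", 2)
    t.add("other", "AAA", 2)
    t.add("other", "CCC", 8)
    return t
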