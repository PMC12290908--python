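import numpy as np
import pytest

from rrmcea import FixtureSpec, Realism, generate_fixture
from rrmcea.tables import AgeRateTable


@pytest.fixture(scope="session")
def paper_bundle():
    """The curated bundle embedding the printed anchor values."""
    return generate_fixture(FixtureSpec(realism=Realism.PAPER_LIKE))


@pytest.fixture(scope="session")
def random_bundle_factory():
    def make(seed: int):
        return generate_fixture(FixtureSpec(seed=seed, realism=Realism.RANDOM_VALID))

    return make


def flat_table(start: int, end: int, value: float) -> AgeRateTable:
    """Constant annual probability over [start, end)."""
    ages = np.arange(start, end)
    return AgeRateTable(ages, np.full(len(ages), value))
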