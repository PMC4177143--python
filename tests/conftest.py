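import numpy as np
import pytest

from tempomine.mine import Transaction
from tempomine.records import default_ranges


@pytest.fixture(scope="session")
def ranges():
    return default_ranges()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_transactions(rng, n_transactions, n_items, density=0.4):
    """Random transaction set over items A..; every transaction non-empty."""
    universe = [chr(ord("A") + i) for i in range(n_items)]
    out = []
    for i in range(n_transactions):
        items = {it for it in universe if rng.random() < density}
        if not items:
            items = {universe[int(rng.integers(n_items))]}
        out.append(Transaction(f"t{i}", frozenset(items)))
    return out


@pytest.fixture
def small_transactions(rng):
    return random_transactions(rng, 20, 6)
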