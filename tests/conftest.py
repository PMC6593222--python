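import numpy as np
import pytest
import biom
from hypothesis import settings

from biomdex.kvstore import MemoryStore

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")


@pytest.fixture
def store():
    return MemoryStore()


def make_table(counts, features, samples) -> biom.Table:
    """Dense counts (features x samples) -> biom Table."""
    return biom.Table(np.asarray(counts, dtype=float), list(features),
                      list(samples))


@pytest.fixture
def toy_table():
    # 3 features x 2 samples; S1 contains f_a and f_c, S2 contains f_b
    return make_table([[1, 0], [0, 5], [2, 0]],
                      ["f_a", "f_b", "f_c"], ["S1", "S2"])


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
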