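import numpy as np
import pytest

from icshapemap import simulate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_spec():
    return simulate.SimSpec(n_transcripts=5, stem_len=6, loop_len=4,
                            depth=200, seed=42)


@pytest.fixture(scope="session")
def small_hairpins(small_spec):
    return simulate.make_hairpin_set(small_spec)
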