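import numpy as np
import pytest

from urfkit import load_genetic_code, make_fixture


@pytest.fixture(scope="session")
def code4():
    """Mold/protozoan/coelenterate mitochondrial code (62 sense codons)."""
    return load_genetic_code(4)


@pytest.fixture(scope="session")
def code1():
    return load_genetic_code("standard")


@pytest.fixture(scope="session")
def beroe_like():
    return make_fixture("beroe-like", seed=101)


@pytest.fixture(scope="session")
def separable_toy():
    return make_fixture("separable-toy", seed=202)


@pytest.fixture(scope="session")
def neutral_null():
    return make_fixture("neutral-null", seed=303)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
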