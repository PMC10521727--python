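import numpy as np
import pytest

from gdpanedit import (default_guides, synthetic_g4_reference,
                       synthetic_reference, truncated_guides)


@pytest.fixture(scope="session")
def reference():
    return synthetic_reference()


@pytest.fixture(scope="session")
def g4_reference():
    return synthetic_g4_reference()


@pytest.fixture(scope="session")
def guides(reference):
    return default_guides(reference)


@pytest.fixture(scope="session")
def trunc_guides(reference):
    return truncated_guides(reference, 0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20220801)


def random_dna(rng, n, gc_rich=False):
    p = [0.2, 0.3, 0.3, 0.2] if gc_rich else None
    return "".join(rng.choice(list("ACGT"), size=n, p=p))
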