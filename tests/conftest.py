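import numpy as np
import pytest

from polq_scars.constructs import (
    distal_amplicon_reference,
    ej5_joined_reference,
    ej5_reference,
    hprt_reference,
)


@pytest.fixture(scope="session")
def ej5():
    return ej5_reference()


@pytest.fixture(scope="session")
def ej5_joined():
    return ej5_joined_reference()


@pytest.fixture(scope="session")
def distal_amplicon():
    return distal_amplicon_reference()


@pytest.fixture(scope="session")
def hprt():
    return hprt_reference()


@pytest.fixture()
def rng():
    return np.random.default_rng(20200827)


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))
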