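import numpy as np
import pytest

from spacedwords import build_rotation_table


@pytest.fixture(scope="session")
def rtab():
    return build_rotation_table(42)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def random_protein(rng, n):
    return "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=n))
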