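import numpy as np
import pytest

from phagekit.datasets import load_orf_table


@pytest.fixture(scope="session")
def orf_df():
    """The bundled 79-row reference ORF table."""
    return load_orf_table()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)


def random_protein(rng, n: int) -> str:
    return "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=n))


def random_dna(rng, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))
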