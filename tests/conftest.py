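import numpy as np
import pytest

from g4kit import generate_records


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20161201)


@pytest.fixture(scope="session")
def record_store():
    """200 synthetic interaction records, the first three being the fixed
    worked-example anchors (Nucleolin/G4DIP1, PMID 25679041, FMRP)."""
    return generate_records(200, seed=7, anchors=True)


def random_dna(rng, length, gc=0.4):
    p_g = p_c = gc / 2
    p_a = p_t = (1 - gc) / 2
    return "".join(rng.choice(list("ACGT"), size=length, p=[p_a, p_c, p_g, p_t]))
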