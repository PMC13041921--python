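import numpy as np
import pytest

from satarch.synthetic import make_monomer_library, random_dna


@pytest.fixture(scope="session")
def alpha_lib():
    """Two ~170 bp monomer families at 20% mutual divergence (S3/S4-like)."""
    return make_monomer_library(2, 170, 0.20, seed=7, names=["S3", "S4"])


@pytest.fixture(scope="session")
def single_lib():
    """One 171 bp monomer family (subterminal-satellite-like)."""
    return make_monomer_library(1, 171, 0.20, seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_random_dna(length: int, seed: int) -> str:
    return random_dna(length, np.random.default_rng(seed))


def hamming(a: str, b: str) -> float:
    assert len(a) == len(b)
    return sum(x != y for x, y in zip(a, b)) / len(a)
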