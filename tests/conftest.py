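import numpy as np
import pytest

from seqgauge import Alphabet, ModelSpec, ParameterVector

SEED = 20240512


@pytest.fixture
def binary():
    return Alphabet.from_string("01")


@pytest.fixture
def dna():
    return Alphabet.from_string("ACGT")


@pytest.fixture
def rng():
    return np.random.default_rng(SEED)


@pytest.fixture
def random_theta():
    """Factory for reproducible standard-normal parameter vectors."""

    def make(spec: ModelSpec, seed: int = SEED) -> ParameterVector:
        gen = np.random.default_rng(seed)
        return ParameterVector(spec, gen.standard_normal(spec.n_features))

    return make
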