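import numpy as np
import pytest

from polyutr import GeneratorConfig, Theta, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A 60-record synthetic library shared by the cheaper model tests."""
    cfg = GeneratorConfig(n=60, n_polya=48)
    return generate_dataset(cfg, seed=7)


def random_dna(rng: np.random.Generator, length: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(list(alphabet), size=length))
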