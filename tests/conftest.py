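import numpy as np
import pytest

from cretrace.aligner import ScoringScheme
from cretrace.synthetic_data import SyntheticConfig


@pytest.fixture(scope="session")
def scheme() -> ScoringScheme:
    return ScoringScheme()


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """Compact locus architecture for fast unit tests (not the study scale)."""
    return SyntheticConfig(
        exon_lengths=(100, 100, 100),
        intron_lengths=(500, 500),
        flank_length=450,
        seed=42,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def random_dna(rng: np.random.Generator, n: int, gc: float = 0.4) -> str:
    g = gc / 2
    a = (1 - gc) / 2
    return "".join(rng.choice(list("GCAT"), p=[g, g, a, a], size=n))
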