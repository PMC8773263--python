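import numpy as np
import pytest

from lightgrn import synthetic_data
from lightgrn.pfm_scan import MarkovBackground


@pytest.fixture
def uniform_background() -> MarkovBackground:
    """Order-0 background with exactly uniform base probabilities."""
    return MarkovBackground(
        order=0,
        transition=np.full((1, 4), 0.25),
        stationary=np.full(4, 0.25),
        context_probs=np.ones(1),
    )


@pytest.fixture(scope="session")
def regulatory_fixture_17():
    """The small planted-GRN fixture (seed 17) shared across test modules."""
    return synthetic_data.generate_regulatory_fixture(
        n_tfs=5, n_genes=200, n_global_regulators=3, seed=17
    )


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
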