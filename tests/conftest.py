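import numpy as np
import pytest

from linkedlmm.design import build_design
from linkedlmm.linking import fit_linked_sequential
from linkedlmm.lmm import fit_lmm
from linkedlmm.simdata import (
    SimConfig,
    generate_corpus,
    slim_duration_spec,
    slim_location_spec,
)


@pytest.fixture(scope="session")
def tiny_config():
    """Desk-scale world: 12 subjects x 20 sentences (~1.4k rows)."""
    return SimConfig.reduced(n_subjects=12, n_sentences=20)


@pytest.fixture(scope="session")
def tiny_corpus(tiny_config):
    return generate_corpus(tiny_config, seed=7)


@pytest.fixture(scope="session")
def tiny_fit1(tiny_corpus):
    return fit_lmm(build_design(slim_location_spec(), tiny_corpus.table))


@pytest.fixture(scope="session")
def linked_both(tiny_corpus, tiny_fit1):
    return fit_linked_sequential(
        tiny_corpus.table, None, slim_duration_spec(), mode="both",
        fit1=tiny_fit1,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
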