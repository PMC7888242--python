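from pathlib import Path

import pandas as pd
import pytest

from igf import (
    ControlPolicy,
    DynamicsParams,
    TargetingConfig,
    build_sentence,
    generate_corpus,
)

FIXTURES = Path(__file__).parent / "fixtures"


@pytest.fixture(scope="session")
def default_dynamics():
    return DynamicsParams()


@pytest.fixture(scope="session")
def default_policy():
    return ControlPolicy()


@pytest.fixture(scope="session")
def default_targeting():
    return TargetingConfig()


@pytest.fixture(scope="session")
def small_corpus():
    return generate_corpus(30, words_per_sentence=(5, 8), seed=123)


@pytest.fixture
def plain_sentence():
    """Six 5-letter words, neutral attributes, no anomalies."""
    return build_sentence(
        lengths=[5] * 6,
        log_freqs=[0.0] * 6,
        predictabilities=[0.3] * 6,
    )


def load_scanpath(name: str) -> pd.DataFrame:
    return pd.read_csv(FIXTURES / f"scanpath_{name}.csv")
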