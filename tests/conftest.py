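import numpy as np
import pytest

from abstractqual.corpus import (
    CovariateVector,
    Document,
    RiskOfBiasRecord,
    Score,
)


@pytest.fixture
def rob_all_yes():
    return RiskOfBiasRecord(tuple([Score.YES] * 12))


@pytest.fixture
def toy_doc():
    return Document.from_text("toy", "The cat sat. The dog ran.")


@pytest.fixture
def six_word_doc():
    return Document.from_text("six", "The cat sat on the mat.")


@pytest.fixture
def example_covariate():
    return CovariateVector(
        intervention="device",
        condition="neoplasms",
        design="parallel",
        control="placebo",
        arms_flag=1,
        sample_size=100,
    )


@pytest.fixture(scope="session")
def small_synthetic():
    """Small corpus reused by several slow-ish tests."""
    from abstractqual.synthetic import SyntheticSpec, generate_corpus

    return generate_corpus(SyntheticSpec(D=120, V=120, doc_length_mean=40.0, seed=11))


def make_rob(yes=0, no=0, unsure=0):
    assert yes + no + unsure == 12
    return RiskOfBiasRecord(
        tuple([Score.YES] * yes + [Score.NO] * no + [Score.UNSURE] * unsure)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
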