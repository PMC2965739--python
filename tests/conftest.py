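import warnings
from pathlib import Path

import pytest

from geneforce.rules import AmbiguousPrecedenceWarning
from geneforce.synthetic import (
    adversarial_threshold_model,
    generate_planted_model,
    toy_condition,
    toy_figure1_model,
    toy_isozyme_variant,
)

DATA = Path(__file__).parent / "data"


@pytest.fixture(autouse=True)
def _quiet_precedence_warnings():
    # Published rule strings legitimately mix NOT/OR at one depth; the
    # warning is aimed at rule authors, not at every test run.
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", AmbiguousPrecedenceWarning)
        yield


@pytest.fixture
def toy_model():
    return toy_figure1_model()


@pytest.fixture
def toy_cond():
    return toy_condition()


@pytest.fixture
def iso_model():
    return toy_isozyme_variant()


@pytest.fixture
def adversarial():
    return adversarial_threshold_model()


@pytest.fixture
def planted_factory():
    return generate_planted_model


@pytest.fixture
def published_rule_strings():
    lines = (DATA / "regulatory_rule_strings.txt").read_text().splitlines()
    return [l for l in lines if l.strip() and not l.startswith("#")]
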