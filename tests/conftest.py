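"""Shared fixtures: one default synthetic panel and one trained model,
built once per session because several test modules exercise them."""

from __future__ import annotations

import pytest

from fiasma.learner import train_model
from fiasma.synthetic import GeneratorConfig, generate_experimental_set, generate_library


@pytest.fixture(scope="session")
def default_experiment():
    return generate_experimental_set(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def labeled(default_experiment):
    return default_experiment.labeled_matrix()


@pytest.fixture(scope="session")
def trained_model(labeled):
    matrix, labels = labeled
    return train_model(matrix, labels)


@pytest.fixture(scope="session")
def natural_library():
    return generate_library(GeneratorConfig(seed=1), "natural_like")


@pytest.fixture(scope="session")
def drug_library():
    return generate_library(GeneratorConfig(seed=1), "drug_like")
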