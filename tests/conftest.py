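import logging

import pytest

from symptomkb import synth, web
from symptomkb.schema import KnowledgeBase

logging.disable(logging.INFO)


@pytest.fixture(scope="session")
def small_config() -> synth.GeneratorConfig:
    """Scaled-down study conditions for fast unit tests."""
    return synth.GeneratorConfig(
        seed=7,
        n_symptoms=20, n_diseases=12, n_medicines=8, n_departments=8,
        n_examinations=6,
        ency_pages_per_label=12, ency_seeds_per_label=6,
        n_records=40, n_train_records=25,
        n_exact_links=10, n_near_miss=10,
    )


@pytest.fixture(scope="session")
def healthcare_fixture(small_config) -> synth.HealthcareFixture:
    return synth.generate_healthcare_site(small_config)


@pytest.fixture(scope="session")
def extracted_kb(small_config, healthcare_fixture) -> KnowledgeBase:
    kb = KnowledgeBase()
    for site in small_config.sites:
        web.extract_site(healthcare_fixture.pages[site], site,
                         healthcare_fixture.wrappers[site], kb=kb)
    return kb


@pytest.fixture(scope="session")
def ency_fixture(small_config, healthcare_fixture) -> synth.EncyclopediaFixture:
    seeds = synth.healthcare_seed_labels(healthcare_fixture.truth)
    return synth.generate_encyclopedia(small_config, seeds)


@pytest.fixture(scope="session")
def emr_fixture(small_config) -> synth.EMRFixture:
    return synth.generate_emr_corpus(small_config)


@pytest.fixture(scope="session")
def linking_fixture(small_config) -> synth.LinkingFixture:
    return synth.generate_linking_fixture(small_config)
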