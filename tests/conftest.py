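import pytest

from pwudflag import GeneratorConfig, PhraseBank, default_lexicon, generate_corpus


@pytest.fixture(scope="session")
def lexicon():
    return default_lexicon()


@pytest.fixture(scope="session")
def bank():
    return PhraseBank()


@pytest.fixture(scope="session")
def small_corpus(lexicon):
    """A reproducible 200-encounter synthetic cohort with generous prevalence."""
    cfg = GeneratorConfig(n_encounters=200, prevalence=0.3, seed=11)
    encounters, gold, truth = generate_corpus(cfg, lexicon=lexicon)
    return cfg, encounters, gold, truth
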