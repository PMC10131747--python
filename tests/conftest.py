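import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from tnstager.config import load_config
from tnstager.preprocessing import clean_text, split_sentences, tag_numbers
from tnstager.types import RawReport, Section, Sentence


@pytest.fixture(scope="session")
def config():
    """Shipped English lexicon + TNM-8 rules, loaded once."""
    return load_config()


@pytest.fixture(scope="session")
def lexicon(config):
    return config.lexicon


@pytest.fixture(scope="session")
def rules(config):
    return config.rules


def make_sentence(text: str, section: str = "report", base: int = 0) -> Sentence:
    """A standalone tagged sentence for unit tests (span starts at `base`)."""
    sent = Sentence(section, (base, base + len(text)), text)
    return tag_numbers(sent)


@pytest.fixture
def sentence_factory():
    return make_sentence
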