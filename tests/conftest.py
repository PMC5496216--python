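import pytest

from meshlingua import GOLD_QUESTIONS, build_fixture_thesaurus


@pytest.fixture(scope="session")
def thesaurus():
    return build_fixture_thesaurus()


@pytest.fixture(scope="session")
def gold_questions():
    return GOLD_QUESTIONS
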