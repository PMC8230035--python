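import datetime as dt

import pytest

from mediascorecard import (
    Article,
    default_helpline_registry,
    default_lexicon,
)


@pytest.fixture(scope="session")
def lexicon():
    return default_lexicon()


@pytest.fixture(scope="session")
def registry():
    return default_helpline_registry()


def make_article(body="", headline="", **kwargs):
    defaults = dict(
        article_id="a1",
        newspaper="The Daily Test",
        publication_date=dt.date(2020, 5, 1),
        headline=headline,
        body=body,
    )
    defaults.update(kwargs)
    return Article(**defaults)


@pytest.fixture
def article_factory():
    return make_article
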