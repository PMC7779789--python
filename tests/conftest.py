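import datetime as dt

import pytest

from emoprosocial import Lexicon, LexiconEntry, SimulationConfig, generate_dataset


@pytest.fixture(scope="session")
def tiny_config() -> SimulationConfig:
    """Small-corpus study conditions for fast end-to-end tests."""
    return SimulationConfig(posts_per_day=(60, 120))


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config):
    return generate_dataset(tiny_config, seed=20200120)


@pytest.fixture
def toy_lexicons():
    """Hand-sized lexicons with known weights for exact-score checks."""
    emotion = Lexicon(
        entries=[
            LexiconEntry("joyword", "happiness", 3.0),
            LexiconEntry("rageword", "anger", 6.5),
            LexiconEntry("bothword", "sadness", 2.0),
            LexiconEntry("bothword", "fear", 4.0),  # multi-category term
        ],
        kind="emotion",
    )
    prosocial = Lexicon(
        entries=[
            LexiconEntry("helpword", "prosocial", 8.2),
            LexiconEntry("giveword", "prosocial", 7.0),
            LexiconEntry("careword", "prosocial", 5.0),
        ],
        kind="prosocial",
    )
    return emotion, prosocial, ["not", "never"]


@pytest.fixture
def study_window():
    return dt.date(2020, 1, 20), dt.date(2020, 2, 29)
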