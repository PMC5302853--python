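import pytest

from textcal.calorimetry import RegionLemmaCounts
from textcal.lexicon import Lexicon, LexiconEntry, Side


@pytest.fixture
def food_lexicon():
    return Lexicon(
        Side.INPUT,
        [
            LexiconEntry(("pizza",), "F1", 266.0),
            LexiconEntry(("apples",), "F2", 52.0),
            LexiconEntry(("ice", "cream"), "F3", 207.0),
        ],
    )


@pytest.fixture
def activity_lexicon():
    return Lexicon(
        Side.OUTPUT,
        [
            LexiconEntry(("running",), "A1", 8.0),
            LexiconEntry(("watching", "tv"), "A2", 1.3),
        ],
    )


@pytest.fixture
def two_lemma_lexicon():
    """The worked shift example: lemma a scores 100, lemma b scores 300."""
    return Lexicon(
        Side.INPUT,
        [LexiconEntry(("a",), "a", 100.0), LexiconEntry(("b",), "b", 300.0)],
    )


def region_counts(region, side, counts):
    return RegionLemmaCounts(region=region, side=side, counts=dict(counts))
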