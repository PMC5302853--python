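"""Serial text partitioning: clause segmentation and phrase extraction.

The extraction model works in two corpus-level passes:

1. *Random-partition frequencies.*  Treat every clause of length ``L`` as
   receiving boundaries independently with probability 1/2 at each of its
   ``L - 1`` internal gaps (clause edges are certain boundaries).  The
   frequency ``f(s)`` of a phrase ``s`` is then the expected number of
   times ``s`` appears as a partition cell across the corpus: each
   contiguous occurrence of an ``l``-token phrase contributes
   ``(1/2)**(l-1)`` for its internal gaps, times a further ``1/2`` for
   each clause-interior flank.

2. *Context-local likelihood.*  A phrase of length ``l`` belongs to ``l``
   one-wildcard context patterns (e.g. ``(new, york, city)`` belongs to
   ``(*, york, city)``, ``(new, *, city)``, ``(new, york, *)``).  The
   likelihood ``L(s)`` is ``f(s)`` divided by the total ``f`` of phrases
   matching a context, minimized over the phrase's contexts — the most
   prevalent (least committal) context wins.

A clause is then segmented greedily left to right: the current phrase is
grown by the next token while the likelihood strictly increases, and
flushed to the partition otherwise.  Lexicon lemmas are counted only when
a partition cell *exactly* equals a lexicon phrase, so "apple" inside an
extracted "apple of my eye" never counts toward the apple lemma.
"""
from __future__ import annotations

import itertools
import re
from collections import Counter
from dataclasses import dataclass
from typing import TYPE_CHECKING, Dict, Iterable, List, Optional, Sequence, Tuple

from ._tokenize import normalize_token

if TYPE_CHECKING:  # pragma: no cover
    from .lexicon import Lexicon

Phrase = Tuple[str, ...]

#: Placeholder token marking the wildcard slot of a context pattern.
#: U+2217 is stripped from real tokens by normalization, so no corpus
#: token can collide with it.
WILDCARD = "∗"

#: Default cap on extracted phrase length, in tokens.
DEFAULT_MAX_LEN = 5

#: Lemmas with corpus-wide count below this are dropped (occurrences of
#: four or fewer are treated as noise).
DEFAULT_MIN_COUNT = 5

_URL_RE = re.compile(r"(?:https?://|www\.)\S+")
_MENTION_TAG_RE = re.compile(r"[@#]\S+")
_CLAUSE_BREAK_RE = re.compile(r"[.!?;:]+")


@dataclass(frozen=True)
class Clause:
    """A punctuation-delimited run of normalized tokens from one message."""

    tokens: Phrase
    source_message_id: str = ""
    region: str = ""

    def __len__(self) -> int:
        return len(self.tokens)


@dataclass
class PhraseStats:
    """Random-partition frequencies ``f`` for phrases up to ``max_len`` tokens."""

    f: Dict[Phrase, float]
    max_len: int


@dataclass
class ContextIndex:
    """Total ``f`` pooled over the member phrases of each context pattern."""

    totals: Dict[Phrase, float]


@dataclass(frozen=True)
class Partition:
    """A lossless segmentation of one clause into phrase cells."""

    cells: Tuple[Phrase, ...]
    clause: Clause


def segment_clauses(
    message_text: str, message_id: str = "", region: str = ""
) -> List[Clause]:
    """Split raw message text into normalized clauses.

    Lowercases, removes URLs, user mentions (``@...``) and hashtags
    (``#...``), breaks clauses at sentence punctuation (``. ! ? ; :``),
    and strips residual punctuation from tokens.  May return an empty
    list.
    """
    text = message_text.lower()
    text = _URL_RE.sub(" ", text)
    text = _MENTION_TAG_RE.sub(" ", text)
    clauses: List[Clause] = []
    for piece in _CLAUSE_BREAK_RE.split(text):
        tokens = [t for t in (normalize_token(raw) for raw in piece.split()) if t]
        if tokens:
            clauses.append(Clause(tuple(tokens), message_id, region))
    return clauses


def random_partition_frequency(
    clauses: Iterable[Clause], max_len: int = DEFAULT_MAX_LEN
) -> PhraseStats:
    """Accumulate expected cell counts ``f(s)`` over a corpus of clauses.

    For an occurrence of an ``l``-token phrase at positions ``i..j`` of a
    clause of length ``L`` the contributed weight is
    ``(1/2)**(l-1) * (1/2 if i > 0) * (1/2 if j < L-1)`` (0-based,
    inclusive), i.e. boundaries are forced at both phrase flanks and
    forbidden inside it.
    """
    if max_len < 1:
        raise ValueError(f"max_len must be >= 1, got {max_len}")
    f: Dict[Phrase, float] = {}
    for clause in clauses:
        toks = clause.tokens
        L = len(toks)
        for i in range(L):
            left = 0.5 if i > 0 else 1.0
            weight = left
            stop = min(i + max_len, L)
            for j in range(i, stop):
                w = weight if j == L - 1 else weight * 0.5
                key = toks[i : j + 1]
                f[key] = f.get(key, 0.0) + w
                weight *= 0.5
    return PhraseStats(f=f, max_len=max_len)


def exact_partition_frequency(
    clauses: Iterable[Clause], max_len: int = DEFAULT_MAX_LEN, limit: int = 20
) -> Dict[Phrase, float]:
    """Brute-force oracle for ``f``: average cell counts over all boundary
    configurations of each clause (``2**(L-1)`` of them), keeping cells of
    at most ``max_len`` tokens.  Exponential; refuses clauses longer than
    ``limit`` tokens.
    """
    f: Dict[Phrase, float] = {}
    for clause in clauses:
        toks = clause.tokens
        L = len(toks)
        if L > limit:
            raise ValueError(f"clause of length {L} exceeds enumeration limit {limit}")
        weight = 0.5 ** (L - 1)
        for gaps in itertools.product((0, 1), repeat=L - 1):
            start = 0
            for pos, cut in enumerate(list(gaps) + [1], start=1):
                if cut:
                    if pos - start <= max_len:
                        cell = toks[start:pos]
                        f[cell] = f.get(cell, 0.0) + weight
                    start = pos
    return f


def contexts(phrase: Phrase) -> List[Phrase]:
    """The ``len(phrase)`` one-wildcard context patterns of a phrase."""
    if len(phrase) < 1:
        raise ValueError("empty phrase has no contexts")
    return [phrase[:k] + (WILDCARD,) + phrase[k + 1 :] for k in range(len(phrase))]


def build_context_index(stats: PhraseStats) -> ContextIndex:
    """Pool ``f`` over the members of every context pattern."""
    totals: Dict[Phrase, float] = {}
    for phrase, weight in stats.f.items():
        for k in range(len(phrase)):
            pattern = phrase[:k] + (WILDCARD,) + phrase[k + 1 :]
            totals[pattern] = totals.get(pattern, 0.0) + weight
    return ContextIndex(totals=totals)


def local_likelihood(phrase: Phrase, stats: PhraseStats, index: ContextIndex) -> float:
    """Context-local likelihood ``L(s)`` in [0, 1].

    Zero on the empty phrase, on phrases never observed, and on phrases
    longer than the frequency cap; otherwise the minimum over the
    phrase's contexts of ``f(s) / total f(context)``.
    """
    n = len(phrase)
    if n == 0 or n > stats.max_len:
        return 0.0
    fs = stats.f.get(phrase, 0.0)
    if fs == 0.0:
        return 0.0
    totals = index.totals
    best = 1.0
    for k in range(n):
        pattern = phrase[:k] + (WILDCARD,) + phrase[k + 1 :]
        p = fs / totals[pattern]
        if p < best:
            best = p
    return best


def serial_partition(clause: Clause, stats: PhraseStats, index: ContextIndex) -> Partition:
    """Greedy left-to-right segmentation of one clause.

    The running phrase ``s`` absorbs the next token whenever the
    likelihood of the extended phrase *strictly* exceeds ``L(s)``;
    otherwise ``s`` is flushed as a cell and restarted.  Cells always
    concatenate back to the clause.
    """
    if len(clause) == 0:
        raise ValueError("cannot partition an empty clause")
    cells: List[Phrase] = []
    s: Phrase = ()
    current = 0.0  # L of the empty phrase
    for token in clause.tokens:
        grown = s + (token,)
        value = local_likelihood(grown, stats, index)
        if value > current:
            s = grown
            current = value
        else:
            if s:
                cells.append(s)
            s = (token,)
            current = local_likelihood(s, stats, index)
    if s:
        cells.append(s)
    return Partition(cells=tuple(cells), clause=clause)


def count_lexicon_lemmas(
    partitions: Iterable[Partition],
    lexicon: "Lexicon",
    min_count: int = DEFAULT_MIN_COUNT,
) -> Dict[str, "RegionLemmaCounts"]:
    """Count lexicon lemmas from partition cells, aggregated per region.

    A lexicon phrase is counted once per cell that exactly equals it;
    counts roll up to the phrase's lemma.  Lemmas whose *corpus-wide*
    count is below ``min_count`` are dropped everywhere.  Returns a map
    region -> :class:`~textcal.calorimetry.RegionLemmaCounts`.
    """
    from .calorimetry import RegionLemmaCounts

    per_region: Dict[str, Counter] = {}
    corpus_total: Counter = Counter()
    lemma_of = lexicon.lemma_of
    for part in partitions:
        region = part.clause.region
        for cell in part.cells:
            lemma = lemma_of(cell)
            if lemma is not None:
                per_region.setdefault(region, Counter())[lemma] += 1
                corpus_total[lemma] += 1
    keep = {lemma for lemma, n in corpus_total.items() if n >= min_count}
    result: Dict[str, RegionLemmaCounts] = {}
    for region, counts in sorted(per_region.items()):
        kept = {lemma: float(n) for lemma, n in counts.items() if lemma in keep}
        if kept:
            result[region] = RegionLemmaCounts(
                region=region, side=lexicon.side, counts=kept
            )
    return result
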