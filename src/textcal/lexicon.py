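"""Food and activity phrase lexicons with caloric scores.

A lexicon is a side-specific table of phrases grouped into *lemmas*:
categorically equivalent phrases ("mash potatoes" / "mashed potatoes")
that share one caloric score.  The input (food) side carries kcal per
100 g; the output (activity) side carries MET values (Metabolic
Equivalent of Task, multiples of resting metabolic rate) which are
converted to kcal expended per hour at a reference body mass —
1 MET = 1 kcal per kg of body mass per hour.

File format: UTF-8 TSV with header ``phrase<TAB>lemma<TAB>score``;
phrase tokens are space-separated and normalized on load.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Tuple

from ._tokenize import phrase_from_text

Phrase = Tuple[str, ...]

#: Average weight of a North American adult, in kilograms; the reference
#: mass at which METs are converted to kcal per hour.
DEFAULT_BODY_MASS_KG = 80.7


class LexiconError(ValueError):
    """Raised for malformed or inconsistent lexicon content."""


class Side(str, Enum):
    """Which half of the caloric balance a lexicon scores."""

    INPUT = "input"    # food: kcal per 100 g
    OUTPUT = "output"  # activity: MET -> kcal per hour


def met_to_kcal_per_hour(met: float, body_mass_kg: float = DEFAULT_BODY_MASS_KG) -> float:
    """Convert a MET value to kcal expended per hour at the given body mass.

    1 MET is 1 kcal per kg of body mass per hour, so the conversion is the
    plain product ``met * body_mass_kg``.

    Raises
    ------
    ValueError
        If ``met`` or ``body_mass_kg`` is not strictly positive.
    """
    if met <= 0:
        raise ValueError(f"MET must be positive, got {met}")
    if body_mass_kg <= 0:
        raise ValueError(f"body mass must be positive, got {body_mass_kg}")
    return met * body_mass_kg


@dataclass(frozen=True)
class LexiconEntry:
    """One phrase row: token tuple, lemma id, and raw score.

    ``raw_score`` is kcal/100 g for food entries and MET for activity
    entries; the per-hour conversion happens at the lexicon level where
    the body mass is known.
    """

    phrase: Phrase
    lemma_id: str
    raw_score: float

    def __post_init__(self) -> None:
        if len(self.phrase) < 1:
            raise LexiconError(f"empty phrase for lemma {self.lemma_id!r}")
        if any(not tok for tok in self.phrase):
            raise LexiconError(f"blank token in phrase {self.phrase!r}")
        if self.raw_score < 0:
            raise LexiconError(
                f"negative score {self.raw_score} for phrase {' '.join(self.phrase)!r}"
            )


class Lexicon:
    """A validated, side-specific phrase->lemma->score table.

    Validation enforced at construction:

    * no phrase appears twice within the side;
    * every entry of a lemma carries the same raw score (lemmas group
      phrases that are *scored identically* by construction, so a
      mismatch is a data error, not something to average away);
    * activity (output-side) scores must be strictly positive METs.
    """

    def __init__(
        self,
        side: Side | str,
        entries: Iterable[LexiconEntry],
        body_mass_kg: float = DEFAULT_BODY_MASS_KG,
    ) -> None:
        if body_mass_kg <= 0:
            raise LexiconError(f"body mass must be positive, got {body_mass_kg}")
        self.side = Side(side)
        self.body_mass_kg = float(body_mass_kg)
        self._entries: List[LexiconEntry] = []
        self._phrase_to_lemma: Dict[Phrase, str] = {}
        raw_by_lemma: Dict[str, float] = {}
        for entry in entries:
            if entry.phrase in self._phrase_to_lemma:
                raise LexiconError(
                    f"duplicate phrase {' '.join(entry.phrase)!r} in {self.side.value} lexicon"
                )
            if self.side is Side.OUTPUT and entry.raw_score <= 0:
                raise LexiconError(
                    f"activity phrase {' '.join(entry.phrase)!r} has non-positive MET "
                    f"{entry.raw_score}"
                )
            known = raw_by_lemma.get(entry.lemma_id)
            if known is not None and known != entry.raw_score:
                raise LexiconError(
                    f"lemma {entry.lemma_id!r} carries inconsistent scores "
                    f"{known} and {entry.raw_score}"
                )
            raw_by_lemma[entry.lemma_id] = entry.raw_score
            self._phrase_to_lemma[entry.phrase] = entry.lemma_id
            self._entries.append(entry)
        if not self._entries:
            raise LexiconError("lexicon has no entries")
        if self.side is Side.OUTPUT:
            self._lemma_score = {
                lemma: met_to_kcal_per_hour(met, self.body_mass_kg)
                for lemma, met in raw_by_lemma.items()
            }
        else:
            self._lemma_score = dict(raw_by_lemma)
        self._raw_by_lemma = raw_by_lemma

    # -- introspection -------------------------------------------------
    @property
    def entries(self) -> Tuple[LexiconEntry, ...]:
        return tuple(self._entries)

    @property
    def lemmas(self) -> Tuple[str, ...]:
        return tuple(sorted(self._lemma_score))

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, phrase: Phrase) -> bool:
        return tuple(phrase) in self._phrase_to_lemma

    def lemma_of(self, phrase: Phrase) -> Optional[str]:
        """Lemma id for an exactly-matching phrase, else ``None``."""
        return self._phrase_to_lemma.get(tuple(phrase))

    def phrases_for(self, lemma_id: str) -> List[Phrase]:
        return [e.phrase for e in self._entries if e.lemma_id == lemma_id]

    def lemma_score(self, lemma_id: str) -> float:
        """Caloric score of a lemma: kcal/100 g (food) or kcal/hour (activity)."""
        try:
            return self._lemma_score[lemma_id]
        except KeyError:
            raise LexiconError(
                f"unknown lemma {lemma_id!r} in {self.side.value} lexicon"
            ) from None

    def scores(self) -> Dict[str, float]:
        """lemma id -> caloric score, for all lemmas."""
        return dict(self._lemma_score)


def lemma_score(lexicon: Lexicon, lemma_id: str) -> float:
    """Functional alias for :meth:`Lexicon.lemma_score`."""
    return lexicon.lemma_score(lemma_id)


_COLUMNS = ("phrase", "lemma", "score")


def load_lexicon(
    path: str | Path,
    side: Side | str,
    body_mass_kg: float = DEFAULT_BODY_MASS_KG,
) -> Lexicon:
    """Load and validate a lexicon TSV (columns ``phrase, lemma, score``)."""
    path = Path(path)
    entries: List[LexiconEntry] = []
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        missing = [c for c in _COLUMNS if reader.fieldnames is None or c not in reader.fieldnames]
        if missing:
            raise LexiconError(f"{path}: missing column(s) {missing}")
        for lineno, row in enumerate(reader, start=2):
            phrase = phrase_from_text(row["phrase"])
            if not phrase:
                raise LexiconError(f"{path}:{lineno}: empty phrase")
            try:
                score = float(row["score"])
            except (TypeError, ValueError):
                raise LexiconError(
                    f"{path}:{lineno}: non-numeric score {row['score']!r}"
                ) from None
            entries.append(LexiconEntry(phrase, row["lemma"].strip(), score))
    return Lexicon(side, entries, body_mass_kg=body_mass_kg)


def write_lexicon(lexicon: Lexicon, path: str | Path) -> None:
    """Write a lexicon back to TSV; inverse of :func:`load_lexicon`."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(_COLUMNS)
        for entry in lexicon.entries:
            writer.writerow([" ".join(entry.phrase), entry.lemma_id, repr(entry.raw_score)])
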