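"""End-to-end orchestration: corpus -> clauses -> partitions -> profiles.

Phrase statistics are corpus-level functions of the whole text, so the
pipeline makes two passes: a first pass builds the random-partition
frequencies and the context index, a second pass partitions every clause
against them and counts lexicon lemmas from the resulting cells.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

from .calorimetry import CaloricProfile, RegionLemmaCounts, build_profiles
from .lexicon import Lexicon
from .partition import (
    DEFAULT_MAX_LEN,
    DEFAULT_MIN_COUNT,
    Clause,
    ContextIndex,
    Partition,
    PhraseStats,
    build_context_index,
    count_lexicon_lemmas,
    random_partition_frequency,
    segment_clauses,
    serial_partition,
)
from .synthetic import read_corpus_jsonl


@dataclass
class PipelineResult:
    counts_in: Dict[str, RegionLemmaCounts]
    counts_out: Dict[str, RegionLemmaCounts]
    profiles: List[CaloricProfile]
    n_messages: int
    n_clauses: int


def corpus_clauses(records: Iterable[Mapping[str, str]]) -> List[Clause]:
    """Segment every message record into clauses carrying its region label."""
    clauses: List[Clause] = []
    n = 0
    for record in records:
        n += 1
        clauses.extend(
            segment_clauses(record["text"], record.get("id", ""), record["region"])
        )
    return clauses


def partition_corpus(
    clauses: Sequence[Clause], max_len: int = DEFAULT_MAX_LEN
) -> List[Partition]:
    """Two-pass partitioning of a clause corpus."""
    stats = random_partition_frequency(clauses, max_len=max_len)
    index = build_context_index(stats)
    return [serial_partition(clause, stats, index) for clause in clauses]


def score_corpus(
    records: Iterable[Mapping[str, str]],
    lexicon_in: Lexicon,
    lexicon_out: Lexicon,
    max_len: int = DEFAULT_MAX_LEN,
    min_count: int = DEFAULT_MIN_COUNT,
    alpha: Optional[float] = None,
) -> PipelineResult:
    """Run the full instrument over a message corpus.

    ``alpha`` of ``None`` picks the mean-matching value across regions.
    """
    records = list(records)
    clauses = corpus_clauses(records)
    partitions = partition_corpus(clauses, max_len=max_len)
    counts_in = count_lexicon_lemmas(partitions, lexicon_in, min_count=min_count)
    counts_out = count_lexicon_lemmas(partitions, lexicon_out, min_count=min_count)
    profiles = build_profiles(counts_in, counts_out, lexicon_in, lexicon_out, alpha=alpha)
    return PipelineResult(
        counts_in=counts_in,
        counts_out=counts_out,
        profiles=profiles,
        n_messages=len(records),
        n_clauses=len(clauses),
    )


def score_corpus_file(
    corpus_path: str | Path,
    lexicon_in: Lexicon,
    lexicon_out: Lexicon,
    **kwargs,
) -> PipelineResult:
    return score_corpus(read_corpus_jsonl(corpus_path), lexicon_in, lexicon_out, **kwargs)
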