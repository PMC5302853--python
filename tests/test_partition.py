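import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from textcal.lexicon import Lexicon, LexiconEntry, Side
from textcal.partition import (
    Clause,
    build_context_index,
    contexts,
    count_lexicon_lemmas,
    exact_partition_frequency,
    local_likelihood,
    random_partition_frequency,
    segment_clauses,
    serial_partition,
)


def build(clauses, max_len=5):
    stats = random_partition_frequency(clauses, max_len=max_len)
    return stats, build_context_index(stats)


class TestSegmentation:
    @pytest.mark.parametrize(
        "text, expected",
        [
            ("I LOVE Pizza", [("i", "love", "pizza")]),
            ("Eating #pizza with @bob at http://x.co", [("eating", "with", "at")]),
            ("pizza. running", [("pizza",), ("running",)]),
            ("so... many!! breaks?", [("so",), ("many",), ("breaks",)]),
            ("#only @mentions http://x.co", []),
            ("don't stop", [("don't", "stop")]),
        ],
    )
    def test_clause_rules(self, text, expected):
        assert [c.tokens for c in segment_clauses(text)] == expected

    def test_labels_carried(self):
        clauses = segment_clauses("a. b", message_id="m1", region="VT")
        assert all(c.source_message_id == "m1" and c.region == "VT" for c in clauses)


class TestRandomPartitionFrequency:
    def test_single_token_clause(self):
        stats, _ = build([Clause(("a",))])
        assert stats.f == {("a",): 1.0}

    def test_three_token_clause_exact_values(self):
        # Enumerating the 4 boundary configurations of (a, b, c) by hand.
        stats, _ = build([Clause(("a", "b", "c"))])
        assert stats.f == {
            ("a",): 0.5,
            ("b",): 0.25,
            ("c",): 0.5,
            ("a", "b"): 0.25,
            ("b", "c"): 0.25,
            ("a", "b", "c"): 0.25,
        }

    def test_replicated_clause_scales_linearly(self):
        clauses = [Clause(("new", "york", "city"))] * 4
        stats, _ = build(clauses)
        assert stats.f == {
            ("new",): 2.0,
            ("york",): 1.0,
            ("city",): 2.0,
            ("new", "york"): 1.0,
            ("york", "city"): 1.0,
            ("new", "york", "city"): 1.0,
        }

    def test_max_len_caps_phrases(self):
        stats, _ = build([Clause(("a", "b", "c"))], max_len=1)
        assert set(stats.f) == {("a",), ("b",), ("c",)}

    @given(
        clause_tokens=st.lists(
            st.lists(st.sampled_from("abcd"), min_size=1, max_size=10).map(tuple),
            min_size=1,
            max_size=4,
        )
    )
    @settings(max_examples=60, derandomize=True)
    def test_matches_enumeration_oracle(self, clause_tokens):
        """The closed-form weights equal the exact average cell counts over
        all 2**(L-1) boundary configurations."""
        clauses = [Clause(t) for t in clause_tokens]
        stats, _ = build(clauses)
        oracle = exact_partition_frequency(clauses, max_len=5)
        assert set(stats.f) == set(oracle)
        for phrase, expected in oracle.items():
            assert stats.f[phrase] == pytest.approx(expected, abs=1e-12)

    def test_unrelated_clause_leaves_f_unchanged(self):
        base = [Clause(("a", "b"))]
        stats_before, _ = build(base)
        stats_after, _ = build(base + [Clause(("x", "y", "z"))])
        for phrase, value in stats_before.f.items():
            assert stats_after.f[phrase] == value


class TestContexts:
    def test_three_token_phrase_has_three_contexts(self):
        patterns = contexts(("new", "york", "city"))
        assert len(patterns) == 3
        assert all(len(p) == 3 for p in patterns)

    @pytest.mark.parametrize("phrase, n", [(("a",), 1), (("a", "b"), 2), (("a", "b", "c", "d"), 4)])
    def test_context_count_equals_length(self, phrase, n):
        pats = contexts(phrase)
        assert len(pats) == n
        # the k-th pattern wildcards exactly position k
        for k, pat in enumerate(pats):
            assert sum(tok != phrase[i] for i, tok in enumerate(pat)) == 1
            assert pat[k] != phrase[k]

    def test_empty_phrase_rejected(self):
        with pytest.raises(ValueError):
            contexts(())


class TestLocalLikelihood:
    def test_empty_phrase_is_zero(self):
        stats, index = build([Clause(("a",))])
        assert local_likelihood((), stats, index) == 0.0

    def test_unobserved_phrase_is_zero(self):
        stats, index = build([Clause(("a", "b"))])
        assert local_likelihood(("z",), stats, index) == 0.0

    def test_hand_trace_values(self):
        stats, index = build([Clause(("new", "york", "city"))] * 4)
        assert local_likelihood(("new",), stats, index) == pytest.approx(0.4)
        assert local_likelihood(("new", "york"), stats, index) == 1.0

    @given(
        clause_tokens=st.lists(
            st.lists(st.sampled_from("abc"), min_size=1, max_size=6).map(tuple),
            min_size=1,
            max_size=4,
        )
    )
    @settings(max_examples=60, derandomize=True)
    def test_bounded_in_unit_interval(self, clause_tokens):
        clauses = [Clause(t) for t in clause_tokens]
        stats, index = build(clauses)
        for phrase in stats.f:
            value = local_likelihood(phrase, stats, index)
            assert 0.0 < value <= 1.0

    def test_unity_iff_unique_in_every_context(self):
        # (a b) shares context (∗, b) with (c b), so neither reaches 1;
        # (x y) is alone in both of its contexts.
        stats, index = build([Clause(("a", "b")), Clause(("c", "b")), Clause(("x", "y"))])
        assert local_likelihood(("a", "b"), stats, index) < 1.0
        assert local_likelihood(("x", "y"), stats, index) == 1.0


class TestSerialPartition:
    def test_single_token_clause(self):
        clause = Clause(("a",))
        stats, index = build([clause])
        assert serial_partition(clause, stats, index).cells == (("a",),)

    def test_hand_trace(self):
        clauses = [Clause(("new", "york", "city"))] * 4
        stats, index = build(clauses)
        part = serial_partition(clauses[0], stats, index)
        assert part.cells == (("new", "york"), ("city",))

    def test_growth_requires_strict_increase(self):
        # Both contexts of every bigram here are saturated at likelihood 1
        # after the first pair, so ties flush.
        clause = Clause(("p", "q", "r"))
        stats, index = build([clause] * 3)
        part = serial_partition(clause, stats, index)
        flat = tuple(tok for cell in part.cells for tok in cell)
        assert flat == clause.tokens
        assert part.cells == (("p", "q"), ("r",))

    @given(
        clause_tokens=st.lists(
            st.lists(st.sampled_from("abcd"), min_size=1, max_size=8).map(tuple),
            min_size=1,
            max_size=5,
        )
    )
    @settings(max_examples=60, derandomize=True)
    def test_partition_is_lossless(self, clause_tokens):
        clauses = [Clause(t) for t in clause_tokens]
        stats, index = build(clauses)
        for clause in clauses:
            part = serial_partition(clause, stats, index)
            assert tuple(tok for cell in part.cells for tok in cell) == clause.tokens


class TestLemmaCounting:
    @pytest.fixture
    def apple_lexicon(self):
        return Lexicon(Side.INPUT, [LexiconEntry(("apple",), "F_APPLE", 52.0)])

    def test_exact_cell_match_counts(self, apple_lexicon):
        clause = Clause(("apple",), region="VT")
        stats, index = build([clause])
        counts = count_lexicon_lemmas(
            [serial_partition(clause, stats, index)], apple_lexicon, min_count=1
        )
        assert counts["VT"].counts == {"F_APPLE": 1.0}

    def test_token_inside_larger_cell_not_counted(self, apple_lexicon):
        # "apple of my eye" repeated: the partition cells are multiword, so
        # the bare lemma never matches.
        clauses = [Clause(("apple", "of", "my", "eye"), region="VT")] * 5
        stats, index = build(clauses)
        parts = [serial_partition(c, stats, index) for c in clauses]
        assert all(("apple",) not in p.cells for p in parts)
        assert count_lexicon_lemmas(parts, apple_lexicon, min_count=1) == {}

    def test_counts_are_additive_within_region(self, apple_lexicon):
        clauses = [Clause(("apple",), region="VT")] * 2
        stats, index = build(clauses)
        parts = [serial_partition(c, stats, index) for c in clauses]
        counts = count_lexicon_lemmas(parts, apple_lexicon, min_count=1)
        assert counts["VT"].counts == {"F_APPLE": 2.0}

    def test_min_count_drops_rare_lemmas_corpus_wide(self, apple_lexicon):
        clauses = [Clause(("apple",), region="VT")] * 4
        stats, index = build(clauses)
        parts = [serial_partition(c, stats, index) for c in clauses]
        assert count_lexicon_lemmas(parts, apple_lexicon, min_count=5) == {}
        kept = count_lexicon_lemmas(parts, apple_lexicon, min_count=4)
        assert kept["VT"].counts == {"F_APPLE": 4.0}
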