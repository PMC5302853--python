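"""Token normalization shared by lexicon loading and corpus segmentation.

All text entering the instrument passes through the same normalization so
that lexicon phrases and corpus tokens live in one space: Unicode NFKC,
lowercase, leading/trailing punctuation and symbol characters (including
emoji) stripped.  Tokens that are emptied by stripping are dropped.
"""
from __future__ import annotations

import unicodedata
from typing import List, Tuple


def normalize_token(token: str) -> str:
    """Return the canonical form of a single whitespace-delimited token.

    May return the empty string (caller drops such tokens).
    """
    token = unicodedata.normalize("NFKC", token).lower()
    start, end = 0, len(token)
    while start < end and unicodedata.category(token[start])[0] in "PS":
        start += 1
    while end > start and unicodedata.category(token[end - 1])[0] in "PS":
        end -= 1
    return token[start:end]


def tokenize(text: str) -> List[str]:
    """Split on whitespace and normalize, dropping emptied tokens."""
    return [t for t in (normalize_token(raw) for raw in text.split()) if t]


def phrase_from_text(text: str) -> Tuple[str, ...]:
    """Normalize a space-separated phrase string into a token tuple."""
    return tuple(tokenize(text))
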