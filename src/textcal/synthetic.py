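"""Synthetic lexicons, corpora, and indicator tables with known ground truth.

The generator emulates the inputs the instrument consumes:

* fixture food/activity lexicons with realistic score ranges (kcal/100 g
  on [20, 600]; METs on [0.95, 14]) and multi-token phrases;
* a region-labelled message corpus in which each message embeds one
  phrase drawn from a per-region multinomial over lemmas, surrounded by
  filler tokens, together with the exact planted counts;
* indicator tables whose columns are noisy monotone transforms of chosen
  caloric measures, plus independent null columns.

Planted phrases are inserted as punctuation-delimited clauses of their
own, with filler runs in neighbouring clauses.  This keeps ground-truth
counts exact: the filler vocabulary is disjoint from lexicon tokens (the
explicit decoy idiom excepted), and each planted phrase is recovered as a
single partition cell.  For phrases of three or more tokens that takes
deliberate ambiguity — a phrase whose prefixes are the *only* observed
members of their contexts saturates the partitioner's likelihood at 1
after two tokens and gets split — so such phrases are accompanied by
"confuser" clauses sharing their leading tokens, which hold the prefix
likelihoods strictly below 1 and let the greedy growth run to the full
phrase.  Real text supplies this ambiguity for free; the generator has to
plant it.

All randomness flows from one seed through named substreams
(``numpy.random.default_rng([seed, stream])``), so outputs are
byte-identical across runs.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .calorimetry import CaloricProfile, caloric_difference
from .correlate import IndicatorTable
from .lexicon import Lexicon, LexiconEntry, Side

Phrase = Tuple[str, ...]

#: The decoy idiom: contains the food token "apple" but is not a lexicon
#: phrase, so a correct extractor must never let it feed the apple lemma.
DECOY_IDIOM: Phrase = ("apple", "of", "my", "eye")

#: Filler vocabulary, disjoint by construction from every lexicon token.
FILLER_VOCAB: Tuple[str, ...] = tuple(f"w{i:02d}" for i in range(40))

# Hand-curated seed entries; scores are typical nutrient-table /
# activity-compendium values.  "apple" must stay first (decoy anchor) and
# a multi-token phrase second so even 2-entry lexicons exercise both.
_BASE_FOODS: Tuple[Tuple[Phrase, str, float], ...] = (
    (("apple",), "F0001", 52.0),
    (("ice", "cream"), "F0002", 207.0),
    (("pizza",), "F0003", 266.0),
    (("peanut", "butter", "cup"), "F0004", 515.0),
    (("mac", "and", "cheese", "bake"), "F0005", 164.0),
    (("green", "beans"), "F0006", 31.0),
)
_BASE_ACTIVITIES: Tuple[Tuple[Phrase, str, float], ...] = (
    (("running",), "A0001", 8.0),
    (("rock", "climbing"), "A0002", 11.0),
    (("watching", "tv"), "A0003", 1.3),
    (("shoveling", "heavy", "snow"), "A0004", 7.5),
    (("talking", "on", "the", "phone"), "A0005", 1.5),
    (("walking",), "A0006", 3.5),
)

_STREAM_LEXICON = 1
_STREAM_PROFILES = 2
_STREAM_CORPUS = 3
_STREAM_INDICATORS = 4
_STREAM_PANEL = 5


@dataclass
class UsageProfile:
    """Planted phrase usage for one region on one side."""

    region: str
    side: Side
    multinomial: Dict[str, float]  # lemma -> probability, sums to 1
    messages: int
    filler_rate: float = 0.6  # target fraction of filler tokens per message

    def __post_init__(self) -> None:
        if self.messages < 1:
            raise ValueError("messages must be >= 1")
        total = sum(self.multinomial.values())
        if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-9):
            raise ValueError(f"multinomial sums to {total}, not 1")
        if not 0.0 <= self.filler_rate < 1.0:
            raise ValueError("filler_rate must lie in [0, 1)")


@dataclass
class PlantedLink:
    """A monotone link from a caloric measure to an indicator column."""

    name: str
    source: str  # "C_in" | "C_out" | "C_rat" | "C_diff"
    slope: float
    noise_sd: float
    alpha: Optional[float] = None  # only meaningful for C_diff

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _substream(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(stream)])


def make_fixture_lexicons(
    n_food: int = 12, n_activity: int = 12, seed: int = 0
) -> Tuple[Lexicon, Lexicon]:
    """Deterministic fixture lexicons (food, activity).

    The first entries are hand-curated (including "apple", the anchor of
    the decoy idiom, and multi-token phrases up to four tokens); any
    remainder is generated with unique tokens and scores drawn uniformly
    from the realistic ranges.
    """
    if n_food < 2 or n_activity < 2:
        raise ValueError("need at least 2 entries per side")
    rng = _substream(seed, _STREAM_LEXICON)
    foods = [LexiconEntry(*row) for row in _BASE_FOODS[:n_food]]
    for i in range(len(foods), n_food):
        if i % 4 == 0:
            phrase: Phrase = (f"food{i}a", f"food{i}b")
        else:
            phrase = (f"food{i}",)
        foods.append(
            LexiconEntry(phrase, f"F1{i:03d}", round(float(rng.uniform(20.0, 600.0)), 1))
        )
    acts = [LexiconEntry(*row) for row in _BASE_ACTIVITIES[:n_activity]]
    for i in range(len(acts), n_activity):
        if i % 4 == 0:
            phrase = (f"act{i}a", f"act{i}b")
        else:
            phrase = (f"act{i}",)
        acts.append(
            LexiconEntry(phrase, f"A1{i:03d}", round(float(rng.uniform(0.95, 14.0)), 2))
        )
    return Lexicon(Side.INPUT, foods), Lexicon(Side.OUTPUT, acts)


def default_usage_profiles(
    lexicon_in: Lexicon,
    lexicon_out: Lexicon,
    n_regions: int = 10,
    messages_per_side: int = 10_000,
    seed: int = 0,
    concentration: float = 1.0,
    filler_rate: float = 0.6,
) -> List[UsageProfile]:
    """One Dirichlet-drawn multinomial per region per side.

    ``concentration`` is the symmetric Dirichlet parameter: 1 gives flat
    random usage mixes, smaller values give spikier regional signatures.
    """
    rng = _substream(seed, _STREAM_PROFILES)
    profiles: List[UsageProfile] = []
    for r in range(n_regions):
        region = f"R{r:02d}"
        for side, lexicon in ((Side.INPUT, lexicon_in), (Side.OUTPUT, lexicon_out)):
            lemmas = lexicon.lemmas
            probs = rng.dirichlet(np.full(len(lemmas), concentration))
            probs = probs / probs.sum()
            profiles.append(
                UsageProfile(
                    region=region,
                    side=side,
                    multinomial=dict(zip(lemmas, probs.tolist())),
                    messages=messages_per_side,
                    filler_rate=filler_rate,
                )
            )
    return profiles


def planted_caloric_means(
    profiles: Sequence[UsageProfile], lexicon: Lexicon
) -> Dict[str, float]:
    """region -> expected caloric score under the planted multinomial."""
    means: Dict[str, float] = {}
    for profile in profiles:
        if profile.side is not lexicon.side:
            continue
        means[profile.region] = sum(
            lexicon.lemma_score(lemma) * p for lemma, p in profile.multinomial.items()
        )
    return means


def _confuser_tokens(lexicon_in: Lexicon, lexicon_out: Lexicon) -> Dict[Phrase, Tuple[str, str]]:
    """Fresh (u, v) tokens per long phrase, never colliding with lexicon
    tokens or fillers."""
    out: Dict[Phrase, Tuple[str, str]] = {}
    idx = 0
    for lexicon in (lexicon_in, lexicon_out):
        for entry in lexicon.entries:
            if len(entry.phrase) >= 3:
                out[entry.phrase] = (f"cu{idx}", f"cv{idx}")
                idx += 1
    return out


def simulate_corpus(
    profiles: Sequence[UsageProfile],
    lexicon_in: Lexicon,
    lexicon_out: Lexicon,
    seed: int = 0,
    decoy_rate: float = 0.0,
) -> Tuple[List[Dict[str, str]], Dict[Tuple[str, str], Dict[str, int]]]:
    """Generate a message corpus plus exact planted counts.

    Each message carries exactly one planted phrase (its own clause),
    filler clauses before/after, confuser clauses for >= 3-token phrases,
    and — with probability ``decoy_rate`` — the decoy idiom as a final
    clause.  Returns ``(records, true_counts)`` where records are JSONL
    dicts ``{"id", "region", "text"}`` and true counts are keyed by
    ``(region, side value)``.
    """
    lex_by_side = {Side.INPUT: lexicon_in, Side.OUTPUT: lexicon_out}
    confusers = _confuser_tokens(lexicon_in, lexicon_out)
    records: List[Dict[str, str]] = []
    true_counts: Dict[Tuple[str, str], Dict[str, int]] = {}
    for p_idx, profile in enumerate(profiles):
        lexicon = lex_by_side[profile.side]
        for lemma in profile.multinomial:
            lexicon.lemma_score(lemma)  # raises on unknown lemma
        rng = _substream(seed, 101 + p_idx)
        lemmas = sorted(profile.multinomial)
        probs = np.array([profile.multinomial[m] for m in lemmas])
        probs = probs / probs.sum()
        counts = true_counts.setdefault((profile.region, profile.side.value), {})
        lemma_draws = rng.choice(len(lemmas), size=profile.messages, p=probs)
        for m_idx in range(profile.messages):
            lemma = lemmas[int(lemma_draws[m_idx])]
            phrases = lexicon.phrases_for(lemma)
            phrase = phrases[int(rng.integers(len(phrases)))]
            counts[lemma] = counts.get(lemma, 0) + 1
            rate = profile.filler_rate
            mean_fill = rate / (1.0 - rate) * len(phrase) if rate > 0 else 0.0
            n_fill = int(rng.poisson(mean_fill)) if mean_fill > 0 else 0
            filler = [FILLER_VOCAB[int(k)] for k in rng.integers(len(FILLER_VOCAB), size=n_fill)]
            n_before = int(rng.integers(n_fill + 1))
            segments: List[List[str]] = []
            if n_before:
                segments.append(filler[:n_before])
            segments.append(list(phrase))
            if n_fill > n_before:
                segments.append(filler[n_before:])
            if len(phrase) >= 3:
                u, v = confusers[phrase]
                segments.append([phrase[0], u])
                if len(phrase) >= 4 and rng.random() < 0.5:
                    segments.append([phrase[0], phrase[1], v])
            if decoy_rate > 0 and rng.random() < decoy_rate:
                segments.append(list(DECOY_IDIOM))
            text = ". ".join(" ".join(seg) for seg in segments) + "."
            records.append(
                {
                    "id": f"{profile.region}-{profile.side.value}-{m_idx:06d}",
                    "region": profile.region,
                    "text": text,
                }
            )
    return records, true_counts


def write_corpus_jsonl(records: Iterable[Mapping[str, str]], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as handle:
        for record in records:
            handle.write(json.dumps(dict(record), ensure_ascii=False) + "\n")


def read_corpus_jsonl(path: str | Path) -> List[Dict[str, str]]:
    records = []
    with Path(path).open(encoding="utf-8") as handle:
        for line in handle:
            line = line.strip()
            if line:
                records.append(json.loads(line))
    return records


def noise_sd_for_spearman(target_rho_s: float, measure_sd: float) -> float:
    """Additive-noise s.d. giving a target population Spearman rho.

    Uses the bivariate-normal identity ``rho_s = (6/pi) asin(r/2)`` to map
    the target rank correlation to a Pearson ``r``, then sizes the noise
    so that ``corr(X, X + e) = r``.
    """
    if not 0.0 < abs(target_rho_s) < 1.0:
        raise ValueError("target rho_s must lie strictly between 0 and 1 in magnitude")
    r = 2.0 * math.sin(math.pi * abs(target_rho_s) / 6.0)
    return measure_sd * math.sqrt(1.0 / r**2 - 1.0)


def simulate_indicators(
    profiles: Sequence[CaloricProfile],
    links: Sequence[PlantedLink],
    n_null: int = 0,
    seed: int = 0,
) -> IndicatorTable:
    """Indicator columns: noisy linear transforms of caloric measures plus
    independent standard-normal null columns."""
    rng = _substream(seed, _STREAM_INDICATORS)
    regions = [p.region for p in profiles]
    data: Dict[str, np.ndarray] = {}
    notes: Dict[str, str] = {}
    for link in links:
        if link.source == "C_in":
            base = np.array([p.c_in for p in profiles])
        elif link.source == "C_out":
            base = np.array([p.c_out for p in profiles])
        elif link.source == "C_rat":
            base = np.array([p.c_rat for p in profiles])
        elif link.source == "C_diff":
            alpha = link.alpha if link.alpha is not None else profiles[0].alpha
            base = np.array([caloric_difference(p.c_in, p.c_out, alpha) for p in profiles])
        else:
            raise ValueError(f"unknown source measure {link.source!r}")
        noise = rng.normal(0.0, link.noise_sd, size=len(base)) if link.noise_sd else 0.0
        data[link.name] = link.slope * base + noise
        notes[link.name] = f"planted on {link.source} (slope {link.slope})"
    for i in range(n_null):
        name = f"null{i:02d}"
        data[name] = rng.normal(0.0, 1.0, size=len(regions))
        notes[name] = "independent null"
    frame = pd.DataFrame(data, index=pd.Index(regions, name="region"))
    return IndicatorTable(data=frame, notes=notes)


def make_profile_panel(
    n_regions: int = 49, seed: int = 0, alpha: float = 0.5
) -> List[CaloricProfile]:
    """A panel of plausible caloric profiles drawn directly (no corpus).

    ``C_in`` is drawn on a kcal/100 g scale around 250-285 and ``C_out``
    on a kcal/hour scale around 160-210, matching the dynamic ranges a
    lexicon-scored national text panel exhibits; ratios and differences
    follow.  Useful for statistical calibration experiments where the
    text pipeline itself is not under study.
    """
    rng = _substream(seed, _STREAM_PANEL)
    c_in = rng.uniform(250.0, 285.0, size=n_regions)
    c_out = rng.uniform(160.0, 210.0, size=n_regions)
    return [
        CaloricProfile(
            region=f"R{i:02d}",
            c_in=float(c_in[i]),
            c_out=float(c_out[i]),
            c_rat=float(c_out[i] / c_in[i]),
            c_diff=caloric_difference(float(c_in[i]), float(c_out[i]), alpha),
            alpha=alpha,
            n_in=1.0,
            n_out=1.0,
        )
        for i in range(n_regions)
    ]


def write_truth_json(
    path: str | Path,
    profiles: Sequence[UsageProfile],
    true_counts: Mapping[Tuple[str, str], Mapping[str, int]],
    links: Sequence[PlantedLink] = (),
    seed: int = 0,
) -> None:
    """Record every planted parameter for downstream assertions."""
    payload = {
        "seed": seed,
        "profiles": [
            {
                "region": p.region,
                "side": p.side.value,
                "messages": p.messages,
                "filler_rate": p.filler_rate,
                "multinomial": p.multinomial,
            }
            for p in profiles
        ],
        "true_counts": {
            f"{region}/{side}": dict(counts)
            for (region, side), counts in sorted(true_counts.items())
        },
        "links": [
            {
                "name": l.name,
                "source": l.source,
                "slope": l.slope,
                "noise_sd": l.noise_sd,
                "alpha": l.alpha,
            }
            for l in links
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")
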