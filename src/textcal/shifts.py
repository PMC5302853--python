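"""Phrase-shift decompositions of caloric differences between texts.

The difference between a comparison text and a reference text factors
exactly over lemmas:

    C(comp) - C(ref) = sum_s [score(s) - C_ref] * [p(s|comp) - p(s|ref)]

(the C_ref term cancels because both usage distributions sum to one).
Each lemma's contribution is normalized to a signed percentage

    delta(s) = 100 * [score(s) - C_ref] * [p_comp(s) - p_ref(s)] / |C_comp - C_ref|

so the contributions sum to +100 when the comparison text scores higher
than the reference and -100 when lower.  Every term falls in one of four
categories from the sign of its score deviation (+/-) and of its usage
deviation (up/down):

    ``+↑``  above-reference score, used more   (raises the measure)
    ``-↓``  below-reference score, used less   (raises the measure)
    ``+↓``  above-reference score, used less   (lowers the measure)
    ``-↑``  below-reference score, used more   (lowers the measure)
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from .calorimetry import RegionLemmaCounts, caloric_score
from .lexicon import Lexicon, Side

#: Category label -> short ASCII key used in exports.
CATEGORY_KEYS = {"+↑": "pu", "-↓": "md", "+↓": "pd", "-↑": "mu"}


@dataclass
class ReferenceDistribution:
    """Equal-weight pooled usage distribution standing in for the
    whole-panel average text."""

    side: Side
    p_ref: Dict[str, float]
    c_ref: float
    label: str = "reference"


@dataclass(frozen=True)
class ShiftTerm:
    lemma_id: str
    delta: float
    score_sign: str  # "+" or "-"
    usage_sign: str  # "↑" or "↓"

    @property
    def category(self) -> str:
        return self.score_sign + self.usage_sign


@dataclass
class ShiftReport:
    """Ranked per-lemma contributions to one comparison-vs-reference shift."""

    side: Side
    comparison: str
    reference: str
    c_comp: float
    c_ref: float
    net: float
    terms: List[ShiftTerm] = field(default_factory=list)

    @property
    def category_totals(self) -> Dict[str, float]:
        totals = {key: 0.0 for key in CATEGORY_KEYS.values()}
        for term in self.terms:
            totals[CATEGORY_KEYS[term.category]] += term.delta
        return totals


def pooled_reference(
    regions: Sequence[RegionLemmaCounts], lexicon: Lexicon, label: str = "pooled"
) -> ReferenceDistribution:
    """Unweighted mean of the per-region usage distributions.

    Every region counts equally regardless of its message volume, mirroring
    an equal-weight panel average.
    """
    if not regions:
        raise ValueError("need at least one region")
    support: set[str] = set()
    for counts in regions:
        if not counts.counts:
            raise ValueError(f"region {counts.region!r} has empty counts")
        if counts.side is not lexicon.side:
            raise ValueError("counts/lexicon side mismatch")
        support.update(counts.p)
    n = len(regions)
    p_ref = {
        lemma: sum(counts.p.get(lemma, 0.0) for counts in regions) / n
        for lemma in sorted(support)
    }
    c_ref = sum(lexicon.lemma_score(lemma) * w for lemma, w in p_ref.items())
    return ReferenceDistribution(side=lexicon.side, p_ref=p_ref, c_ref=c_ref, label=label)


def classify_contribution(
    score: float, c_ref: float, p_comp: float, p_ref: float
) -> str:
    """Category of a single contribution; both deviations must be nonzero
    (zero-deviation terms contribute delta = 0 and are dropped upstream)."""
    if score == c_ref or p_comp == p_ref:
        raise ValueError("zero score- or usage-deviation term has no category")
    score_sign = "+" if score > c_ref else "-"
    usage_sign = "↑" if p_comp > p_ref else "↓"
    return score_sign + usage_sign


def phrase_shift(
    comp: RegionLemmaCounts, ref: ReferenceDistribution, lexicon: Lexicon
) -> ShiftReport:
    """Decompose ``C(comp) - C_ref`` into per-lemma percentage terms.

    Terms are sorted by decreasing ``|delta|`` (lexicographic within ties)
    and exactly-zero terms are omitted.  Raises if the two texts score
    identically (the normalization denominator would vanish).
    """
    if comp.side is not ref.side or comp.side is not lexicon.side:
        raise ValueError("comparison, reference, and lexicon sides must agree")
    c_comp = caloric_score(comp, lexicon)
    denom = abs(c_comp - ref.c_ref)
    if denom == 0.0:
        raise ValueError(
            f"comparison {comp.region!r} and reference {ref.label!r} have equal "
            "caloric scores; the shift is undefined"
        )
    p_comp = comp.p
    terms: List[ShiftTerm] = []
    for lemma in set(p_comp) | set(ref.p_ref):
        pc = p_comp.get(lemma, 0.0)
        pr = ref.p_ref.get(lemma, 0.0)
        score = lexicon.lemma_score(lemma)
        delta = 100.0 * (score - ref.c_ref) * (pc - pr) / denom
        if delta == 0.0:
            continue
        terms.append(
            ShiftTerm(
                lemma_id=lemma,
                delta=delta,
                score_sign="+" if score > ref.c_ref else "-",
                usage_sign="↑" if pc > pr else "↓",
            )
        )
    terms.sort(key=lambda t: (-abs(t.delta), t.lemma_id))
    return ShiftReport(
        side=comp.side,
        comparison=comp.region,
        reference=ref.label,
        c_comp=c_comp,
        c_ref=ref.c_ref,
        net=math.fsum(t.delta for t in terms),
        terms=terms,
    )


def distinguishing_lemma(report: ShiftReport) -> Optional[str]:
    """The increased-usage lemma that most moves the comparison text away
    from the reference in the direction it actually moved.

    Among terms with usage ``↑`` whose delta shares the sign of the net
    shift, returns the largest ``|delta|`` (lexicographic on ties); ``None``
    when no term qualifies.
    """
    if not report.terms:
        raise ValueError("empty shift report")
    sign = 1.0 if report.net > 0 else -1.0
    aligned = [
        t for t in report.terms if t.usage_sign == "↑" and t.delta * sign > 0
    ]
    if not aligned:
        return None
    return min(aligned, key=lambda t: (-abs(t.delta), t.lemma_id)).lemma_id


def report_to_dict(report: ShiftReport, top: Optional[int] = 23) -> Dict:
    """JSON-ready form; ``top`` truncates the term list (``None`` keeps all)."""
    terms = report.terms if top is None else report.terms[:top]
    return {
        "side": report.side.value,
        "comparison": report.comparison,
        "reference": report.reference,
        "c_comp": report.c_comp,
        "c_ref": report.c_ref,
        "net": report.net,
        "category_totals": report.category_totals,
        "terms": [
            {"lemma": t.lemma_id, "delta": t.delta, "category": t.category}
            for t in terms
        ],
    }


def write_shift_json(report: ShiftReport, path: str | Path, top: Optional[int] = 23) -> None:
    Path(path).write_text(
        json.dumps(report_to_dict(report, top=top), ensure_ascii=False, indent=2) + "\n",
        encoding="utf-8",
    )


def write_shift_tsv(report: ShiftReport, path: str | Path, top: Optional[int] = None) -> None:
    """Flat plotting export: lemma, delta, category per line."""
    terms = report.terms if top is None else report.terms[:top]
    with Path(path).open("w", encoding="utf-8") as handle:
        handle.write("lemma\tdelta\tcategory\n")
        for t in terms:
            handle.write(f"{t.lemma_id}\t{t.delta!r}\t{t.category}\n")
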