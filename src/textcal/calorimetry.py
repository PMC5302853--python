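"""Per-region caloric indices and their summaries.

Given per-region lemma counts for the food (input) and activity (output)
sides, each region's text gets:

* ``C_in``  — the score-weighted mean of its food-lemma distribution, in
  kcal per 100 g;
* ``C_out`` — the score-weighted mean of its activity-lemma distribution,
  in kcal per hour at the reference body mass;
* ``C_rat = C_out / C_in`` — a dimensionless comparative index (the value
  1 carries no special meaning);
* ``C_diff(alpha) = alpha * C_out - (1 - alpha) * C_in`` — a tunable
  composite, with ``alpha`` set either by mean-matching across regions or
  by maximizing rank correlation with a target indicator.

Both weighted means are convex combinations of lemma scores, so they are
invariant to the overall message volume of a region and always lie within
the score range of their lexicon.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import cached_property
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .lexicon import Lexicon, Side

logger = logging.getLogger(__name__)

#: Measure names accepted by ranking/correlation helpers.
MEASURES = ("C_in", "C_out", "C_rat", "C_diff")


@dataclass
class RegionLemmaCounts:
    """Lemma counts for one region on one side, with normalized usage ``p``."""

    region: str
    side: Side
    counts: Dict[str, float]

    @property
    def total(self) -> float:
        return float(sum(self.counts.values()))

    @cached_property
    def p(self) -> Dict[str, float]:
        """counts normalized to a probability distribution over lemmas."""
        total = self.total
        if total <= 0:
            return {}
        return {lemma: n / total for lemma, n in self.counts.items()}


@dataclass(frozen=True)
class CaloricProfile:
    """The caloric indices of one region's text."""

    region: str
    c_in: float
    c_out: float
    c_rat: float
    c_diff: float
    alpha: float
    n_in: float
    n_out: float


def caloric_score(counts: RegionLemmaCounts, lexicon: Lexicon) -> float:
    """Score-weighted mean ``sum_s score(s) * p(s|T)`` for one region.

    Units follow the side: kcal/100 g (input) or kcal/hour (output).
    """
    if counts.side is not lexicon.side:
        raise ValueError(
            f"counts side {counts.side.value!r} does not match lexicon side "
            f"{lexicon.side.value!r}"
        )
    if not counts.counts or counts.total <= 0:
        raise ValueError(f"region {counts.region!r} has no counted lemmas")
    return float(
        sum(lexicon.lemma_score(lemma) * weight for lemma, weight in counts.p.items())
    )


def caloric_ratio(c_in: float, c_out: float) -> float:
    """``C_rat = C_out / C_in``; requires ``C_in > 0``."""
    if c_in <= 0:
        raise ValueError(f"C_in must be positive, got {c_in}")
    return c_out / c_in


def caloric_difference(c_in: float, c_out: float, alpha: float) -> float:
    """``C_diff(alpha) = alpha * C_out - (1 - alpha) * C_in``, 0 <= alpha <= 1."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    return alpha * c_out - (1.0 - alpha) * c_in


def tune_alpha_mean_match(profiles: Sequence[CaloricProfile]) -> float:
    """Mean-matching alpha: solve ``alpha*<C_out> = (1-alpha)*<C_in>``.

    Region means are unweighted.  The resulting regional mean of
    ``C_diff(alpha)`` is zero by construction.
    """
    if not profiles:
        raise ValueError("need at least one profile")
    mean_in = float(np.mean([p.c_in for p in profiles]))
    mean_out = float(np.mean([p.c_out for p in profiles]))
    if mean_in <= 0 or mean_out <= 0:
        raise ValueError("mean caloric scores must be positive")
    return mean_in / (mean_in + mean_out)


def tune_alpha_to_indicator(
    profiles: Sequence[CaloricProfile],
    indicator: Mapping[str, float],
    grid_step: float = 0.001,
) -> float:
    """Grid-search alpha maximizing ``|Spearman(C_diff(alpha), indicator)|``.

    ``|rho_s|`` is piecewise constant in alpha (ranks only change when two
    regions cross), so an exact grid search is deterministic; ties return
    the smallest alpha.
    """
    from scipy.stats import spearmanr

    if not 0.0 < grid_step < 1.0:
        raise ValueError(f"grid_step must lie in (0, 1), got {grid_step}")
    missing = [p.region for p in profiles if p.region not in indicator]
    if missing:
        raise ValueError(f"indicator missing regions: {missing}")
    if len(profiles) < 3:
        raise ValueError("need at least 3 regions to tune alpha")
    y = np.array([indicator[p.region] for p in profiles], dtype=float)
    c_in = np.array([p.c_in for p in profiles], dtype=float)
    c_out = np.array([p.c_out for p in profiles], dtype=float)
    grid = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    best_alpha, best_val = 0.0, -np.inf
    for alpha in grid:
        diff = alpha * c_out - (1.0 - alpha) * c_in
        if np.ptp(diff) == 0:
            continue
        rho = abs(spearmanr(diff, y).statistic)
        if rho > best_val + 1e-12:
            best_alpha, best_val = float(alpha), float(rho)
    return best_alpha


def dominant_lemma(counts: RegionLemmaCounts, lexicon: Lexicon) -> str:
    """The lemma with the largest product ``score(s) * p(s|T)``.

    This is the single biggest contributor to the region's caloric score —
    a function of both usage volume and caloric weight.  Ties break
    lexicographically.
    """
    if not counts.counts:
        raise ValueError(f"region {counts.region!r} has no counted lemmas")
    return min(
        counts.p,
        key=lambda lemma: (-lexicon.lemma_score(lemma) * counts.p[lemma], lemma),
    )


def dynamic_range(values: Sequence[float]) -> Tuple[float, float, float]:
    """``(min, max, max/min)`` of a positive sequence; ratio to 2 decimals."""
    vals = list(values)
    if not vals:
        raise ValueError("empty sequence")
    if any(v <= 0 for v in vals):
        raise ValueError("all values must be positive")
    lo, hi = min(vals), max(vals)
    return lo, hi, round(hi / lo, 2)


def _measure_value(profile: CaloricProfile, measure: str) -> float:
    try:
        return {
            "C_in": profile.c_in,
            "C_out": profile.c_out,
            "C_rat": profile.c_rat,
            "C_diff": profile.c_diff,
        }[measure]
    except KeyError:
        raise ValueError(f"unknown measure {measure!r}; expected one of {MEASURES}") from None


def measure_values(profiles: Sequence[CaloricProfile], measure: str) -> Dict[str, float]:
    """region -> value of the chosen measure."""
    return {p.region: _measure_value(p, measure) for p in profiles}


def rank_regions(profiles: Sequence[CaloricProfile], measure: str) -> Dict[str, int]:
    """Dense descending ranks: 1 is the largest value.

    Tied regions receive consecutive ranks in lexicographic order, so the
    result is a deterministic bijection onto ``1..n``.
    """
    if not profiles:
        raise ValueError("need at least one profile")
    values = measure_values(profiles, measure)
    ordered = sorted(values, key=lambda region: (-values[region], region))
    return {region: rank for rank, region in enumerate(ordered, start=1)}


def build_profiles(
    counts_in: Mapping[str, RegionLemmaCounts],
    counts_out: Mapping[str, RegionLemmaCounts],
    lexicon_in: Lexicon,
    lexicon_out: Lexicon,
    alpha: Optional[float] = None,
) -> List[CaloricProfile]:
    """Assemble per-region profiles from both sides' counts.

    Regions lacking counted lemmas on either side are excluded with a
    logged warning (the weighted mean is undefined on empty support).
    When ``alpha`` is ``None`` it is set by mean-matching across the
    retained regions.
    """
    regions = sorted(set(counts_in) | set(counts_out))
    kept: List[Tuple[str, float, float, float, float]] = []
    for region in regions:
        cin = counts_in.get(region)
        cout = counts_out.get(region)
        if cin is None or not cin.counts or cout is None or not cout.counts:
            logger.warning(
                "region %r dropped: no counted lemmas on the %s side",
                region,
                "input" if cin is None or not cin.counts else "output",
            )
            continue
        kept.append(
            (
                region,
                caloric_score(cin, lexicon_in),
                caloric_score(cout, lexicon_out),
                cin.total,
                cout.total,
            )
        )
    if not kept:
        raise ValueError("no region has counts on both sides")
    if alpha is None:
        mean_in = float(np.mean([c_in for _, c_in, _, _, _ in kept]))
        mean_out = float(np.mean([c_out for _, _, c_out, _, _ in kept]))
        alpha = mean_in / (mean_in + mean_out)
    return [
        CaloricProfile(
            region=region,
            c_in=c_in,
            c_out=c_out,
            c_rat=caloric_ratio(c_in, c_out),
            c_diff=caloric_difference(c_in, c_out, alpha),
            alpha=alpha,
            n_in=n_in,
            n_out=n_out,
        )
        for region, c_in, c_out, n_in, n_out in kept
    ]


def profiles_table(profiles: Sequence[CaloricProfile]) -> pd.DataFrame:
    """Map/histogram-ready export: indices, ranks, and deviations from the
    unweighted regional mean for each measure."""
    if not profiles:
        raise ValueError("need at least one profile")
    rank_in = rank_regions(profiles, "C_in")
    rank_out = rank_regions(profiles, "C_out")
    rank_rat = rank_regions(profiles, "C_rat")
    frame = pd.DataFrame(
        {
            "region": [p.region for p in profiles],
            "C_in": [p.c_in for p in profiles],
            "C_out": [p.c_out for p in profiles],
            "C_rat": [p.c_rat for p in profiles],
            "C_diff": [p.c_diff for p in profiles],
            "alpha": [p.alpha for p in profiles],
            "rank_in": [rank_in[p.region] for p in profiles],
            "rank_out": [rank_out[p.region] for p in profiles],
            "rank_rat": [rank_rat[p.region] for p in profiles],
            "n_in": [p.n_in for p in profiles],
            "n_out": [p.n_out for p in profiles],
        }
    )
    for measure, col in (("C_in", "dev_in"), ("C_out", "dev_out"), ("C_rat", "dev_rat")):
        frame[col] = frame[measure] - frame[measure].mean()
    return frame.sort_values("region").reset_index(drop=True)


def write_profiles_tsv(profiles: Sequence[CaloricProfile], path: str | Path) -> None:
    profiles_table(profiles).to_csv(path, sep="\t", index=False)


def read_profiles_tsv(path: str | Path) -> List[CaloricProfile]:
    """Rebuild profiles from a :func:`write_profiles_tsv` export."""
    frame = pd.read_csv(path, sep="\t")
    return [
        CaloricProfile(
            region=str(row.region),
            c_in=float(row.C_in),
            c_out=float(row.C_out),
            c_rat=float(row.C_rat),
            c_diff=float(row.C_diff),
            alpha=float(row.alpha),
            n_in=float(row.n_in),
            n_out=float(row.n_out),
        )
        for row in frame.itertuples()
    ]
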