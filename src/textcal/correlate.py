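"""Correlating caloric indices with external region-level indicators.

One Spearman rank correlation per (measure, indicator) pair, with
two-sided p-values from the usual t-approximation on n-2 degrees of
freedom, corrected for multiple comparisons with Benjamini-Hochberg
step-up q-values applied across the whole family of tests at once.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .calorimetry import MEASURES, CaloricProfile, measure_values


@dataclass
class IndicatorTable:
    """Region x indicator matrix with optional per-indicator notes
    (e.g. "lower is better")."""

    data: pd.DataFrame  # index: region, columns: indicator names
    notes: Dict[str, str] = field(default_factory=dict)

    @property
    def indicators(self) -> Tuple[str, ...]:
        return tuple(self.data.columns)


def load_indicators(path: str | Path) -> IndicatorTable:
    """Read an indicator TSV (``region<TAB>name1<TAB>...``)."""
    frame = pd.read_csv(path, sep="\t", dtype={"region": str})
    if "region" not in frame.columns:
        raise ValueError(f"{path}: missing 'region' column")
    frame = frame.set_index("region")
    non_numeric = [c for c in frame.columns if not np.issubdtype(frame[c].dtype, np.number)]
    if non_numeric:
        raise ValueError(f"{path}: non-numeric indicator column(s) {non_numeric}")
    return IndicatorTable(data=frame)


def write_indicators(table: IndicatorTable, path: str | Path) -> None:
    table.data.rename_axis("region").to_csv(path, sep="\t")


def spearman(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Spearman's rho with its two-sided t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be aligned 1-d sequences")
    if len(x) < 3:
        raise ValueError(f"need at least 3 pairs, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    result = stats.spearmanr(x, y)
    return float(result.statistic), float(result.pvalue)


def pearson_with_fit(
    x: Sequence[float], y: Sequence[float]
) -> Tuple[float, float, float]:
    """Pearson's rho plus the ordinary least-squares line ``y = m x + b``.

    Returns ``(rho, slope, intercept)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError(f"need at least 3 pairs, got {len(x)}")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; the fit is undefined")
    fit = stats.linregress(x, y)
    return float(fit.rvalue), float(fit.slope), float(fit.intercept)


def bh_qvalues(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order.

    Sorted ascending, each p is scaled by m/rank, monotonicity enforced by
    a cumulative minimum from the largest rank, clipped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def correlation_table(
    profiles: Sequence[CaloricProfile],
    indicators: IndicatorTable | pd.DataFrame,
    measures: Sequence[str] = ("C_in", "C_out", "C_rat"),
    min_regions: int = 3,
    single_family: bool = True,
) -> pd.DataFrame:
    """All measure x indicator Spearman tests with BH q-values.

    By default the BH correction treats every test as one family (the
    conservative convention for a full dashboard of comparisons); with
    ``single_family=False`` the correction is applied per measure.
    Regions with missing indicator cells are dropped pairwise, per
    indicator.  Returns a tidy frame with one row per test, sorted by
    ascending q for ``C_rat`` (or the first measure when ``C_rat`` is not
    requested), with significance bands at q < 0.01 and q < 0.05.
    """
    for measure in measures:
        if measure not in MEASURES:
            raise ValueError(f"unknown measure {measure!r}")
    data = indicators.data if isinstance(indicators, IndicatorTable) else indicators
    rows = []
    for name in data.columns:
        series = data[name].dropna()
        dropped = len(data[name]) - len(series)
        for measure in measures:
            values = measure_values(profiles, measure)
            common = [r for r in (p.region for p in profiles) if r in series.index]
            if len(common) < min_regions:
                raise ValueError(
                    f"indicator {name!r} shares only {len(common)} regions with the "
                    f"profiles (need >= {min_regions})"
                )
            x = [values[r] for r in common]
            y = [float(series[r]) for r in common]
            rho, p = spearman(x, y)
            rows.append(
                {
                    "indicator": name,
                    "measure": measure,
                    "n": len(common),
                    "n_dropped": dropped,
                    "rho_s": rho,
                    "p_value": p,
                }
            )
    frame = pd.DataFrame(rows)
    if single_family:
        frame["q_value"] = bh_qvalues(frame["p_value"].to_numpy())
    else:
        frame["q_value"] = np.nan
        for measure in measures:
            mask = frame["measure"] == measure
            frame.loc[mask, "q_value"] = bh_qvalues(frame.loc[mask, "p_value"].to_numpy())
    frame["band"] = np.select(
        [frame["q_value"] < 0.01, frame["q_value"] < 0.05], ["q<0.01", "q<0.05"], ""
    )
    sort_measure = "C_rat" if "C_rat" in measures else measures[0]
    order = (
        frame[frame["measure"] == sort_measure]
        .sort_values(["q_value", "indicator"])["indicator"]
        .tolist()
    )
    frame["indicator"] = pd.Categorical(frame["indicator"], categories=order, ordered=True)
    frame = frame.sort_values(["indicator", "measure"]).reset_index(drop=True)
    frame["indicator"] = frame["indicator"].astype(str)
    return frame


def summary_table(long: pd.DataFrame, band_measure: Optional[str] = None) -> pd.DataFrame:
    """Pivot the tidy test table into one row per indicator with
    ``rho_<measure>`` / ``q_<measure>`` columns, preserving row order.

    The ``band`` column reflects ``band_measure`` (default ``C_rat`` when
    present, else the first measure)."""
    measures = long["measure"].drop_duplicates().tolist()
    if band_measure is None:
        band_measure = "C_rat" if "C_rat" in measures else measures[0]
    order = long["indicator"].drop_duplicates().tolist()
    wide = long.pivot(index="indicator", columns="measure", values=["rho_s", "q_value"])
    wide.columns = [f"{'rho' if kind == 'rho_s' else 'q'}_{m}" for kind, m in wide.columns]
    wide = wide.loc[order].reset_index()
    bands = (
        long[long["measure"] == band_measure].set_index("indicator")["band"]
    )
    wide["band"] = wide["indicator"].map(bands)
    return wide


def write_correlation_tsv(long: pd.DataFrame, path: str | Path) -> None:
    summary_table(long).to_csv(path, sep="\t", index=False)
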