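"""Treatment, year and warming-magnitude effect summaries.

Percent changes follow the study's reduction convention: a positive value is
a decrease relative to the reference group (the control within a year, or
2017 between years). Group comparisons use the Welch unequal-variance t test;
the mixed-model machinery of the original analysis is out of scope here.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ahp import ScoreTable
from .core import TREATMENTS, TraitTable

__all__ = [
    "EffectSummary",
    "WarmingSummary",
    "percent_change",
    "year_effect",
    "welch_t",
    "delta_t",
    "summarize_effects",
    "round_half_up",
]


def round_half_up(x: float, digits: int = 2) -> float:
    """Display rounding: half-up at the given number of decimals."""
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class EffectSummary:
    """One contrast: reference vs comparison mean, percent change, Welch test."""

    trait: str
    kind: str  # 'treatment-within-year' | 'year-pooled' | 'score'
    year: int | None
    reference_mean: float
    comparison_mean: float
    percent_change: float  # positive = decrease vs reference
    direction: str  # 'decrease' | 'increase' | 'none'
    t: float | None = None
    df: float | None = None
    p: float | None = None


@dataclass(frozen=True)
class WarmingSummary:
    """Season-mean warmed and ambient temperatures and their difference."""

    year: int | None
    warmed_mean: float
    ambient_mean: float
    delta: float


def percent_change(reference_mean: float, comparison_mean: float) -> float:
    """100 x (reference - comparison) / reference; positive = decrease.

    Full precision is kept internally; use round_half_up for display.
    """
    if reference_mean <= 0:
        raise ValueError("reference mean must be positive")
    return 100.0 * (reference_mean - comparison_mean) / reference_mean


def year_effect(
    cells: Mapping[tuple[str, int], float] | Sequence[float],
) -> float:
    """Percent change of the 2018 pooled mean vs 2017, pooling by unweighted
    mean of the two treatment cells (cells have equal n by design).

    Accepts a mapping keyed by (treatment, year) or the four means in the
    order control-2017, warming-2017, control-2018, warming-2018.
    """
    if isinstance(cells, Mapping):
        try:
            vals = [
                cells[("control", 2017)],
                cells[("warming", 2017)],
                cells[("control", 2018)],
                cells[("warming", 2018)],
            ]
        except KeyError as exc:
            raise ValueError(f"missing cell mean: {exc.args[0]}") from exc
    else:
        vals = list(cells)
        if len(vals) != 4:
            raise ValueError("need exactly four cell means")
    c17, w17, c18, w18 = (float(v) for v in vals)
    for v in (c17, w17, c18, w18):
        if v <= 0:
            raise ValueError("cell means must be positive")
    return percent_change((c17 + w17) / 2.0, (c18 + w18) / 2.0)


def welch_t(sample_a: Iterable[float], sample_b: Iterable[float]) -> tuple[float, float, float]:
    """Welch unequal-variance t statistic, Welch-Satterthwaite df, two-sided p."""
    a = np.asarray(list(sample_a), dtype=float)
    b = np.asarray(list(sample_b), dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 observations")
    if np.var(a, ddof=1) <= 0 or np.var(b, ddof=1) <= 0:
        raise ValueError("each sample needs positive variance")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def delta_t(
    warmed_daily_means: Iterable[float],
    ambient_daily_means: Iterable[float],
    year: int | None = None,
) -> WarmingSummary:
    """Season summary of a paired daily-mean temperature record (degrees C)."""
    w = np.asarray(list(warmed_daily_means), dtype=float)
    a = np.asarray(list(ambient_daily_means), dtype=float)
    if w.size == 0 or a.size == 0:
        raise ValueError("temperature series must be non-empty")
    if w.size != a.size:
        raise ValueError("warmed and ambient series must be paired (equal length)")
    wm, am = float(np.mean(w)), float(np.mean(a))
    return WarmingSummary(year=year, warmed_mean=wm, ambient_mean=am, delta=wm - am)


def _direction(pct: float) -> str:
    if pct > 0:
        return "decrease"
    if pct < 0:
        return "increase"
    return "none"


def summarize_effects(
    table: TraitTable, scores: ScoreTable | None = None
) -> pd.DataFrame:
    """All standard contrasts of a trait table, one row per EffectSummary.

    Per trait and year: warming vs control (percent change of sample means
    plus a Welch test). Per trait: 2018 vs 2017 pooled over treatments.
    When a score table is supplied, the same treatment contrasts are added
    for the comprehensive score. Ordering is deterministic (catalog order,
    ascending year, then year contrasts, then score rows).
    """
    rows: list[EffectSummary] = []
    years = sorted(table.df["year"].unique())
    for trait in table.trait_columns:
        for year in years:
            ref = table.cell("control", year)[trait].dropna()
            cmp_ = table.cell("warming", year)[trait].dropna()
            if len(ref) < 2 or len(cmp_) < 2:
                continue
            pct = percent_change(float(ref.mean()), float(cmp_.mean()))
            try:
                t, df, p = welch_t(ref, cmp_)
            except ValueError:
                t = df = p = None
            rows.append(
                EffectSummary(
                    trait=trait,
                    kind="treatment-within-year",
                    year=int(year),
                    reference_mean=float(ref.mean()),
                    comparison_mean=float(cmp_.mean()),
                    percent_change=pct,
                    direction=_direction(pct),
                    t=t,
                    df=df,
                    p=p,
                )
            )
    if set(years) >= {2017, 2018}:
        for trait in table.trait_columns:
            cells = {}
            for year in (2017, 2018):
                for tr in TREATMENTS:
                    v = table.cell(tr, year)[trait].dropna()
                    if len(v):
                        cells[(tr, year)] = float(v.mean())
            if len(cells) < 4:
                continue
            pct = year_effect(cells)
            a = table.df[table.df["year"] == 2017][trait].dropna()
            b = table.df[table.df["year"] == 2018][trait].dropna()
            try:
                t, df, p = welch_t(a, b)
            except ValueError:
                t = df = p = None
            rows.append(
                EffectSummary(
                    trait=trait,
                    kind="year-pooled",
                    year=None,
                    reference_mean=(cells[("control", 2017)] + cells[("warming", 2017)]) / 2,
                    comparison_mean=(cells[("control", 2018)] + cells[("warming", 2018)]) / 2,
                    percent_change=pct,
                    direction=_direction(pct),
                    t=t,
                    df=df,
                    p=p,
                )
            )
    if scores is not None:
        for year in sorted(scores.scores["year"].unique()):
            s = scores.scores
            ref = s[(s["treatment"] == "control") & (s["year"] == year)]["score"]
            cmp_ = s[(s["treatment"] == "warming") & (s["year"] == year)]["score"]
            if len(ref) < 2 or len(cmp_) < 2:
                continue
            pct = percent_change(float(ref.mean()), float(cmp_.mean()))
            t, df, p = welch_t(ref, cmp_)
            rows.append(
                EffectSummary(
                    trait="comprehensive_score",
                    kind="score",
                    year=int(year),
                    reference_mean=float(ref.mean()),
                    comparison_mean=float(cmp_.mean()),
                    percent_change=pct,
                    direction=_direction(pct),
                    t=t,
                    df=df,
                    p=p,
                )
            )
    return pd.DataFrame([vars(r) for r in rows])
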