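"""Cohort summaries, the two-tailed Mann-Whitney test, and stress-trend fits."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .biomechanics import GrowthRecord

__all__ = [
    "GroupSummary",
    "TrendFit",
    "summarize",
    "mann_whitney",
    "fit_stress_trend",
    "EXACT_LIMIT",
    "SIGNIFICANCE_LEVEL",
]

EXACT_LIMIT = 14          # pooled n up to which the exact null is enumerated
SIGNIFICANCE_LEVEL = 0.05


@dataclass(frozen=True)
class GroupSummary:
    n: int
    median: float
    q25: float
    q75: float
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not self.q25 <= self.median <= self.q75:
            raise ValueError("quantiles out of order")


@dataclass(frozen=True)
class TrendFit:
    channel: str                # length | volume | diameter
    slope_pct_per_Pa: float
    intercept_pct: float
    residual_sd_pct: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("trend fit needs n >= 3")


def summarize(values: Iterable[float]) -> GroupSummary:
    """Median, linear-interpolation quartiles, mean and sample sd (n-1)."""
    arr = np.asarray(list(values), float)
    if arr.size < 1:
        raise ValueError("need at least one value")
    q25, med, q75 = np.percentile(arr, [25, 50, 75])
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
    return GroupSummary(
        n=int(arr.size), median=float(med), q25=float(q25), q75=float(q75),
        mean=float(arr.mean()), sd=sd,
    )


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-tailed Mann-Whitney U test, ``(U_a, p)``.

    Exact null distribution when the pooled sample has no ties and at most
    ``EXACT_LIMIT`` observations; tie- and continuity-corrected normal
    approximation otherwise.
    """
    a = np.asarray(list(a), float)
    b = np.asarray(list(b), float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    if no_ties and pooled.size <= EXACT_LIMIT:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


_CHANNEL_COLUMNS = {
    "length": ("L0_mm", "L1_mm"),
    "volume": ("V0_mm3", "V1_mm3"),
    "diameter": ("d0_mm", "d1_mm"),
}


def _changes_and_stress(records, channel: str):
    if channel not in _CHANNEL_COLUMNS:
        raise ValueError(f"unknown channel {channel!r}")
    if isinstance(records, pd.DataFrame):
        c0, c1 = _CHANNEL_COLUMNS[channel]
        stress = records["stress_Pa"].to_numpy(float)
        pct = (records[c1].to_numpy(float) / records[c0].to_numpy(float) - 1.0) * 100.0
        return stress, pct
    stress, pct = [], []
    for rec in records:
        if not isinstance(rec, GrowthRecord):
            raise TypeError("records must be GrowthRecord instances or a DataFrame")
        if channel not in rec.rel_changes:
            rec.compute_changes()
        stress.append(rec.stress.stress_Pa if rec.stress else 0.0)
        pct.append(rec.rel_changes[channel] * 100.0)
    return np.asarray(stress, float), np.asarray(pct, float)


def fit_stress_trend(records, channel: str) -> TrendFit:
    """OLS line of percent change vs applied stress (controls at 0 Pa)."""
    stress, pct = _changes_and_stress(records, channel)
    if len(stress) < 3:
        raise ValueError("trend fit needs >= 3 records")
    if np.unique(stress).size < 2:
        raise ValueError("all stresses equal: trend is undefined")
    res = stats.linregress(stress, pct)
    resid = pct - (res.intercept + res.slope * stress)
    dof = max(len(stress) - 2, 1)
    return TrendFit(
        channel=channel,
        slope_pct_per_Pa=float(res.slope),
        intercept_pct=float(res.intercept),
        residual_sd_pct=float(np.sqrt(np.sum(resid**2) / dof)),
        n=int(len(stress)),
    )
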