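"""Carrier prevalence, Wilson intervals, Yates chi-squared comparisons.

Prevalence is reported the way screening papers print it — "1 in N" with N
rounded half away from zero — alongside the raw rate and a Wilson score
interval (the score interval reproduces published bounds near 0 where the
normal approximation does not).  Categorical comparisons use Pearson's
chi-squared with the Yates continuity correction on 2x2 tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist
from statsmodels.stats.proportion import proportion_confint

#: self-reported categories excluded from prevalence estimation
EXCLUDED_SELF_REPORTED = ("Native American", "Other", "Multiple selected", "Not available")


@dataclass(frozen=True)
class PrevalenceResult:
    group: str
    n: int
    carriers: int
    rate: float
    one_in_n: int | None
    ci_low: float
    ci_high: float

    def render_one_in_n(self) -> str:
        return "-" if self.one_in_n is None else f"1:{self.one_in_n}"


@dataclass(frozen=True)
class ContingencyResult:
    table: tuple[tuple[int, int], tuple[int, int]]
    chi2: float
    p_value: float
    proportions: tuple[float, float]  # row-wise a/(a+b), c/(c+d)
    ratio: float  # ratio of the two row proportions


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def prevalence(carriers: int, n: int, group: str = "", confidence: float = 0.95) -> PrevalenceResult:
    """Carrier rate with "1 in N" formatting and a Wilson interval."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0 <= carriers <= n):
        raise ValueError("carriers must be in [0, n]")
    rate = carriers / n
    one_in_n = _round_half_away(n / carriers) if carriers >= 1 else None
    lo, hi = wilson_ci(carriers, n, confidence)
    return PrevalenceResult(group, n, carriers, rate, one_in_n, lo, hi)


def wilson_ci(k: int, n: int, confidence: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0 <= k <= n):
        raise ValueError("k must be in [0, n]")
    lo, hi = proportion_confint(k, n, alpha=1 - confidence, method="wilson")
    return float(max(lo, 0.0)), float(min(hi, 1.0))


def yates_chi2(a: int, b: int, c: int, d: int) -> ContingencyResult:
    """Yates-corrected chi-squared test of independence on a 2x2 table.

    chi2 = sum over cells of max(|O - E| - 0.5, 0)^2 / E, df = 1.  The
    correction is floored at zero so perfectly independent tables give
    chi2 = 0, p = 1.
    """
    obs = np.array([[a, b], [c, d]], dtype=float)
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    total = obs.sum()
    if (rows == 0).any() or (cols == 0).any():
        raise ValueError("all row and column margins must be positive")
    expected = np.outer(rows, cols) / total
    stat = float(np.sum(np.maximum(np.abs(obs - expected) - 0.5, 0.0) ** 2 / expected))
    p = float(chi2_dist.sf(stat, df=1))
    p1 = a / (a + b)
    p2 = c / (c + d)
    ratio = p1 / p2 if p2 > 0 else math.inf
    return ContingencyResult(((a, b), (c, d)), stat, p, (p1, p2), ratio)


def render_percent(x: float) -> str:
    """One-decimal percent, rounded half away from zero (table style)."""
    return f"{_round_half_away(x * 1000) / 10:.1f}"


def group_rates(
    carrier_status: pd.DataFrame,
    cohort: pd.DataFrame,
    grouping: str,
    unrelated_ids: list[str] | None = None,
    confidence: float = 0.95,
) -> tuple[list[PrevalenceResult], list[str]]:
    """Per-group carrier prevalence on a chosen grouping.

    Parameters
    ----------
    carrier_status : DataFrame with sample_id, status columns
        (carrier = status "variant_positive").
    cohort : per-sample metadata with the grouping column:
        "self_reported", "community", or "admixture_bin".
    grouping : one of "self-reported", "genetic community", "admixture bin".
    unrelated_ids : restrict to this sample subset when given.

    Returns the per-group results and the list of excluded group labels
    (self-reported categories the study design drops from prevalence).
    """
    column = {
        "self-reported": "self_reported",
        "genetic community": "community",
        "admixture bin": "admixture_bin",
    }.get(grouping)
    if column is None:
        raise ValueError(f"unknown grouping {grouping!r}")
    if column not in cohort.columns:
        raise ValueError(f"cohort table lacks column {column!r}")
    df = cohort.merge(carrier_status[["sample_id", "status"]], on="sample_id", how="inner")
    if unrelated_ids is not None:
        df = df[df["sample_id"].isin(set(unrelated_ids))]
    excluded: list[str] = []
    if grouping == "self-reported":
        present = set(df[column])
        excluded = [g for g in EXCLUDED_SELF_REPORTED if g in present]
        df = df[~df[column].isin(EXCLUDED_SELF_REPORTED)]
    results = []
    for label, g in df.groupby(column, sort=True):
        carriers = int((g["status"] == "variant_positive").sum())
        results.append(prevalence(carriers, len(g), group=str(label), confidence=confidence))
    return results, excluded


def prevalence_frame(results: list[PrevalenceResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "group": [r.group for r in results],
            "n": [r.n for r in results],
            "carriers": [r.carriers for r in results],
            "rate_percent": [render_percent(r.rate) for r in results],
            "prevalence": [r.render_one_in_n() for r in results],
            "ci_low": [r.ci_low for r in results],
            "ci_high": [r.ci_high for r in results],
        }
    )
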