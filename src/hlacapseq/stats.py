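"""Differential-allelic-expression statistics.

Summaries follow spreadsheet conventions: quartiles by linear interpolation
(inclusive, i.e. QUARTILE.INC), box-and-whisker with whiskers at the most
extreme points within 1.5 interquartile ranges of the box, and half-up
rounding to one decimal for ratios and percentages.  Dispersion per group
is summarized by the ratio of hinges (Q3/Q1) and the coefficient of
variation (sample SD / mean); between-group location differences use
fixed-effects one-way ANOVA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .reference import AlleleName

__all__ = [
    "FiveNumber",
    "DAESummary",
    "FoldChangeResult",
    "BoxWhisker",
    "GroupComparison",
    "round_half_up",
    "five_number",
    "ratio_of_hinges",
    "fold_change",
    "anova_one_way",
    "coefficient_of_variation",
    "pearson_r2",
    "null_allele_fraction",
    "box_whisker",
    "summarize",
    "compare_groups",
    "locus_summary_table",
    "allele_summary_table",
]


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (spreadsheet-style), not banker's."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class FiveNumber:
    minimum: float
    q1: float
    median: float
    q3: float
    maximum: float
    n: int

    def __post_init__(self) -> None:
        if not (
            self.minimum <= self.q1 <= self.median <= self.q3 <= self.maximum
        ):
            raise ValueError("five-number summary must be non-decreasing")


def five_number(values: Sequence[float]) -> FiveNumber:
    """Min, quartiles and max with inclusive linear-interpolation quartiles."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("five_number requires at least one value")
    mn, q1, med, q3, mx = np.quantile(v, [0.0, 0.25, 0.5, 0.75, 1.0], method="linear")
    return FiveNumber(float(mn), float(q1), float(med), float(q3), float(mx), int(v.size))


def ratio_of_hinges(f: FiveNumber) -> float | None:
    """Q3/Q1 rounded half-up to one decimal; None (missing) when Q1 <= 0."""
    if f.q1 <= 0:
        return None
    return round_half_up(f.q3 / f.q1, 1)


def fold_change(median_low: float, median_high: float) -> float:
    """Highest/lowest allele median, rounded half-up to one decimal."""
    if median_low <= 0:
        raise ValueError("median_low must be positive")
    if median_high < median_low:
        raise ValueError("median_high must be >= median_low")
    return round_half_up(median_high / median_low, 1)


def anova_one_way(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Fixed-effects one-way ANOVA: returns (F, p).

    For two groups F equals the square of the pooled-variance t statistic.
    Degenerate input (zero within- and between-group variance) returns
    (0.0, 1.0) rather than a division error.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("ANOVA requires at least two groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs n >= 2")
    n_total = sum(a.size for a in arrays)
    k = len(arrays)
    grand = sum(a.sum() for a in arrays) / n_total
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_between = k - 1
    df_within = n_total - k
    if ss_within == 0.0:
        if ss_between == 0.0:
            return 0.0, 1.0
        return math.inf, 0.0
    f_stat = (ss_between / df_between) / (ss_within / df_within)
    p = float(sps.f.sf(f_stat, df_between, df_within))
    return float(f_stat), p


def coefficient_of_variation(values: Sequence[float]) -> float:
    """Sample standard deviation (n-1 denominator) divided by the mean."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("CV requires n >= 2")
    mean = v.mean()
    if mean <= 0:
        raise ValueError("CV requires a positive mean")
    return float(v.std(ddof=1) / mean)


def pearson_r2(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson r and coefficient of determination r^2.

    Zero variance in either input makes the correlation undefined; (nan,
    nan) is returned as the missing marker.
    """
    xa, ya = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if xa.size != ya.size or xa.size < 3:
        raise ValueError("pearson_r2 requires equal lengths >= 3")
    if xa.std() == 0 or ya.std() == 0:
        return math.nan, math.nan
    r = float(sps.pearsonr(xa, ya).statistic)
    return r, r * r


def null_allele_fraction(
    allele_median_reads: float, locus_average_median_reads: float
) -> float:
    """Allele median as a percentage of the locus average median (1 dp)."""
    if locus_average_median_reads <= 0:
        raise ValueError("locus average median must be positive")
    return round_half_up(
        100.0 * allele_median_reads / locus_average_median_reads, 1
    )


@dataclass(frozen=True)
class BoxWhisker:
    q1: float
    median: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: tuple[float, ...]


def box_whisker(values: Sequence[float]) -> BoxWhisker:
    """Box at the quartiles; whiskers at the most extreme points within 1.5
    interquartile ranges of the box; points beyond are outliers."""
    v = np.asarray(values, dtype=float)
    f = five_number(v)
    iqr = f.q3 - f.q1
    lo_fence, hi_fence = f.q1 - 1.5 * iqr, f.q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    outliers = tuple(sorted(v[(v < lo_fence) | (v > hi_fence)].tolist()))
    if inside.size == 0:  # degenerate; fences collapse onto the box
        w_lo, w_hi = f.q1, f.q3
    else:
        w_lo, w_hi = float(inside.min()), float(inside.max())
    return BoxWhisker(f.q1, f.median, f.q3, w_lo, w_hi, outliers)


@dataclass(frozen=True)
class DAESummary:
    """Per-group dispersion summary: five numbers, hinge ratio, CV."""

    label: str
    five: FiveNumber
    hinge_ratio: float | None
    cv: float | None
    n: int


def summarize(values: Sequence[float], label: str) -> DAESummary:
    f = five_number(values)
    cv = coefficient_of_variation(values) if f.n >= 2 and np.mean(values) > 0 else None
    return DAESummary(label, f, ratio_of_hinges(f), cv, f.n)


@dataclass(frozen=True)
class FoldChangeResult:
    locus: str
    lowest_allele: str
    lowest_median: float
    highest_allele: str
    highest_median: float
    fold_change: float
    p_value: float | None


@dataclass(frozen=True)
class GroupComparison:
    key: str
    groups: tuple[DAESummary, ...]
    anova_f: float
    anova_p: float
    p_adjusted: float | None = None


def compare_groups(
    dataset: pd.DataFrame,
    grouping: str | Callable[[pd.Series], str] | Mapping[str, str],
    min_n: int = 3,
    value_col: str = "normalized_reads",
    key: str = "comparison",
    bonferroni_m: int | None = None,
) -> GroupComparison | None:
    """ANOVA across groups of normalized reads.

    ``grouping`` is a column name, a row -> label callable, or an
    allele -> class map (rows with unmapped alleles are dropped; this is how
    e.g. a DPB1-allele -> rs9277534 A/G class map is applied).  Groups with
    fewer than ``min_n`` observations are dropped; with fewer than two
    qualifying groups the comparison is skipped (returns None).  No
    multiple-testing correction is applied unless ``bonferroni_m`` is set.
    """
    df = dataset
    if isinstance(grouping, str):
        labels = df[grouping].astype(str)
    elif isinstance(grouping, Mapping):
        labels = df["allele"].map(grouping)
        keep = labels.notna()
        df, labels = df[keep], labels[keep].astype(str)
    else:
        labels = df.apply(grouping, axis=1).astype(str)

    summaries = []
    samples = []
    for label, sub in sorted(df.groupby(labels, sort=False), key=lambda kv: kv[0]):
        vals = sub[value_col].to_numpy(dtype=float)
        if vals.size < min_n:
            continue
        summaries.append(summarize(vals, str(label)))
        samples.append(vals)
    if len(samples) < 2:
        return None
    f_stat, p = anova_one_way(samples)
    p_adj = min(1.0, p * bonferroni_m) if bonferroni_m else None
    return GroupComparison(key, tuple(summaries), f_stat, p, p_adj)


def locus_summary_table(dataset: pd.DataFrame) -> pd.DataFrame:
    """Per-locus five-number summary of normalized reads with hinge ratio.

    One observation per (sample, allele) row, pooled within locus — the
    locus-level dispersion view of a comparative dataset.
    """
    rows = []
    for locus, sub in dataset.groupby("locus", sort=True):
        s = summarize(sub["normalized_reads"].to_numpy(dtype=float), str(locus))
        rows.append(
            {
                "locus": locus,
                "n": s.n,
                "minimum": s.five.minimum,
                "q1": s.five.q1,
                "median": s.five.median,
                "q3": s.five.q3,
                "maximum": s.five.maximum,
                "ratio_of_hinges": s.hinge_ratio,
                "cv": s.cv,
            }
        )
    return pd.DataFrame(rows)


def allele_summary_table(
    dataset: pd.DataFrame,
    min_n: int = 3,
    anova_mode: str = "extremes",
) -> pd.DataFrame:
    """Per-locus lowest/highest expressed alleles and their fold change.

    Allele medians are taken over samples (alleles observed in fewer than
    ``min_n`` samples are dropped).  ``anova_mode`` selects the reported
    p-value: "extremes" compares only the lowest vs highest allele groups,
    "all" compares all qualifying alleles at the locus.
    """
    if anova_mode not in ("extremes", "all"):
        raise ValueError("anova_mode must be 'extremes' or 'all'")
    rows = []
    for locus, sub in dataset.groupby("locus", sort=True):
        per_allele = {
            allele: g["normalized_reads"].to_numpy(dtype=float)
            for allele, g in sub.groupby("allele", sort=True)
        }
        per_allele = {a: v for a, v in per_allele.items() if v.size >= min_n}
        if len(per_allele) < 2:
            continue
        medians = {a: float(np.median(v)) for a, v in per_allele.items()}
        lowest = min(medians, key=lambda a: (medians[a], a))
        highest = max(medians, key=lambda a: (medians[a], a))
        fc = fold_change(medians[lowest], medians[highest])
        if anova_mode == "extremes":
            groups = [per_allele[lowest], per_allele[highest]]
        else:
            groups = list(per_allele.values())
        try:
            _, p = anova_one_way(groups)
        except ValueError:
            p = math.nan
        rows.append(
            {
                "locus": locus,
                "n_alleles": len(per_allele),
                "average_median_reads": float(np.mean(list(medians.values()))),
                "lowest_allele": lowest,
                "lowest_median": medians[lowest],
                "highest_allele": highest,
                "highest_median": medians[highest],
                "fold_change": fc,
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)
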