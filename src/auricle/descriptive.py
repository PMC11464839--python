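"""Descriptive summaries of a case series.

Frequency tables over demographic strata (sex, age band, reporter, country,
outcome codes), median/IQR summaries of continuous variables, yearly report
counts with pairwise percent changes, and per-report time to onset (days
from the earliest primary-suspect drug start to the earliest event date).

Quantiles use linear interpolation (the "type 7" convention), so a
singleton yields median = q1 = q3 and ``[1..5]`` yields (2, 3, 4).  Age
bands are half-open — <1, [1, 4), [4, 10), ≥10, unknown — so boundary ages
fall in exactly one band.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .ingest import DrugRole, SafetyReport

__all__ = [
    "FrequencyTable",
    "QuantileSummary",
    "YearlySeries",
    "tabulate",
    "median_iqr",
    "yearly_counts",
    "time_to_onset",
    "AGE_BAND_LABELS",
]

AGE_BAND_LABELS = ["<1", "1-4", "4-10", ">=10", "unknown"]


@dataclass(frozen=True, slots=True)
class FrequencyTable:
    variable: str
    rows: tuple[tuple[str, int, float], ...]  # (label, count, percent)
    denominator: int

    def __post_init__(self) -> None:
        for label, count, percent in self.rows:
            if count < 0:
                raise ValueError(f"negative count for {label!r}")
            expected = 100.0 * count / self.denominator if self.denominator else 0.0
            if abs(percent - expected) > 0.01:
                raise ValueError(
                    f"percent for {label!r} inconsistent with denominator"
                )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["category", "count", "percent"])


@dataclass(frozen=True, slots=True)
class QuantileSummary:
    median: float
    q1: float
    q3: float
    n_nonmissing: int

    def __post_init__(self) -> None:
        if not (self.q1 <= self.median <= self.q3):
            raise ValueError("quartiles out of order")


@dataclass(frozen=True, slots=True)
class YearlySeries:
    rows: tuple[tuple[int, int], ...]  # (year, count), years strictly increasing
    pct_changes: tuple[tuple[int, float], ...]  # (year, percent change vs previous)
    max_increase: tuple[int, int, float] | None  # (year_from, year_to, percent)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.rows, columns=["year", "count"])
        changes = dict(self.pct_changes)
        df["pct_change"] = [changes.get(y, float("nan")) for y, _ in self.rows]
        return df


def _age_band(age: float | None) -> str:
    if age is None:
        return "unknown"
    if age < 1:
        return "<1"
    if age < 4:
        return "1-4"
    if age < 10:
        return "4-10"
    return ">=10"


def tabulate(
    cases: Sequence[SafetyReport],
    variable: str,
    denominator_policy: str = "cases",
    top_k_countries: int = 5,
) -> FrequencyTable:
    """Frequency table of one categorical variable over a case series.

    ``variable`` is one of ``sex``, ``age_band``, ``reporter``, ``country``,
    ``outcomes``.  For countries, the ``top_k_countries`` most frequent are
    listed and the remainder pooled as "Other".  For outcomes,
    ``denominator_policy`` chooses between percent-of-cases and
    percent-of-outcome-occurrences (a report may carry several codes).
    """
    if variable == "sex":
        counts = Counter(r.sex.value for r in cases)
        labels = ["female", "male", "unknown"]
        rows = [(lab, counts.get(lab, 0)) for lab in labels]
        denom = len(cases)
    elif variable == "age_band":
        counts = Counter(_age_band(r.age_years) for r in cases)
        rows = [(lab, counts.get(lab, 0)) for lab in AGE_BAND_LABELS]
        denom = len(cases)
    elif variable == "reporter":
        counts = Counter(r.reporter.value for r in cases)
        rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        denom = len(cases)
    elif variable == "country":
        counts = Counter(r.country or "unknown" for r in cases)
        ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        head = ranked[:top_k_countries]
        tail_total = sum(c for _, c in ranked[top_k_countries:])
        rows = list(head)
        if tail_total:
            rows.append(("Other", tail_total))
        denom = len(cases)
    elif variable == "outcomes":
        counts = Counter(code.value for r in cases for code in r.outcomes)
        rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        if denominator_policy == "occurrences":
            denom = sum(counts.values())
        elif denominator_policy == "cases":
            denom = len(cases)
        else:
            raise ValueError(f"unknown denominator_policy {denominator_policy!r}")
    else:
        raise ValueError(f"unknown variable {variable!r}")

    out = tuple(
        (label, count, 100.0 * count / denom if denom else 0.0)
        for label, count in rows
    )
    return FrequencyTable(variable=variable, rows=out, denominator=denom)


def median_iqr(values: Iterable[float | None]) -> QuantileSummary:
    """Median and quartiles (linear interpolation) of the non-missing values."""
    arr = np.asarray([v for v in values if v is not None], dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ValueError("median_iqr requires at least one non-missing value")
    q1, med, q3 = np.quantile(arr, [0.25, 0.5, 0.75], method="linear")
    return QuantileSummary(median=float(med), q1=float(q1), q3=float(q3),
                           n_nonmissing=int(arr.size))


def yearly_counts(cases: Sequence[SafetyReport]) -> YearlySeries:
    """Report counts per receipt year, pairwise percent changes, and the
    consecutive-year pair with the largest percent increase."""
    counts = Counter(
        r.receipt_date.year for r in cases if r.receipt_date is not None
    )
    years = sorted(counts)
    rows = tuple((y, counts[y]) for y in years)
    changes: list[tuple[int, float]] = []
    for prev, cur in zip(years, years[1:]):
        if cur == prev + 1 and counts[prev] > 0:
            changes.append((cur, 100.0 * (counts[cur] - counts[prev]) / counts[prev]))
    max_inc = None
    if changes:
        best_year, best_pct = max(changes, key=lambda t: t[1])
        max_inc = (best_year - 1, best_year, best_pct)
    return YearlySeries(rows=rows, pct_changes=tuple(changes), max_increase=max_inc)


def time_to_onset(report: SafetyReport) -> int | None:
    """Days from the earliest primary-suspect drug start date to the earliest
    event date; missing if either date is absent.  Negative gaps are treated
    as data-entry artifacts: missing, with a warning."""
    starts = [
        m.start_date for m in report.drugs
        if m.role is DrugRole.PRIMARY_SUSPECT and m.start_date is not None
    ]
    events = [m.event_date for m in report.reactions if m.event_date is not None]
    if not starts or not events:
        return None
    delta = (min(events) - min(starts)).days
    if delta < 0:
        warnings.warn(
            f"negative time-to-onset ({delta} d) in report {report.report_id}; "
            "treated as missing",
            stacklevel=2,
        )
        return None
    return delta
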