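"""Trend statistics on monthly filing-count series.

Year-on-year change compares January-December calendar-year totals:
``change_t = 100 * (total_t - total_{t-1}) / total_{t-1}``. Years whose
previous year had zero filings are skipped (a percentage change from zero is
undefined) and reported, and the mean percentage change averages the defined
changes only. Period medians, peak months and a centered moving average for
display complete the summary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from patenttrends.records import MonthlyCountSeries, ym_add, ym_diff, ym_parse, ym_str

__all__ = [
    "TrendSummary",
    "yearly_percent_changes",
    "mean_percent_change",
    "period_median",
    "peak_month",
    "smooth_series",
]


@dataclass
class TrendSummary:
    """Yearly totals and percentage changes for one taxon's series."""

    taxon: str
    yearly_totals: dict[int, int]
    yoy_changes: dict[int, float]
    skipped_years: list[int]
    period_medians: dict[str, float] = field(default_factory=dict)
    peak: tuple[str, int] | None = None

    @property
    def mean_percent_change(self) -> float:
        return mean_percent_change(self)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "taxon": self.taxon,
            "yearly_totals": {str(k): v for k, v in self.yearly_totals.items()},
            "yoy_changes": {str(k): v for k, v in self.yoy_changes.items()},
            "skipped_years": self.skipped_years,
            "mean_percent_change": self.mean_percent_change if self.yoy_changes else None,
            "period_medians": self.period_medians,
            "peak": list(self.peak) if self.peak else None,
        }
        Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")


def yearly_percent_changes(
    series: MonthlyCountSeries, start_year: int, end_year: int
) -> TrendSummary:
    """Year-on-year percentage change of January-December totals.

    The comparison window is an explicit parameter because a study may start
    the rate comparison at different epochs (e.g. the first year every taxon
    has filings). Changes for years whose previous-year total is zero are
    undefined and recorded in ``skipped_years``.
    """
    if end_year - start_year < 1:
        raise ValueError("window must cover at least two complete calendar years")
    sy, sm = ym_parse(series.start_month)
    totals: dict[int, int] = {}
    for year in range(start_year, end_year + 1):
        i0 = ym_diff(ym_str(year, 1), series.start_month)
        i1 = ym_diff(ym_str(year, 12), series.start_month)
        if i0 < 0 or i1 >= len(series):
            raise ValueError(
                f"year {year} is not fully covered by the series "
                f"({series.start_month}..{series.month_at(len(series) - 1)})"
            )
        totals[year] = int(series.counts[i0 : i1 + 1].sum())
    changes: dict[int, float] = {}
    skipped: list[int] = []
    for year in range(start_year + 1, end_year + 1):
        prev = totals[year - 1]
        if prev == 0:
            skipped.append(year)
        else:
            changes[year] = 100.0 * (totals[year] - prev) / prev
    return TrendSummary(
        taxon=series.taxon,
        yearly_totals=totals,
        yoy_changes=changes,
        skipped_years=skipped,
    )


def mean_percent_change(summary: TrendSummary) -> float:
    """Arithmetic mean of the defined year-on-year changes."""
    if not summary.yoy_changes:
        raise ValueError("no defined year-on-year changes (all previous years zero?)")
    return float(np.mean(list(summary.yoy_changes.values())))


def period_median(series: MonthlyCountSeries, period: tuple[str, str]) -> float:
    """Median monthly count over a closed year-month period."""
    start, end = period
    i0 = ym_diff(start, series.start_month)
    i1 = ym_diff(end, series.start_month)
    if i0 > i1:
        raise ValueError("empty period")
    if i0 < 0 or i1 >= len(series):
        raise ValueError("period extends outside the series")
    return float(np.median(series.counts[i0 : i1 + 1]))


def peak_month(series: MonthlyCountSeries) -> tuple[str, int]:
    """Earliest month attaining the maximum monthly count."""
    idx = int(np.argmax(series.counts))  # argmax returns the first maximum
    return series.month_at(idx), int(series.counts[idx])


def smooth_series(series: MonthlyCountSeries, window: int = 13) -> np.ndarray:
    """Centered moving average for display, truncating the window at edges.

    ``window`` must be odd so the average is centered (hence the 13-month
    default, the closest odd span to one year); output length equals input
    length.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd positive integer")
    if window > len(series):
        raise ValueError("window exceeds series length")
    half = window // 2
    counts = series.counts.astype(float)
    out = np.empty_like(counts)
    for i in range(len(counts)):
        lo = max(0, i - half)
        hi = min(len(counts), i + half + 1)
        out[i] = counts[lo:hi].mean()
    return out
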