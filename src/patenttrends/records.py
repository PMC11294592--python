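"""Patent-record data model, I/O, deduplication, keyword filtering, aggregation.

A :class:`PatentRecord` is one filed patent: an opaque unique identifier,
title and abstract text, the priority date (date of first filing, used as the
event timestamp throughout), a jurisdiction code, the filing entities, and a
taxon tag. Records are read and written as JSONL or CSV; monthly aggregation
produces a gapless :class:`MonthlyCountSeries` consumed by the changepoint
and trends modules.

Keyword filtering follows include/NOT-exclude semantics: a record is kept if
at least one include term matches and no exclude term matches, exclusion
overriding inclusion. Matching is case-insensitive; Latin-script terms match
on word boundaries (multi-word terms as contiguous phrases), terms containing
non-Latin characters match as literal substrings.
"""

from __future__ import annotations

import csv
import datetime as _dt
import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "PatentRecord",
    "KeywordSpec",
    "MonthlyCountSeries",
    "RecordError",
    "DEFAULT_DATE_WINDOW",
    "read_records",
    "write_records",
    "deduplicate",
    "filter_by_keywords",
    "aggregate_monthly",
    "load_keyword_specs",
    "ym_parse",
    "ym_str",
    "ym_add",
    "ym_diff",
]

#: Study period: dates outside this window violate the record invariant.
DEFAULT_DATE_WINDOW = (_dt.date(1970, 1, 1), _dt.date(2020, 12, 31))


# ---------------------------------------------------------------------------
# year-month arithmetic ("YYYY-MM" strings)

def ym_parse(ym: str) -> tuple[int, int]:
    """Parse ``"YYYY-MM"`` into ``(year, month)``; raises ValueError if malformed."""
    m = re.fullmatch(r"(\d{4})-(\d{2})", ym)
    if not m:
        raise ValueError(f"not a YYYY-MM month: {ym!r}")
    year, month = int(m.group(1)), int(m.group(2))
    if not 1 <= month <= 12:
        raise ValueError(f"month out of range in {ym!r}")
    return year, month


def ym_str(year: int, month: int) -> str:
    return f"{year:04d}-{month:02d}"


def ym_add(ym: str, k: int) -> str:
    """Month ``k`` steps after (or before, if negative) ``ym``."""
    year, month = ym_parse(ym)
    total = year * 12 + (month - 1) + k
    return ym_str(total // 12, total % 12 + 1)


def ym_diff(a: str, b: str) -> int:
    """Number of months from ``b`` to ``a`` (a - b)."""
    ya, ma = ym_parse(a)
    yb, mb = ym_parse(b)
    return (ya * 12 + ma) - (yb * 12 + mb)


# ---------------------------------------------------------------------------
# data model


@dataclass
class PatentRecord:
    """One filed patent.

    ``matched_terms`` is empty until populated by :func:`filter_by_keywords`.
    """

    record_id: str
    title: str
    abstract: str
    priority_date: _dt.date
    jurisdiction: str
    applicants: list[str] = field(default_factory=list)
    taxon: str = ""
    matched_terms: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.record_id:
            raise ValueError("record_id must be non-empty")
        if isinstance(self.priority_date, str):
            self.priority_date = _dt.date.fromisoformat(self.priority_date)
        if not isinstance(self.priority_date, _dt.date):
            raise TypeError("priority_date must be a datetime.date")

    @property
    def month(self) -> str:
        return ym_str(self.priority_date.year, self.priority_date.month)

    def to_dict(self) -> dict:
        return {
            "record_id": self.record_id,
            "title": self.title,
            "abstract": self.abstract,
            "priority_date": self.priority_date.isoformat(),
            "jurisdiction": self.jurisdiction,
            "applicants": list(self.applicants),
            "taxon": self.taxon,
            "matched_terms": list(self.matched_terms),
        }


@dataclass
class KeywordSpec:
    """Include/exclude search terms for one taxon.

    Include and exclude lists must be disjoint after normalization
    (lowercasing and whitespace collapsing).
    """

    taxon: str
    include_terms: list[str]
    exclude_terms: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.include_terms:
            raise ValueError("include_terms must be non-empty")
        inc = {_normalize_term(t) for t in self.include_terms}
        exc = {_normalize_term(t) for t in self.exclude_terms}
        overlap = inc & exc
        if overlap:
            raise ValueError(f"include and exclude terms overlap: {sorted(overlap)}")


@dataclass
class MonthlyCountSeries:
    """Contiguous monthly filing counts starting at ``start_month``.

    ``counts[i]`` is the number of filings in month ``start_month + i``;
    there are no gaps and the series has at least two months.
    """

    taxon: str
    start_month: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        ym_parse(self.start_month)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 1 or len(self.counts) < 2:
            raise ValueError("counts must be a 1-d array of length >= 2")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    def __len__(self) -> int:
        return len(self.counts)

    def month_at(self, i: int) -> str:
        return ym_add(self.start_month, i)

    @property
    def months(self) -> list[str]:
        return [self.month_at(i) for i in range(len(self.counts))]

    def reversed(self) -> "MonthlyCountSeries":
        """Time-reversed copy (used by symmetry checks)."""
        return MonthlyCountSeries(self.taxon, self.start_month, self.counts[::-1].copy())

    def slice(self, start: int, stop: int) -> "MonthlyCountSeries":
        """Sub-series over month indices ``[start, stop)``."""
        if stop - start < 2:
            raise ValueError("a series slice needs at least two months")
        return MonthlyCountSeries(self.taxon, self.month_at(start), self.counts[start:stop].copy())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"month": self.months, "count": self.counts})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, taxon: str = "") -> "MonthlyCountSeries":
        df = pd.read_csv(path, dtype={"month": str})
        months = list(df["month"])
        for prev, nxt in zip(months, months[1:]):
            if ym_diff(nxt, prev) != 1:
                raise ValueError(f"series has a gap between {prev} and {nxt}")
        return cls(taxon, months[0], df["count"].to_numpy())


@dataclass
class RecordError:
    """A malformed input row: its 1-based line (or row) number and the cause."""

    line: int
    message: str


# ---------------------------------------------------------------------------
# readers / writers

_REQUIRED_FIELDS = ("record_id", "title", "abstract", "priority_date", "jurisdiction")


def _record_from_mapping(
    row: dict, line: int, date_window: tuple[_dt.date, _dt.date]
) -> PatentRecord:
    # title/abstract may be empty strings; the identifying fields may not
    missing = [k for k in _REQUIRED_FIELDS if row.get(k) is None]
    missing += [
        k for k in ("record_id", "priority_date", "jurisdiction")
        if row.get(k) == ""
    ]
    if missing:
        raise ValueError(f"missing required field(s): {', '.join(missing)}")
    try:
        date = _dt.date.fromisoformat(str(row["priority_date"]))
    except ValueError as exc:
        raise ValueError(f"unparseable priority_date {row['priority_date']!r}: {exc}") from exc
    lo, hi = date_window
    if not lo <= date <= hi:
        raise ValueError(f"priority_date {date.isoformat()} outside window {lo}..{hi}")
    applicants = row.get("applicants") or []
    matched = row.get("matched_terms") or []
    if isinstance(applicants, str):
        applicants = [a for a in applicants.split("|") if a]
    if isinstance(matched, str):
        matched = [t for t in matched.split("|") if t]
    return PatentRecord(
        record_id=str(row["record_id"]),
        title=str(row["title"]),
        abstract=str(row["abstract"]),
        priority_date=date,
        jurisdiction=str(row["jurisdiction"]),
        applicants=list(applicants),
        taxon=str(row.get("taxon") or ""),
        matched_terms=list(matched),
    )


def read_records(
    path: str | Path,
    fmt: str = "jsonl",
    date_window: tuple[_dt.date, _dt.date] = DEFAULT_DATE_WINDOW,
) -> tuple[list[PatentRecord], list[RecordError]]:
    """Read patent records from a JSONL or CSV file.

    Malformed rows (bad JSON, missing fields, unparseable or out-of-window
    dates) are never silently dropped: each is reported as a
    :class:`RecordError` with its line number. Duplicate ids are legal at this
    stage; see :func:`deduplicate`.

    Returns
    -------
    (records, errors)
        Valid records in file order, and the error report.
    """
    path = Path(path)
    records: list[PatentRecord] = []
    errors: list[RecordError] = []
    if fmt == "jsonl":
        with path.open(encoding="utf-8") as fh:
            for line_no, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    row = json.loads(line)
                    records.append(_record_from_mapping(row, line_no, date_window))
                except (ValueError, TypeError) as exc:
                    errors.append(RecordError(line_no, str(exc)))
    elif fmt == "csv":
        with path.open(encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            for row_no, row in enumerate(reader, start=2):  # header is line 1
                try:
                    records.append(_record_from_mapping(row, row_no, date_window))
                except (ValueError, TypeError) as exc:
                    errors.append(RecordError(row_no, str(exc)))
    else:
        raise ValueError(f"unknown format {fmt!r}; expected 'jsonl' or 'csv'")
    return records, errors


def write_records(records: Iterable[PatentRecord], path: str | Path, fmt: str = "jsonl") -> None:
    """Write records as JSONL (one object per line) or CSV (pipe-delimited lists)."""
    path = Path(path)
    rows = [r.to_dict() for r in records]
    if fmt == "jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for row in rows:
                fh.write(json.dumps(row, ensure_ascii=False) + "\n")
    elif fmt == "csv":
        cols = list(_REQUIRED_FIELDS) + ["applicants", "taxon", "matched_terms"]
        with path.open("w", encoding="utf-8", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=cols)
            writer.writeheader()
            for row in rows:
                row = dict(row)
                row["applicants"] = "|".join(row["applicants"])
                row["matched_terms"] = "|".join(row["matched_terms"])
                writer.writerow(row)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def load_keyword_specs(path: str | Path) -> list[KeywordSpec]:
    """Load keyword specs from YAML/JSON: ``{taxon: {include: [...], exclude: [...]}}``."""
    with Path(path).open(encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    specs = []
    for taxon, entry in data.items():
        specs.append(
            KeywordSpec(
                taxon=taxon,
                include_terms=list(entry.get("include", [])),
                exclude_terms=list(entry.get("exclude", [])),
            )
        )
    return specs


# ---------------------------------------------------------------------------
# deduplication


def deduplicate(records: Sequence[PatentRecord]) -> tuple[list[PatentRecord], int]:
    """Collapse records sharing a ``record_id``, keeping the earliest priority date.

    Output order is the order of first appearance of each id; ties on date
    keep the first-seen record. Returns ``(unique_records, removed_count)``.
    """
    best: dict[str, PatentRecord] = {}
    order: list[str] = []
    for rec in records:
        cur = best.get(rec.record_id)
        if cur is None:
            best[rec.record_id] = rec
            order.append(rec.record_id)
        elif rec.priority_date < cur.priority_date:
            best[rec.record_id] = rec
    out = [best[rid] for rid in order]
    return out, len(records) - len(out)


# ---------------------------------------------------------------------------
# keyword filtering

_LATIN_ONLY = re.compile(r"[A-Za-z0-9\s\-']+\Z")


def _normalize_term(term: str) -> str:
    return re.sub(r"\s+", " ", term.strip().lower())


def _compile_term(term: str) -> re.Pattern:
    """Compile a search term to a case-insensitive pattern.

    Latin-script terms bind to word boundaries, with internal whitespace
    matching any whitespace run (contiguous-phrase semantics). Terms with any
    non-Latin character (e.g. CJK) match as literal substrings, since word
    boundaries are meaningless there.
    """
    norm = _normalize_term(term)
    if _LATIN_ONLY.match(norm):
        parts = [re.escape(p) for p in norm.split(" ")]
        return re.compile(r"\b" + r"\s+".join(parts) + r"\b", re.IGNORECASE)
    return re.compile(re.escape(norm), re.IGNORECASE)


def match_terms(text: str, terms: Sequence[str]) -> list[str]:
    """Return the subset of ``terms`` that matches ``text`` (original spellings)."""
    return [t for t in terms if _compile_term(t).search(text)]


def filter_by_keywords(
    records: Sequence[PatentRecord],
    spec: KeywordSpec,
    fields: Sequence[str] = ("title", "abstract"),
) -> tuple[list[PatentRecord], list[PatentRecord]]:
    """Partition records by include/NOT-exclude keyword rules.

    A record is kept iff at least one include term matches and no exclude
    term matches any of the searched ``fields`` (title and abstract by
    default); exclusion overrides inclusion. Kept records carry their matched
    include terms in ``matched_terms``. The two output lists partition the
    input exactly.
    """
    bad = set(fields) - {"title", "abstract"}
    if bad:
        raise ValueError(f"unknown searchable fields: {sorted(bad)}")
    kept: list[PatentRecord] = []
    excluded: list[PatentRecord] = []
    for rec in records:
        text = " \n ".join(getattr(rec, f) for f in fields)
        if match_terms(text, spec.exclude_terms):
            excluded.append(rec)
            continue
        hits = match_terms(text, spec.include_terms)
        if hits:
            kept.append(replace(rec, matched_terms=hits))
        else:
            excluded.append(rec)
    return kept, excluded


# ---------------------------------------------------------------------------
# monthly aggregation


def aggregate_monthly(
    records: Sequence[PatentRecord],
    window: tuple[str, str],
    taxon: str = "",
) -> tuple[MonthlyCountSeries, int]:
    """Count records per calendar month of their priority date.

    ``window`` is a closed ``("YYYY-MM", "YYYY-MM")`` pair; months with no
    records are explicit zeros. Records dated outside the window are dropped
    and counted in the second return value.
    """
    start, end = window
    n_months = ym_diff(end, start) + 1
    if n_months < 2:
        raise ValueError(f"window {start}..{end} must span at least two months")
    counts = np.zeros(n_months, dtype=np.int64)
    dropped = 0
    for rec in records:
        idx = ym_diff(rec.month, start)
        if 0 <= idx < n_months:
            counts[idx] += 1
        else:
            dropped += 1
    return MonthlyCountSeries(taxon, start, counts), dropped
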