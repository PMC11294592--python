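"""Codebook-based thematic coding of patents.

Topics discovered by LDA are turned into a human-auditable codebook: each
thematic label (medicine, food, farming, synthetics, detection, ...) maps to
a keyword list seeded from the first five non-generic top terms of its LDA
topics plus configured standard terms (e.g. 'disorders' or 'pain' for
medicine). Patents are then coded multi-label: a patent receives every label
with a matching keyword, labels are not mutually exclusive, and every
assignment is backed by a stored (record, keyword, label) match triple.

Coding iterates: while any record is uncovered, an expansion policy proposes
new keywords (the automated default appends each uncovered record's most
frequent non-generic term to its dominant LDA topic's label; a review hook
can substitute human edits), and the corpus is re-coded. Coverage is
monotone non-decreasing because keywords are only ever added.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from patenttrends.records import PatentRecord, match_terms, ym_add, ym_diff
from patenttrends.topics import TopicModelResult, top_terms

__all__ = [
    "TopicCodebook",
    "LabeledCorpus",
    "DEFAULT_LABELS",
    "build_codebook",
    "label_records",
    "iterate_labeling",
    "make_lda_expansion_policy",
    "cumulative_label_proportions",
]

#: Thematic label taxonomy observed across taxa (fully configurable).
DEFAULT_LABELS = [
    "medicine",
    "food",
    "cosmetics",
    "synthetics",
    "farming",
    "processing",
    "detection",
    "agriculture",
    "electronics",
    "leather",
    "snuff",
]

_TOKEN_RE = re.compile(r"\w+", re.UNICODE)

# keyword provenance tags
LDA_TOP_TERM = "lda_top_term"
STANDARD_TERM = "standard_term"


@dataclass
class TopicCodebook:
    """Label -> keyword lists with per-keyword provenance."""

    labels: list[str]
    keywords: dict[str, list[str]]
    provenance: dict[str, dict[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for label in self.labels:
            kws = self.keywords.get(label, [])
            if not kws:
                raise ValueError(f"label {label!r} has no keywords")
            if any(not k for k in kws):
                raise ValueError(f"label {label!r} has an empty keyword")
            self.provenance.setdefault(label, {})
            for k in kws:
                self.provenance[label].setdefault(k, "unspecified")

    def add_keyword(self, label: str, keyword: str, provenance: str) -> bool:
        """Add a keyword; returns False if it was already present."""
        if label not in self.keywords:
            self.labels.append(label)
            self.keywords[label] = []
            self.provenance[label] = {}
        if keyword.lower() in {k.lower() for k in self.keywords[label]}:
            return False
        self.keywords[label].append(keyword)
        self.provenance[label][keyword] = provenance
        return True

    def to_dict(self) -> dict:
        return {
            label: {k: self.provenance[label][k] for k in self.keywords[label]}
            for label in self.labels
        }


@dataclass
class LabeledCorpus:
    """Multi-label assignment with coverage bookkeeping.

    ``matches`` holds one (record_id, keyword, label) triple per assignment
    justification; ``iteration_log`` records (keywords_added, coverage) per
    labeling pass.
    """

    labels_by_record: dict[str, set[str]]
    coverage: float
    uncovered: list[str]
    matches: list[tuple[str, str, str]]
    iteration_log: list[tuple[int, float]] = field(default_factory=list)
    converged: bool = True

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"record_id": rid, "label": lab, "matched_keyword": kw}
            for rid, kw, lab in self.matches
        ]
        return pd.DataFrame(rows, columns=["record_id", "label", "matched_keyword"])


def build_codebook(
    model: TopicModelResult,
    label_map: dict[int, str],
    standard_terms: dict[str, Sequence[str]] | None = None,
    generic_stoplist: Sequence[str] | set = (),
    n_top: int = 5,
) -> TopicCodebook:
    """Seed a codebook from LDA top terms plus configured standard terms.

    Each label collects the first ``n_top`` non-generic terms of every topic
    mapped to it, then its standard terms. Duplicates keep the LDA
    provenance. A label that ends up with zero keywords is an error.
    """
    standard_terms = standard_terms or {}
    per_label: dict[str, list[tuple[str, str]]] = {}
    for topic, label in label_map.items():
        terms, _ = top_terms(model, topic, n_top, generic_stoplist)
        per_label.setdefault(label, []).extend((t, LDA_TOP_TERM) for t in terms)
    for label, terms in standard_terms.items():
        per_label.setdefault(label, []).extend((t, STANDARD_TERM) for t in terms)

    labels, keywords, provenance = [], {}, {}
    for label, pairs in per_label.items():
        kws: list[str] = []
        prov: dict[str, str] = {}
        for term, source in pairs:
            if term.lower() in {k.lower() for k in kws}:
                continue  # first (LDA) source wins
            kws.append(term)
            prov[term] = source
        if not kws:
            raise ValueError(f"label {label!r} resolved to zero keywords")
        labels.append(label)
        keywords[label] = kws
        provenance[label] = prov
    if not labels:
        raise ValueError("codebook has no labels")
    return TopicCodebook(labels, keywords, provenance)


def label_records(
    records: Sequence[PatentRecord],
    codebook: TopicCodebook,
    fields: Sequence[str] = ("title", "abstract"),
) -> LabeledCorpus:
    """Assign every matching codebook label to every record.

    Matching uses the same case-insensitive word-boundary rules as keyword
    filtering. Labels are non-exclusive. Unlabeled records are enumerated in
    ``uncovered``.
    """
    labels_by_record: dict[str, set[str]] = {}
    matches: list[tuple[str, str, str]] = []
    uncovered: list[str] = []
    for rec in records:
        text = " \n ".join(getattr(rec, f) for f in fields)
        got: set[str] = set()
        for label in codebook.labels:
            hits = match_terms(text, codebook.keywords[label])
            for kw in hits:
                matches.append((rec.record_id, kw, label))
            if hits:
                got.add(label)
        labels_by_record[rec.record_id] = got
        if not got:
            uncovered.append(rec.record_id)
    coverage = 1.0 - len(uncovered) / len(records) if records else 1.0
    return LabeledCorpus(labels_by_record, coverage, uncovered, matches)


def make_lda_expansion_policy(
    model: TopicModelResult,
    label_map: dict[int, str],
    generic_stoplist: Sequence[str] | set = (),
) -> Callable[[list[PatentRecord], TopicCodebook], list[tuple[str, str]]]:
    """Automated expansion policy: dominant term -> dominant topic's label.

    For each uncovered record, its most frequent non-generic abstract term is
    proposed as a keyword under the label of its highest-probability LDA
    topic. Records unknown to the model fall back to the first codebook
    label.
    """
    stop = {s.lower() for s in generic_stoplist}
    doc_index = {rid: i for i, rid in enumerate(model.doc_ids)}

    def policy(
        uncovered: list[PatentRecord], codebook: TopicCodebook
    ) -> list[tuple[str, str]]:
        proposals: list[tuple[str, str]] = []
        for rec in uncovered:
            tokens = [
                t for t in _TOKEN_RE.findall(rec.abstract.lower()) if t not in stop
            ]
            if not tokens:
                continue
            term = Counter(tokens).most_common(1)[0][0]
            i = doc_index.get(rec.record_id)
            if i is None:
                label = codebook.labels[0]
            else:
                topic = int(np.argmax(model.doc_topic[i]))
                label = label_map.get(topic, codebook.labels[0])
            proposals.append((label, term))
        return proposals

    return policy


def iterate_labeling(
    records: Sequence[PatentRecord],
    codebook: TopicCodebook,
    expansion_policy: Callable[[list[PatentRecord], TopicCodebook], list[tuple[str, str]]],
    max_iterations: int = 10,
    fields: Sequence[str] = ("title", "abstract"),
) -> tuple[LabeledCorpus, TopicCodebook]:
    """Label, expand the codebook, and repeat until full coverage.

    Each pass labels the corpus; if coverage < 1 the ``expansion_policy`` is
    asked for (label, keyword) proposals for the uncovered records, which are
    appended with ``expansion_iteration_k`` provenance. Terminates on full
    coverage, on ``max_iterations``, or — flagged as non-converged — when the
    policy adds nothing new. Coverage is monotone non-decreasing.
    """
    if max_iterations < 1:
        raise ValueError("max_iterations must be >= 1")
    by_id = {r.record_id: r for r in records}
    labeled = label_records(records, codebook, fields)
    labeled.iteration_log.append((0, labeled.coverage))
    for it in range(1, max_iterations + 1):
        if labeled.coverage >= 1.0:
            break
        uncovered = [by_id[rid] for rid in labeled.uncovered]
        proposals = expansion_policy(uncovered, codebook)
        added = 0
        for label, keyword in proposals:
            if codebook.add_keyword(label, keyword, f"expansion_iteration_{it}"):
                added += 1
        if added == 0:
            labeled.converged = False
            labeled.iteration_log.append((0, labeled.coverage))
            return labeled, codebook
        log = labeled.iteration_log
        labeled = label_records(records, codebook, fields)
        labeled.iteration_log = log + [(added, labeled.coverage)]
    labeled.converged = labeled.coverage >= 1.0
    return labeled, codebook


def cumulative_label_proportions(
    labeled: LabeledCorpus,
    records: Sequence[PatentRecord],
    window: tuple[str, str],
) -> pd.DataFrame:
    """Per-month cumulative share of each label among all label assignments.

    For each month m in the closed window, the numerator of label L is the
    number of (record, L) assignments to records dated at or before m, and
    the denominator is the total number of assignments up to m — a record
    with two labels contributes two, so topics are not mutually exclusive by
    construction. Rows are all-zero until the first labeled record, then sum
    to 1.
    """
    start, end = window
    n_months = ym_diff(end, start) + 1
    if n_months < 1:
        raise ValueError("empty window")
    labels = sorted({lab for labs in labeled.labels_by_record.values() for lab in labs})
    months = [ym_add(start, i) for i in range(n_months)]
    if not labels:
        import warnings

        warnings.warn("no labeled records in window; returning empty proportions")
        return pd.DataFrame(index=pd.Index(months, name="month"))
    counts = np.zeros((n_months, len(labels)))
    col = {lab: j for j, lab in enumerate(labels)}
    for rec in records:
        idx = ym_diff(rec.month, start)
        if idx >= n_months:
            continue
        idx = max(idx, 0)  # records before the window count from its first month
        for lab in labeled.labels_by_record.get(rec.record_id, ()):
            counts[idx, col[lab]] += 1
    cum = counts.cumsum(axis=0)
    totals = cum.sum(axis=1, keepdims=True)
    props = np.divide(cum, totals, out=np.zeros_like(cum), where=totals > 0)
    return pd.DataFrame(props, index=pd.Index(months, name="month"), columns=labels)
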