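"""Synthetic patent corpora with planted ground truth.

The paper-style raw data (a web scrape of patent search results) cannot be
redistributed, so every downstream stage is exercised on generated corpora
with known truth: monthly filing counts follow an NB2 negative-binomial
process with an abrupt planted rate shift; abstracts are token bags drawn
from a planted LDA topic mixture over a Latin-script pseudo-word vocabulary;
each record carries a taxon include keyword, and a configurable fraction
additionally carries a confounder ("decoy") exclusion term emulating
false-positive search hits such as the fruit-fly gene sharing the pangolin
name. Priority dates are uniform within each record's month, since monthly
aggregation is the only downstream consumer of the day field.

All generators are deterministic in their seed.
"""

from __future__ import annotations

import calendar
import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from patenttrends.records import MonthlyCountSeries, PatentRecord, ym_add, ym_parse

__all__ = [
    "SimSeriesConfig",
    "SimCorpusConfig",
    "PlantedTruth",
    "simulate_count_series",
    "simulate_patent_corpus",
    "pseudo_word",
]

_JURISDICTIONS = ["CN", "US", "EP", "JP", "KR", "RU", "GB"]
_JURISDICTION_W = np.array([0.55, 0.15, 0.10, 0.08, 0.06, 0.03, 0.03])

_CONSONANTS = "bcdfghjklmnpqrstvz"
_VOWELS = "aeiou"


def pseudo_word(i: int) -> str:
    """Deterministic Latin-script pseudo-word for vocabulary id ``i``."""
    syllables = []
    n = i
    for _ in range(3):
        syllables.append(_CONSONANTS[n % len(_CONSONANTS)] + _VOWELS[(n // len(_CONSONANTS)) % len(_VOWELS)])
        n //= len(_CONSONANTS) * len(_VOWELS)
    return "".join(syllables) + str(i % 10)


@dataclass
class SimSeriesConfig:
    """Negative-binomial count-series generator settings.

    ``changepoint_month`` is the index of the first month governed by the
    late parameters; ``None`` plants no shift. Dispersion follows the NB2
    convention (variance ``mu + mu**2/phi``).
    """

    n_months: int
    mu_early: float
    mu_late: float
    phi_early: float = 1.0
    phi_late: float = 1.0
    changepoint_month: int | None = None
    seed: int = 0
    taxon: str = ""
    start_month: str = "1970-01"

    def __post_init__(self) -> None:
        if self.n_months < 2:
            raise ValueError("n_months must be >= 2")
        for name in ("mu_early", "mu_late", "phi_early", "phi_late"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.changepoint_month is not None and not (
            1 <= self.changepoint_month <= self.n_months - 1
        ):
            raise ValueError(
                f"changepoint_month must lie strictly inside [1, {self.n_months - 1}]"
            )
        ym_parse(self.start_month)


def _nb2_draw(rng: np.random.Generator, mu: float, phi: float, size: int) -> np.ndarray:
    # NB2(mu, phi) == numpy's negative_binomial(n=phi, p=phi/(phi+mu))
    return rng.negative_binomial(phi, phi / (phi + mu), size=size)


def simulate_count_series(config: SimSeriesConfig) -> MonthlyCountSeries:
    """Draw a monthly count series with an optional planted rate shift.

    Months before ``changepoint_month`` are NB2(mu_early, phi_early); months
    at/after it are NB2(mu_late, phi_late). Identical configs (including
    seed) produce identical series.
    """
    rng = np.random.Generator(np.random.PCG64(config.seed))
    tau = config.changepoint_month if config.changepoint_month is not None else config.n_months
    early = _nb2_draw(rng, config.mu_early, config.phi_early, tau)
    late = _nb2_draw(rng, config.mu_late, config.phi_late, config.n_months - tau)
    return MonthlyCountSeries(config.taxon, config.start_month, np.concatenate([early, late]))


@dataclass
class SimCorpusConfig:
    """Corpus generator settings: one count series per taxon plus the planted
    topic mixture.

    ``topic_word`` may pin the planted topic-word rows explicitly (e.g.
    disjoint-support topics for recovery tests); otherwise rows are drawn
    from a symmetric Dirichlet with concentration
    ``topic_word_concentration``. ``decoy_fraction`` of records carry one of
    the ``decoy_terms`` in their abstract in addition to a taxon include
    keyword.
    """

    series: dict[str, SimSeriesConfig]
    n_topics_true: int = 3
    doc_topic_concentration: float = 0.3
    topic_word_concentration: float = 0.1
    vocabulary_size: int = 200
    doc_length_mean: float = 40.0
    taxon_keywords: dict[str, list[str]] = field(default_factory=dict)
    decoy_terms: list[str] = field(default_factory=lambda: ["drosophila"])
    decoy_fraction: float = 0.0
    topic_word: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.series:
            raise ValueError("at least one taxon series is required")
        if not 0 <= self.decoy_fraction <= 1:
            raise ValueError("decoy_fraction must be in [0, 1]")
        if self.vocabulary_size < self.n_topics_true:
            raise ValueError("vocabulary_size must be >= n_topics_true")
        if self.doc_topic_concentration <= 0 or self.topic_word_concentration <= 0:
            raise ValueError("Dirichlet concentrations must be positive")
        if self.topic_word is not None:
            tw = np.asarray(self.topic_word, dtype=float)
            if tw.shape != (self.n_topics_true, self.vocabulary_size):
                raise ValueError("topic_word must be (n_topics_true, vocabulary_size)")
            if not np.allclose(tw.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError("topic_word rows must sum to 1")
            self.topic_word = tw
        for taxon in self.series:
            if taxon not in self.taxon_keywords:
                self.taxon_keywords.setdefault(taxon, [taxon])


@dataclass
class PlantedTruth:
    """Ground truth for a simulated corpus.

    One entry per generated record in every per-record mapping; topic-word
    rows sum to 1.
    """

    changepoint_index: dict[str, int | None]
    changepoint_month: dict[str, str | None]
    topic_word: np.ndarray
    vocabulary: list[str]
    true_topic: dict[str, int]
    decoy_flag: dict[str, bool]

    def __post_init__(self) -> None:
        tw = np.asarray(self.topic_word, dtype=float)
        if not np.allclose(tw.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("topic_word rows must sum to 1")
        if set(self.true_topic) != set(self.decoy_flag):
            raise ValueError("per-record truth maps must cover the same records")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "changepoint_index": self.changepoint_index,
            "changepoint_month": self.changepoint_month,
            "topic_word": np.asarray(self.topic_word).tolist(),
            "vocabulary": self.vocabulary,
            "true_topic": self.true_topic,
            "decoy_flag": self.decoy_flag,
        }
        Path(path).write_text(json.dumps(payload), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "PlantedTruth":
        d = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            changepoint_index=d["changepoint_index"],
            changepoint_month=d["changepoint_month"],
            topic_word=np.asarray(d["topic_word"]),
            vocabulary=d["vocabulary"],
            true_topic={k: int(v) for k, v in d["true_topic"].items()},
            decoy_flag={k: bool(v) for k, v in d["decoy_flag"].items()},
        )


def simulate_patent_corpus(
    config: SimCorpusConfig,
) -> tuple[list[PatentRecord], PlantedTruth]:
    """Generate patent records driven by per-taxon count series.

    Per taxon and month, exactly as many records are emitted as the driving
    series counts. Abstracts are bags of pseudo-word tokens from the planted
    LDA process, plus one taxon include keyword; a ``decoy_fraction`` share
    of records also carries a decoy exclusion term. Returns the records and
    the :class:`PlantedTruth` aligned to them.
    """
    root = np.random.SeedSequence(config.seed)
    topic_rng, corpus_rng = (np.random.Generator(np.random.PCG64(s)) for s in root.spawn(2))

    vocab = [pseudo_word(i) for i in range(config.vocabulary_size)]
    if config.topic_word is not None:
        topic_word = np.asarray(config.topic_word, dtype=float)
    else:
        topic_word = topic_rng.dirichlet(
            np.full(config.vocabulary_size, config.topic_word_concentration),
            size=config.n_topics_true,
        )

    records: list[PatentRecord] = []
    true_topic: dict[str, int] = {}
    decoy_flag: dict[str, bool] = {}
    cp_index: dict[str, int | None] = {}
    cp_month: dict[str, str | None] = {}

    for taxon in sorted(config.series):
        scfg = config.series[taxon]
        series = simulate_count_series(scfg)
        cp_index[taxon] = scfg.changepoint_month
        cp_month[taxon] = (
            None if scfg.changepoint_month is None else ym_add(scfg.start_month, scfg.changepoint_month)
        )
        keywords = config.taxon_keywords[taxon]
        rec_no = 0
        for m_idx, count in enumerate(series.counts):
            month = series.month_at(m_idx)
            year, mon = ym_parse(month)
            n_days = calendar.monthrange(year, mon)[1]
            for _ in range(int(count)):
                rec_no += 1
                rid = f"{taxon.upper()}-{rec_no:06d}"
                theta = corpus_rng.dirichlet(
                    np.full(config.n_topics_true, config.doc_topic_concentration)
                )
                n_words = max(5, int(corpus_rng.poisson(config.doc_length_mean)))
                zs = corpus_rng.choice(config.n_topics_true, size=n_words, p=theta)
                words = [
                    vocab[int(corpus_rng.choice(config.vocabulary_size, p=topic_word[z]))]
                    for z in zs
                ]
                keyword = keywords[int(corpus_rng.integers(len(keywords)))]
                tokens = words + [keyword]
                is_decoy = bool(
                    config.decoy_terms and corpus_rng.random() < config.decoy_fraction
                )
                if is_decoy:
                    tokens.append(
                        config.decoy_terms[int(corpus_rng.integers(len(config.decoy_terms)))]
                    )
                day = int(corpus_rng.integers(1, n_days + 1))
                counts = np.bincount(zs, minlength=config.n_topics_true)
                records.append(
                    PatentRecord(
                        record_id=rid,
                        title=f"Composition and method relating to {keyword} ({rec_no})",
                        abstract=" ".join(tokens),
                        priority_date=_dt.date(year, mon, day),
                        jurisdiction=_JURISDICTIONS[
                            int(corpus_rng.choice(len(_JURISDICTIONS), p=_JURISDICTION_W))
                        ],
                        applicants=[f"{taxon} applicant {1 + rec_no % 7}"],
                        taxon=taxon,
                    )
                )
                true_topic[rid] = int(np.argmax(counts))
                decoy_flag[rid] = is_decoy

    truth = PlantedTruth(
        changepoint_index=cp_index,
        changepoint_month=cp_month,
        topic_word=topic_word,
        vocabulary=vocab,
        true_topic=true_topic,
        decoy_flag=decoy_flag,
    )
    return records, truth
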