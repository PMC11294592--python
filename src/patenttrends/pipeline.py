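"""End-to-end seeded pipeline: simulate/ingest -> filter -> aggregate ->
changepoint -> topics -> label -> trends -> report.

Every stage reads and writes plain files (JSONL/CSV/JSON/YAML) under the
configured output directory, so any stage can be re-run standalone on
another stage's outputs. The pipeline is a pure function of (config, seed)
at the level of written artifacts: stage seeds are derived deterministically
from the global seed, and the run report deliberately contains no
timestamps so that reruns are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from patenttrends import __version__
from patenttrends.changepoint import (
    ChangepointPosterior,
    ChangepointPriors,
    SamplerConfig,
    sample_changepoint_posterior,
)
from patenttrends.labeling import (
    DEFAULT_LABELS,
    build_codebook,
    cumulative_label_proportions,
    iterate_labeling,
    make_lda_expansion_policy,
)
from patenttrends.records import (
    KeywordSpec,
    aggregate_monthly,
    deduplicate,
    filter_by_keywords,
    read_records,
    write_records,
)
from patenttrends.simulate import SimCorpusConfig, SimSeriesConfig, simulate_patent_corpus
from patenttrends.topics import (
    DEFAULT_STOPLIST,
    LDAConfig,
    fit_lda,
    generic_terms,
    preprocess,
    select_topic_number,
)
from patenttrends.trends import (
    peak_month,
    period_median,
    smooth_series,
    yearly_percent_changes,
)

__all__ = ["PipelineConfig", "RunReport", "StageError", "run_pipeline"]

log = logging.getLogger("patenttrends")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r}: {message}")


@dataclass
class PipelineConfig:
    """Validated pipeline settings (see ``PipelineConfig.from_yaml``)."""

    output_dir: Path
    seed: int = 0
    window: tuple[str, str] = ("1970-01", "1989-12")
    synthetic: dict[str, Any] | None = None
    records_path: Path | None = None
    keywords: dict[str, dict] = field(default_factory=dict)
    changepoint: dict[str, Any] = field(default_factory=dict)
    topics: dict[str, Any] = field(default_factory=dict)
    label: dict[str, Any] = field(default_factory=dict)
    trends: dict[str, Any] = field(default_factory=dict)
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path, seed: int | None = None) -> "PipelineConfig":
        with Path(path).open(encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(
            output_dir=Path(raw.get("output_dir", "pipeline_out")),
            seed=int(raw.get("seed", 0)) if seed is None else int(seed),
            window=(
                str(raw.get("window", {}).get("start", "1970-01")),
                str(raw.get("window", {}).get("end", "1989-12")),
            ),
            synthetic=raw.get("synthetic"),
            records_path=Path(raw["records_path"]) if raw.get("records_path") else None,
            keywords=raw.get("keywords", {}),
            changepoint=raw.get("changepoint", {}),
            topics=raw.get("topics", {}),
            label=raw.get("label", {}),
            trends=raw.get("trends", {}),
            log_level=str(raw.get("log_level", "INFO")),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.synthetic is None and self.records_path is None:
            raise StageError("simulate", "config needs either 'synthetic' or 'records_path'")
        if self.records_path is not None and not self.records_path.exists():
            raise StageError("simulate", f"records_path {self.records_path} does not exist")
        codebook_path = self.label.get("codebook_path")
        if codebook_path and not Path(codebook_path).exists():
            raise StageError("label", f"codebook {codebook_path} does not exist")

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        d["output_dir"] = str(d["output_dir"])
        d["records_path"] = str(d["records_path"]) if d["records_path"] else None
        d["window"] = list(d["window"])
        return d


@dataclass
class RunReport:
    """Per-stage counts, convergence flags and the output-file manifest."""

    version: str
    config: dict
    stages: dict[str, dict] = field(default_factory=dict)
    manifest: list[str] = field(default_factory=list)

    def add(self, stage: str, info: dict, files: list[Path]) -> None:
        self.stages[stage] = info
        self.manifest.extend(sorted(f.name for f in files))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "version": self.version,
                    "config": self.config,
                    "stages": self.stages,
                    "manifest": self.manifest,
                },
                indent=2,
                sort_keys=True,
            ),
            encoding="utf-8",
        )


def _stage_seed(seed: int, stage: str) -> int:
    # crc32 keyed spawn: stable across processes (unlike built-in str hash)
    key = zlib.crc32(stage.encode("utf-8"))
    return int(np.random.SeedSequence([seed, key]).generate_state(1)[0] % (2**31))


def _write_posterior(fit: ChangepointPosterior, stem: Path) -> list[Path]:
    files = []
    tau_csv = stem.with_suffix(".tau_probs.csv")
    pd.DataFrame({"month": fit.candidate_months, "probability": fit.tau_probs}).to_csv(
        tau_csv, index=False, float_format="%.10g"
    )
    files.append(tau_csv)
    if fit.draws is not None:
        draws_csv = stem.with_suffix(".draws.csv")
        flat = {name: arr.reshape(-1) for name, arr in fit.draws.items()}
        chains, keep = next(iter(fit.draws.values())).shape
        flat["chain"] = np.repeat(np.arange(chains), keep)
        pd.DataFrame(flat).to_csv(draws_csv, index=False, float_format="%.10g")
        files.append(draws_csv)
    diag_json = stem.with_suffix(".diagnostics.json")
    diag = {
        "map_month": fit.map_month,
        "converged": fit.converged,
        "parameters": {
            name: {"rhat": d["rhat"], "ess": d["ess"]}
            for name, d in (fit.diagnostics or {}).items()
        },
    }
    diag_json.write_text(json.dumps(diag, indent=2, sort_keys=True), encoding="utf-8")
    files.append(diag_json)
    return files


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute all stages in order, writing each stage's interface files.

    Any stage failure raises :class:`StageError` naming the stage; files
    written by earlier stages are left in place as a partial manifest.
    """
    config.validate()
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(version=__version__, config=config.echo())

    # --- simulate / ingest ------------------------------------------------
    t0 = time.perf_counter()
    if config.synthetic is not None:
        syn = config.synthetic
        taxa_cfg = syn.get("taxa", {})
        if not taxa_cfg:
            raise StageError("simulate", "synthetic config lists no taxa")
        series_cfgs = {}
        for i, (taxon, entry) in enumerate(sorted(taxa_cfg.items())):
            series_cfgs[taxon] = SimSeriesConfig(
                n_months=int(entry["n_months"]),
                mu_early=float(entry["mu_early"]),
                mu_late=float(entry["mu_late"]),
                phi_early=float(entry.get("phi_early", 1.0)),
                phi_late=float(entry.get("phi_late", 1.0)),
                changepoint_month=entry.get("changepoint_month"),
                seed=_stage_seed(config.seed, f"series:{taxon}"),
                taxon=taxon,
                start_month=str(entry.get("start_month", config.window[0])),
            )
        corpus_cfg = SimCorpusConfig(
            series=series_cfgs,
            n_topics_true=int(syn.get("n_topics_true", 3)),
            doc_topic_concentration=float(syn.get("doc_topic_concentration", 0.3)),
            topic_word_concentration=float(syn.get("topic_word_concentration", 0.1)),
            vocabulary_size=int(syn.get("vocabulary_size", 200)),
            doc_length_mean=float(syn.get("doc_length_mean", 40.0)),
            taxon_keywords={t: e.get("keywords", [t]) for t, e in taxa_cfg.items()},
            decoy_terms=list(syn.get("decoy_terms", ["drosophila"])),
            decoy_fraction=float(syn.get("decoy_fraction", 0.0)),
            seed=_stage_seed(config.seed, "corpus"),
        )
        records, truth = simulate_patent_corpus(corpus_cfg)
        records_path = out / "records.jsonl"
        write_records(records, records_path)
        truth_path = out / "planted_truth.json"
        truth.to_json(truth_path)
        report.add("simulate", {"records": len(records)}, [records_path, truth_path])
        errors = []
    else:
        records, errors = read_records(config.records_path)
        report.add("simulate", {"records": len(records), "errors": len(errors)}, [])
    log.info("stage=simulate records=%d elapsed=%.2fs", len(records), time.perf_counter() - t0)

    # --- deduplicate + filter --------------------------------------------
    t0 = time.perf_counter()
    records, removed = deduplicate(records)
    taxa = sorted({r.taxon for r in records})
    kept_by_taxon: dict[str, list] = {}
    filter_files = []
    n_excluded = 0
    for taxon in taxa:
        tax_records = [r for r in records if r.taxon == taxon]
        kw = config.keywords.get(taxon)
        if kw:
            spec = KeywordSpec(taxon, list(kw.get("include", [])), list(kw.get("exclude", [])))
            kept, excluded = filter_by_keywords(tax_records, spec)
        else:
            kept, excluded = tax_records, []
        kept_by_taxon[taxon] = kept
        n_excluded += len(excluded)
        fp = out / f"filtered_{taxon}.jsonl"
        write_records(kept, fp)
        filter_files.append(fp)
    report.add(
        "filter",
        {"duplicates_removed": removed, "excluded": n_excluded,
         "kept": sum(len(v) for v in kept_by_taxon.values())},
        filter_files,
    )
    log.info("stage=filter kept=%d excluded=%d elapsed=%.2fs",
             sum(len(v) for v in kept_by_taxon.values()), n_excluded, time.perf_counter() - t0)

    # --- aggregate --------------------------------------------------------
    t0 = time.perf_counter()
    series_by_taxon = {}
    agg_files = []
    dropped_total = 0
    for taxon in taxa:
        series, dropped = aggregate_monthly(kept_by_taxon[taxon], config.window, taxon)
        series_by_taxon[taxon] = series
        dropped_total += dropped
        fp = out / f"series_{taxon}.csv"
        series.to_csv(fp)
        agg_files.append(fp)
    report.add("aggregate", {"taxa": len(taxa), "dropped_outside_window": dropped_total}, agg_files)
    log.info("stage=aggregate taxa=%d elapsed=%.2fs", len(taxa), time.perf_counter() - t0)

    # --- changepoint -------------------------------------------------------
    t0 = time.perf_counter()
    cp = config.changepoint
    priors = ChangepointPriors(
        mu_prior_mean=float(cp.get("mu_prior_mean", 10.0)),
        phi_prior_mean=float(cp.get("phi_prior_mean", 1.0)),
    )
    cp_files = []
    cp_info = {}
    for taxon in taxa:
        scfg = SamplerConfig(
            iterations=int(cp.get("iterations", 2000)),
            chains=int(cp.get("chains", 4)),
            warmup_fraction=float(cp.get("warmup_fraction", 0.5)),
            target_accept=float(cp.get("target_accept", 0.95)),
            seed=_stage_seed(config.seed, f"changepoint:{taxon}"),
        )
        try:
            fit = sample_changepoint_posterior(series_by_taxon[taxon], priors, scfg)
        except (ValueError, RuntimeError) as exc:
            raise StageError("changepoint", f"taxon {taxon}: {exc}") from exc
        cp_files.extend(_write_posterior(fit, out / f"changepoint_{taxon}"))
        cp_info[taxon] = {"map_month": fit.map_month, "converged": fit.converged}
    report.add("changepoint", cp_info, cp_files)
    log.info("stage=changepoint taxa=%d elapsed=%.2fs", len(taxa), time.perf_counter() - t0)

    # --- topics ------------------------------------------------------------
    t0 = time.perf_counter()
    tp = config.topics
    all_kept = [r for taxon in taxa for r in kept_by_taxon[taxon]]
    if not all_kept:
        raise StageError("topics", "no records survived filtering")
    corpus = preprocess(
        all_kept,
        stoplist=set(tp.get("stoplist", DEFAULT_STOPLIST)),
        min_term_count=int(tp.get("min_term_count", 2)),
    )
    template = LDAConfig(
        n_topics=2,
        eta=float(tp.get("eta", 0.01)),
        gibbs_iterations=int(tp.get("gibbs_iterations", 1000)),
        burn_in=int(tp.get("burn_in", 500)),
        seed=_stage_seed(config.seed, "topics"),
    )
    k_grid = [int(k) for k in tp.get("k_grid", [3])]
    if len(k_grid) > 1:
        k_star, score_table = select_topic_number(corpus, k_grid, template)
    else:
        k_star = k_grid[0]
        score_table = pd.DataFrame({"k": [k_star]})
    model = fit_lda(
        corpus,
        LDAConfig(
            n_topics=k_star,
            eta=template.eta,
            gibbs_iterations=template.gibbs_iterations,
            burn_in=template.burn_in,
            seed=(template.seed * 131 + k_star) % (2**31),
        ),
    )
    topic_files = []
    tw_csv = out / "topic_word.csv"
    pd.DataFrame(model.topic_word, columns=model.vocabulary).to_csv(
        tw_csv, index_label="topic", float_format="%.10g"
    )
    dt_csv = out / "doc_topic.csv"
    pd.DataFrame(model.doc_topic, index=model.doc_ids).to_csv(
        dt_csv, index_label="record_id", float_format="%.10g"
    )
    scores_csv = out / "topic_scores.csv"
    score_table.to_csv(scores_csv, index=False, float_format="%.10g")
    topic_files += [tw_csv, dt_csv, scores_csv]
    report.add(
        "topics",
        {"k_selected": k_star, "vocabulary": corpus.vocab_size,
         "documents": corpus.n_docs, "dropped_documents": len(corpus.dropped_doc_ids)},
        topic_files,
    )
    log.info("stage=topics k=%d docs=%d elapsed=%.2fs", k_star, corpus.n_docs, time.perf_counter() - t0)

    # --- label -------------------------------------------------------------
    t0 = time.perf_counter()
    lb = config.label
    labels_pool = list(lb.get("labels", DEFAULT_LABELS))
    explicit_map = lb.get("label_map") or {}
    label_map = {
        t: explicit_map.get(t, explicit_map.get(str(t), labels_pool[t % len(labels_pool)]))
        for t in range(model.n_topics)
    }
    standard_terms = lb.get("standard_terms", {})
    if lb.get("codebook_path"):
        with Path(lb["codebook_path"]).open(encoding="utf-8") as fh:
            extra = yaml.safe_load(fh) or {}
        standard_terms = {**extra, **standard_terms}
    generic = set(DEFAULT_STOPLIST) | generic_terms(corpus)
    try:
        codebook = build_codebook(model, label_map, standard_terms, generic)
    except ValueError as exc:
        raise StageError("label", str(exc)) from exc
    policy = make_lda_expansion_policy(model, label_map, generic)
    labeled, codebook = iterate_labeling(
        all_kept, codebook, policy, max_iterations=int(lb.get("max_iterations", 10))
    )
    label_files = []
    labels_csv = out / "labels.csv"
    labeled.to_frame().to_csv(labels_csv, index=False)
    codebook_yaml = out / "codebook.yaml"
    codebook_yaml.write_text(
        yaml.safe_dump(codebook.to_dict(), sort_keys=True), encoding="utf-8"
    )
    props_csv = out / "cumulative_label_proportions.csv"
    cumulative_label_proportions(labeled, all_kept, config.window).to_csv(
        props_csv, float_format="%.10g"
    )
    label_files += [labels_csv, codebook_yaml, props_csv]
    report.add(
        "label",
        {"coverage": labeled.coverage, "converged": labeled.converged,
         "iterations": len(labeled.iteration_log)},
        label_files,
    )
    log.info("stage=label coverage=%.3f elapsed=%.2fs", labeled.coverage, time.perf_counter() - t0)

    # --- trends ------------------------------------------------------------
    t0 = time.perf_counter()
    tr = config.trends
    trend_files = []
    for taxon in taxa:
        series = series_by_taxon[taxon]
        start_year = int(tr.get("start_year", int(config.window[0][:4]) + 1))
        end_year = int(tr.get("end_year", int(config.window[1][:4])))
        summary = yearly_percent_changes(series, start_year, end_year)
        if tr.get("median_period"):
            p = tr["median_period"]
            summary.period_medians[f"{p[0]}..{p[1]}"] = period_median(series, (p[0], p[1]))
        summary.peak = peak_month(series)
        fp = out / f"trends_{taxon}.json"
        summary.to_json(fp)
        trend_files.append(fp)
        smooth_csv = out / f"smoothed_{taxon}.csv"
        window = int(tr.get("smooth_window", 13))
        pd.DataFrame(
            {"month": series.months, "count": series.counts,
             "smoothed": smooth_series(series, window)}
        ).to_csv(smooth_csv, index=False, float_format="%.10g")
        trend_files.append(smooth_csv)
    report.add("trends", {"taxa": len(taxa)}, trend_files)
    log.info("stage=trends taxa=%d elapsed=%.2fs", len(taxa), time.perf_counter() - t0)

    report_path = out / "run_report.json"
    report.to_json(report_path)
    return report
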