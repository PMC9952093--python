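"""End-to-end pipeline runs: ingest -> preprocess -> vectorize -> cluster ->
describe, plus group-comparison and evidence-table runs.

Every run writes a bundle of plain-text artifacts (CSV tables, JSON
summaries) into an output directory together with a run manifest recording
the full configuration and seed, so re-running from the manifest reproduces
the bundle bit-identically.  Floating-point cells are written with a fixed
12-significant-digit format for that reason.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .analyze import citation_stats, pca_2d, top_words, topn_overlap, trend_by_year
from .cluster import kmeans_fit, subcluster, sweep_k
from .corpus import (
    Corpus,
    read_corpus_csv,
    read_espacenet_export,
    read_scopus_csv,
    split_by_open_access,
    split_top_cited,
    write_corpus_csv,
)
from .evidence import load_activity_table, summarize
from .preprocess import default_policy, preprocess_corpus
from .vectorize import fit_vocabulary, tfidf

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_review", "run_compare", "run_evidence"]

_FLOAT_FORMAT = "%.12g"


@dataclass
class PipelineConfig:
    """Everything a run needs; serializable to/from YAML."""

    input_path: str | None = None
    input_format: str = "canonical"  # canonical | scopus | espacenet
    column_map: dict = field(default_factory=dict)
    extra_stopwords: tuple[str, ...] = ()
    min_len: int = 2
    max_len: int = 21
    min_df: int = 1
    k_min: int = 2
    k_max: int = 16
    k: int | None = None            # override the silhouette-guided choice
    seed: int = 0
    n_init: int = 10
    subcluster_target: int | None = None
    compare_mode: str = "open_access"  # open_access | citations
    citation_fraction: float = 0.2
    top_n: int = 20
    year_min: int = 2001
    year_max: int = 2021
    activity_table: str | None = None  # None -> packaged evidence table
    outdir: str = "litmine_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.column_map = dict(cfg.column_map)
        cfg.extra_stopwords = tuple(cfg.extra_stopwords)
        return cfg

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["extra_stopwords"] = list(self.extra_stopwords)
        return out

    def write_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def _load_corpus(config: PipelineConfig) -> Corpus:
    if not config.input_path:
        raise FileNotFoundError("no input_path configured")
    path = Path(config.input_path)
    if not path.exists():
        raise FileNotFoundError(f"input path does not exist: {path}")
    if config.input_format == "scopus":
        return read_scopus_csv(path, column_map=config.column_map or None)
    if config.input_format == "espacenet":
        return read_espacenet_export(path)
    if config.input_format == "canonical":
        return read_corpus_csv(path)
    raise ValueError(f"unknown input_format {config.input_format!r}")


def _policy(config: PipelineConfig):
    base = default_policy(extra_custom=config.extra_stopwords)
    return dataclasses.replace(base, min_len=config.min_len, max_len=config.max_len)


def _write_csv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, index=False, float_format=_FLOAT_FORMAT)


def _write_json(payload: dict, path: Path) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _manifest(config: PipelineConfig, stage_sizes: dict, outdir: Path) -> None:
    _write_json(
        {
            "tool": "litmine",
            "version": __version__,
            "config": config.to_dict(),
            "stage_sizes": stage_sizes,
        },
        outdir / "manifest.json",
    )


def run_review(config: PipelineConfig, corpus: Corpus | None = None) -> dict:
    """The full review pipeline on one corpus.

    Writes: canonical corpus copy, cluster assignments with silhouettes,
    k-selection report, per-cluster top-word tables, 2-D PCA projection,
    year-by-cluster trend table, and the run manifest.  Returns a small
    in-memory summary (chosen k, cluster sizes, output paths).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if corpus is None:
        corpus = _load_corpus(config)
    stage_sizes = {"ingest": len(corpus)}
    logger.info("ingest: %d documents", len(corpus))

    toks = preprocess_corpus(corpus, _policy(config))
    stage_sizes["preprocess_tokens"] = int(sum(len(t.tokens) for t in toks))
    vocab = fit_vocabulary(toks, min_df=config.min_df)
    X = tfidf(toks, vocab)
    stage_sizes["vocabulary"] = len(vocab)
    logger.info("vectorize: %d x %d matrix", X.n_docs, X.n_terms)

    k_max = min(config.k_max, len(corpus))
    report = sweep_k(X, k_min=config.k_min, k_max=k_max, seed=config.seed, n_init=config.n_init)
    final_k = config.k if config.k is not None else report.chosen_k
    result = report.results.get(final_k) or kmeans_fit(
        X, final_k, seed=config.seed, n_init=config.n_init
    )
    stage_sizes["clusters"] = int(result.k)

    write_corpus_csv(corpus, outdir / "corpus.csv")
    _write_csv(
        pd.DataFrame(
            {
                "id": X.doc_ids,
                "cluster": result.labels,
                "silhouette": result.silhouettes,
            }
        ),
        outdir / "assignments.csv",
    )
    _write_json(
        {**report.summary(), "final_k": int(final_k), "k_overridden": config.k is not None},
        outdir / "kselect.json",
    )

    toks_by_cluster = {
        c: [t for t, lab in zip(toks, result.labels) if lab == c]
        for c in range(result.k)
    }
    top_tables = []
    for c, ctoks in toks_by_cluster.items():
        tab = top_words(ctoks, n=config.top_n, scope=f"cluster {c}")
        frame = tab.table.copy()
        frame.insert(0, "cluster", c)
        top_tables.append(frame)
    _write_csv(pd.concat(top_tables, ignore_index=True), outdir / "top_words.csv")

    proj = pca_2d(X, result.centroids)
    doc_frame = pd.DataFrame(
        {
            "id": X.doc_ids,
            "x": proj.doc_xy[:, 0],
            "y": proj.doc_xy[:, 1],
            "cluster": result.labels,
        }
    )
    cen_frame = pd.DataFrame(
        {
            "id": [f"centroid{c}" for c in range(result.k)],
            "x": proj.centroid_xy[:, 0],
            "y": proj.centroid_xy[:, 1],
            "cluster": list(range(result.k)),
        }
    )
    _write_csv(pd.concat([doc_frame, cen_frame], ignore_index=True), outdir / "projection.csv")

    trend = trend_by_year(corpus, result.labels, config.year_min, config.year_max)
    trend.counts.to_csv(outdir / "trends.csv")

    if config.subcluster_target is not None:
        sub, sub_report, sub_result = subcluster(
            corpus,
            result,
            config.subcluster_target,
            policy=_policy(config),
            min_df=config.min_df,
            k_min=config.k_min,
            k_max=config.k_max,
            seed=config.seed,
            n_init=config.n_init,
        )
        _write_csv(
            pd.DataFrame(
                {
                    "id": [d.id for d in sub],
                    "subcluster": sub_result.labels,
                    "silhouette": sub_result.silhouettes,
                }
            ),
            outdir / "subcluster_assignments.csv",
        )
        _write_json(sub_report.summary(), outdir / "subcluster_kselect.json")
        stage_sizes["subcluster_documents"] = len(sub)

    _manifest(config, stage_sizes, outdir)
    return {
        "n_documents": len(corpus),
        "chosen_k": int(report.chosen_k),
        "final_k": int(final_k),
        "cluster_sizes": [int(s) for s in result.sizes],
        "outdir": str(outdir),
    }


def run_compare(
    config: PipelineConfig,
    mode: str | None = None,
    fraction: float | None = None,
    corpus: Corpus | None = None,
) -> dict:
    """Split the corpus by a metadata attribute and compare group language.

    Produces per-group top-word tables, their top-N overlap report, and (for
    the citation mode) per-group citation summaries.
    """
    mode = mode or config.compare_mode
    fraction = config.citation_fraction if fraction is None else fraction
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if corpus is None:
        corpus = _load_corpus(config)

    if mode == "open_access":
        if all(d.open_access is None for d in corpus):
            raise ValueError("corpus has no open_access metadata")
        group_a, group_b = split_by_open_access(corpus)
        group_names = ("open_access", "closed_access")
    elif mode == "citations":
        group_a, group_b = split_top_cited(corpus, fraction)
        group_names = ("most_cited", "rest")
    else:
        raise ValueError(f"unknown compare mode {mode!r}")

    policy = _policy(config)
    tables = {}
    for name, group in zip(group_names, (group_a, group_b)):
        toks = preprocess_corpus(group, policy)
        tab = top_words(toks, n=config.top_n, scope=name)
        tables[name] = tab
        _write_csv(tab.table, outdir / f"top_words_{name}.csv")

    overlap = topn_overlap(tables[group_names[0]], tables[group_names[1]], n=config.top_n)
    payload = {
        "mode": mode,
        "group_sizes": {group_names[0]: len(group_a), group_names[1]: len(group_b)},
        "top_n": overlap.n,
        "common_count": overlap.common_count,
        "common_terms": sorted(overlap.common_terms),
        "only_" + group_names[0]: [list(t) for t in overlap.only_a],
        "only_" + group_names[1]: [list(t) for t in overlap.only_b],
    }
    if mode == "citations":
        for name, group in zip(group_names, (group_a, group_b)):
            stats = citation_stats(group)
            payload[f"citations_{name}"] = {
                "min": stats.min,
                "max": stats.max,
                "mean": round(stats.mean, 2),
                "median": stats.median,
            }
    _write_json(payload, outdir / f"compare_{mode}.json")
    _manifest(config, {"ingest": len(corpus)}, outdir)
    return payload


def run_evidence(config: PipelineConfig) -> dict:
    """Summarize an antibacterial evidence table (packaged table by default):
    category shares per field and per-bacterium mean MICs, as CSV + JSON."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = load_activity_table(config.activity_table)
    summary = summarize(records)
    for fld, frame in summary.shares.items():
        _write_csv(frame, outdir / f"evidence_share_{fld}.csv")
    _write_csv(summary.means.assign(mean_mic=summary.means["mean_mic"].round(3)),
               outdir / "evidence_means.csv")
    payload = summary.to_json_dict()
    _write_json(payload, outdir / "evidence_summary.json")
    _manifest(config, {"evidence_records": summary.n_records}, outdir)
    return payload
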