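"""Labeled synthetic corpora and activity tables with known ground truth.

The corpus generator emulates the structure of a topic-clustered abstract
collection: each document belongs to one latent topic and its tokens are
drawn i.i.d. — from the topic's private vocabulary with probability
``p_topic``, otherwise from a background vocabulary shared by all topics
(the generic terms — "plant", "study" — that dominate real abstract
corpora and make cluster recovery nontrivial).  Publication year, citation
count (rounded log-normal) and Open Access flag are drawn independently of
the topic unless configured otherwise.

Synthetic words are consonant-only strings over an alphabet that no Porter
rule rewrites and no stopword list contains, so they pass the preprocessing
stage unchanged; topic vocabularies are pairwise disjoint by construction.

Everything is driven by one ``numpy`` generator seeded from the config, so
identical configurations produce byte-identical corpora.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import fmean
from typing import Sequence

import numpy as np
import pandas as pd

from .corpus import Corpus, Document

__all__ = [
    "TopicSpec",
    "GeneratorConfig",
    "generate_labeled_corpus",
    "generate_nested_corpus",
    "generate_activity_table",
]

# Consonants whose strings are fixed points of the Porter stemmer (no vowels,
# no y, and none of the letters suffix rules need: s, e, d, g).
_WORD_ALPHABET = "bcfhklmnprtvwz"


def _encode(j: int, length: int = 3) -> str:
    base = len(_WORD_ALPHABET)
    out = []
    for _ in range(length):
        out.append(_WORD_ALPHABET[j % base])
        j //= base
    return "".join(out)


def make_topic_word(topic: int, j: int) -> str:
    return f"k{_WORD_ALPHABET[topic % len(_WORD_ALPHABET)]}{_encode(j)}"


def make_background_word(j: int) -> str:
    return f"bb{_encode(j)}"


@dataclass(frozen=True)
class TopicSpec:
    """One latent topic: its private vocabulary, prevalence weight and the
    linear slope of its expected share of documents across the year range."""

    topic_id: int
    vocabulary: tuple[str, ...]
    weight: float = 1.0
    year_trend: float = 0.0

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValueError("topic weight must be positive")
        if not self.vocabulary:
            raise ValueError("topic vocabulary must be non-empty")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions of the synthetic corpus.

    Defaults model a mid-sized single-topic-per-document abstract corpus:
    five equally prevalent topics over 500 documents, 60 content tokens per
    abstract (the tokens surviving stopword removal in a real abstract),
    70% topic-specific vocabulary against a shared background of 100 terms,
    years 2001-2021, heavy-tailed citation counts, 30% open access.
    """

    n_docs: int = 500
    k_topics: int = 5
    tokens_per_doc: int = 60
    p_topic: float = 0.7
    topic_vocab_size: int = 40
    background_vocab_size: int = 100
    weights: tuple[float, ...] | None = None
    year_trends: tuple[float, ...] | None = None
    year_range: tuple[int, int] = (2001, 2021)
    citation_lognorm: tuple[float, float] = (2.5, 1.2)  # (mu, sigma)
    p_open_access: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.p_topic <= 1:
            raise ValueError("p_topic must be in [0, 1]")
        if self.n_docs < self.k_topics:
            raise ValueError("need at least one document per topic")
        if self.k_topics < 1 or self.tokens_per_doc < 1:
            raise ValueError("k_topics and tokens_per_doc must be positive")
        if self.weights is not None and len(self.weights) != self.k_topics:
            raise ValueError("weights length must equal k_topics")
        if self.year_trends is not None and len(self.year_trends) != self.k_topics:
            raise ValueError("year_trends length must equal k_topics")
        if not 0 <= self.p_open_access <= 1:
            raise ValueError("p_open_access must be in [0, 1]")
        if self.year_range[0] > self.year_range[1]:
            raise ValueError("invalid year range")

    def topics(self) -> list[TopicSpec]:
        weights = self.weights or tuple(1.0 for _ in range(self.k_topics))
        trends = self.year_trends or tuple(0.0 for _ in range(self.k_topics))
        return [
            TopicSpec(
                topic_id=t,
                vocabulary=tuple(
                    make_topic_word(t, j) for j in range(self.topic_vocab_size)
                ),
                weight=weights[t],
                year_trend=trends[t],
            )
            for t in range(self.k_topics)
        ]


def _sample_year(rng: np.random.Generator, spec: TopicSpec, years: np.ndarray) -> int:
    # Linear-in-year density 1 + slope * progress, clipped at zero.
    progress = (years - years[0]) / max(len(years) - 1, 1)
    density = np.clip(1.0 + spec.year_trend * progress, 0.0, None)
    if density.sum() == 0:
        density = np.ones_like(density)
    return int(rng.choice(years, p=density / density.sum()))


def _zipf_probs(n_words: int, zipf_s: float = 1.0) -> np.ndarray:
    """Zipf rank weights.  Word frequencies in real corpora are Zipfian, so
    every vocabulary pool (background and topic alike) is sampled with
    1/rank weights: generic terms dominate the frequency tables the way
    "plant" or "study" do in real abstract corpora, and each topic has a few
    characteristic frequent words above a long tail."""
    ranks = np.arange(1, n_words + 1, dtype=float)
    p = ranks ** -zipf_s
    return p / p.sum()


def _draw_tokens(
    rng: np.random.Generator,
    n: int,
    p_topic: float,
    topic_vocab: Sequence[str],
    background: Sequence[str],
    topic_probs: np.ndarray,
    bg_probs: np.ndarray,
) -> list[str]:
    from_topic = rng.random(n) < p_topic
    return [
        topic_vocab[rng.choice(len(topic_vocab), p=topic_probs)]
        if t
        else background[rng.choice(len(background), p=bg_probs)]
        for t in from_topic
    ]


def generate_labeled_corpus(config: GeneratorConfig) -> tuple[Corpus, np.ndarray]:
    """Generate a corpus plus the ground-truth topic label per document."""
    rng = np.random.default_rng(config.seed)
    topics = config.topics()
    vocabularies = [set(t.vocabulary) for t in topics]
    for i in range(len(vocabularies)):
        for j in range(i + 1, len(vocabularies)):
            if vocabularies[i] & vocabularies[j]:
                raise ValueError("topic vocabularies are not disjoint")
    background = [make_background_word(j) for j in range(config.background_vocab_size)]
    bg_probs = _zipf_probs(config.background_vocab_size)
    topic_probs = _zipf_probs(config.topic_vocab_size)
    weights = np.asarray([t.weight for t in topics], dtype=float)
    weights = weights / weights.sum()
    years = np.arange(config.year_range[0], config.year_range[1] + 1)
    mu, sigma = config.citation_lognorm

    docs, labels = [], []
    for i in range(config.n_docs):
        t = int(rng.choice(config.k_topics, p=weights))
        spec = topics[t]
        tokens = _draw_tokens(
            rng, config.tokens_per_doc, config.p_topic, spec.vocabulary, background,
            topic_probs, bg_probs,
        )
        docs.append(
            Document(
                id=f"syn{i + 1:05d}",
                title="",
                abstract=" ".join(tokens),
                year=_sample_year(rng, spec, years),
                citations=int(np.round(rng.lognormal(mu, sigma))),
                open_access=bool(rng.random() < config.p_open_access),
                source="article",
            )
        )
        labels.append(t)
    corpus = Corpus(docs, provenance=f"synthetic(seed={config.seed})")
    return corpus, np.asarray(labels, dtype=np.int64)


def generate_nested_corpus(
    config: GeneratorConfig,
    n_subtopics: int = 3,
    nested_topic: int = 0,
    core_fraction: float = 0.25,
    p_core: float = 0.7,
) -> tuple[Corpus, np.ndarray, np.ndarray]:
    """Corpus where one topic is itself a mixture of sub-topics.

    The nested topic's vocabulary is partitioned into a shared core
    (``core_fraction`` of its words) plus one disjoint block per sub-topic.
    A nested document's topic-vocabulary tokens come from the core with
    probability ``p_core`` and otherwise from its own sub-block, so *all*
    sub-structure stays inside the parent's vocabulary: at corpus scale the
    topic clusters as one coherent group, while re-vectorizing its documents
    alone exposes the sub-blocks.  Sub-topics have equal prevalence and are
    assigned to the nested documents in balanced rotation.

    Returns the corpus, the coarse topic labels, and fine labels (sub-topic
    index for nested documents, -1 elsewhere).
    """
    if n_subtopics < 1:
        raise ValueError("n_subtopics must be >= 1")
    if not 0 <= nested_topic < config.k_topics:
        raise ValueError("nested_topic out of range")
    if n_subtopics == 1:
        corpus, labels = generate_labeled_corpus(config)
        fine = np.where(labels == nested_topic, 0, -1)
        return corpus, labels, fine
    if config.topic_vocab_size < 2 * n_subtopics:
        raise ValueError("topic vocabulary too small to split into sub-blocks")

    rng = np.random.default_rng(config.seed)
    topics = config.topics()
    background = [make_background_word(j) for j in range(config.background_vocab_size)]
    bg_probs = _zipf_probs(config.background_vocab_size)
    topic_probs = _zipf_probs(config.topic_vocab_size)
    nested_vocab = list(topics[nested_topic].vocabulary)
    n_core = max(1, int(round(core_fraction * len(nested_vocab))))
    core = nested_vocab[:n_core]
    core_probs = _zipf_probs(n_core)
    blocks = [list(b) for b in np.array_split(np.asarray(nested_vocab[n_core:]), n_subtopics)]
    weights = np.asarray([t.weight for t in topics], dtype=float)
    weights = weights / weights.sum()
    years = np.arange(config.year_range[0], config.year_range[1] + 1)
    mu, sigma = config.citation_lognorm

    docs, coarse, fine = [], [], []
    n_nested_seen = 0
    for i in range(config.n_docs):
        t = int(rng.choice(config.k_topics, p=weights))
        spec = topics[t]
        if t == nested_topic:
            s = n_nested_seen % n_subtopics
            n_nested_seen += 1
            tokens = []
            for _ in range(config.tokens_per_doc):
                if rng.random() < config.p_topic:
                    # Zipf head as the shared core; flat tail as sub-blocks.
                    if rng.random() < p_core:
                        tokens.append(core[int(rng.choice(len(core), p=core_probs))])
                    else:
                        tokens.append(blocks[s][int(rng.integers(len(blocks[s])))])
                else:
                    tokens.append(background[int(rng.choice(len(background), p=bg_probs))])
        else:
            s = -1
            tokens = _draw_tokens(
                rng, config.tokens_per_doc, config.p_topic, spec.vocabulary, background,
                topic_probs, bg_probs,
            )
        docs.append(
            Document(
                id=f"syn{i + 1:05d}",
                title="",
                abstract=" ".join(tokens),
                year=_sample_year(rng, spec, years),
                citations=int(np.round(rng.lognormal(mu, sigma))),
                open_access=bool(rng.random() < config.p_open_access),
                source="article",
            )
        )
        coarse.append(t)
        fine.append(s)
    corpus = Corpus(docs, provenance=f"synthetic-nested(seed={config.seed})")
    return corpus, np.asarray(coarse, dtype=np.int64), np.asarray(fine, dtype=np.int64)


# Category pools for synthetic evidence tables.  Values per bacterium follow
# log-normal MIC distributions; the generator returns the exact summary its
# own draws imply, for oracle comparison.
_SPECIES = ("Cistus alpha", "Cistus beta", "Cistus gamma", "Cistus delta")
_PARTS = ("Leaves", "Aerial parts", "Flowers", "Whole plant")
_SOLVENTS = ("Ethanol", "Water", "Methanol", "Acetone", "Hexane")
_BACTERIA = (
    "Staphylococcus aureus",
    "Escherichia coli",
    "Pseudomonas aeruginosa",
    "Bacillus subtilis",
)


def generate_activity_table(
    n_records: int, seed: int = 0, p_mic50: float = 0.1
) -> tuple[pd.DataFrame, dict]:
    """Synthetic evidence table plus its exact ground-truth summary.

    Returns a DataFrame in the canonical evidence-CSV schema and a dict with
    the exact (unrounded) category shares and per-bacterium MIC-only means
    implied by the generated rows.
    """
    if n_records < 1:
        raise ValueError("n_records must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_records):
        bact = _BACTERIA[int(rng.integers(len(_BACTERIA)))]
        value = float(np.round(rng.lognormal(0.5, 1.0), 3))
        value = max(value, 0.001)
        mic50 = bool(rng.random() < p_mic50)
        rows.append(
            {
                "species": _SPECIES[int(rng.integers(len(_SPECIES)))],
                "part": _PARTS[int(rng.integers(len(_PARTS)))],
                "solvent": _SOLVENTS[int(rng.integers(len(_SOLVENTS)))],
                "bacterium": bact,
                "value": f"{value} #" if mic50 else str(value),
                "reference": f"synref{int(rng.integers(1, 9)):02d}",
                "_value_num": value,
                "_mic50": mic50,
            }
        )
    frame = pd.DataFrame(rows)
    truth: dict = {"shares": {}, "means": {}, "n_records": n_records}
    for fld in ("species", "part", "solvent", "bacterium"):
        counts = frame[fld].value_counts()
        truth["shares"][fld] = {
            k: 100.0 * v / n_records for k, v in counts.items()
        }
    for bact in sorted(frame["bacterium"].unique()):
        sub = frame[(frame["bacterium"] == bact) & (~frame["_mic50"])]
        if len(sub):
            truth["means"][bact] = {
                "mean": fmean(sub["_value_num"]),
                "n": int(len(sub)),
            }
    return frame.drop(columns=["_value_num", "_mic50"]), truth
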