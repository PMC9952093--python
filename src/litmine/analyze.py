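"""Descriptive analyses over a clustered corpus: word-frequency tables
(bar-graph and word-cloud data), year-by-cluster trend tables, 2-D PCA
projections with centroids, top-N word-list overlaps between groups, and
citation summaries.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from statistics import fmean, median
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA

from .corpus import Corpus
from .preprocess import TokenizedDoc

__all__ = [
    "WordFrequencyTable",
    "TrendTable",
    "Projection2D",
    "OverlapReport",
    "CitationStats",
    "top_words",
    "wordcloud_data",
    "trend_by_year",
    "pca_2d",
    "topn_overlap",
    "citation_stats",
]


@dataclass(frozen=True)
class WordFrequencyTable:
    """Ranked (term, count, relative_frequency) rows for one scope.

    Relative frequency is the term's share of all token occurrences in the
    scope (so the full, un-truncated table sums to 1).  Rows are ordered by
    count descending, ties broken alphabetically; ranks run from 1.
    """

    table: pd.DataFrame  # columns: term, count, relative_frequency, rank
    scope: str = "corpus"
    total_tokens: int = 0

    @property
    def terms(self) -> tuple[str, ...]:
        return tuple(self.table["term"])

    def __len__(self) -> int:
        return len(self.table)


def top_words(
    docs: Sequence[TokenizedDoc],
    n: int,
    scope: str = "corpus",
    mode: str = "token",
) -> WordFrequencyTable:
    """The ``n`` most frequent terms in the pooled token stream.

    ``mode="token"`` counts every occurrence; ``mode="document"`` counts each
    term once per document (document frequency), relative to the number of
    documents.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if mode not in ("token", "document"):
        raise ValueError(f"unknown mode {mode!r}")
    counts: Counter[str] = Counter()
    for doc in docs:
        counts.update(doc.tokens if mode == "token" else set(doc.tokens))
    total = sum(counts.values()) if mode == "token" else max(len(docs), 1)
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:n]
    table = pd.DataFrame(
        {
            "term": [t for t, _ in ranked],
            "count": [c for _, c in ranked],
            "relative_frequency": [c / total if total else 0.0 for _, c in ranked],
            "rank": np.arange(1, len(ranked) + 1),
        }
    )
    return WordFrequencyTable(table=table, scope=scope, total_tokens=total)


def wordcloud_data(docs: Sequence[TokenizedDoc], n: int = 75, scope: str = "corpus") -> WordFrequencyTable:
    """(term, weight) rows for a word-cloud renderer: the 75 most common
    terms by default, weights proportional to counts."""
    return top_words(docs, n=n, scope=scope)


@dataclass(frozen=True)
class TrendTable:
    """Document counts per (year, cluster) within a year range."""

    counts: pd.DataFrame  # index: year, columns: cluster ids
    n_unknown_year: int = 0
    n_outside_range: int = 0


def trend_by_year(
    corpus: Corpus,
    labels: Sequence[int],
    year_min: int = 2001,
    year_max: int = 2021,
) -> TrendTable:
    """Cluster size per calendar year; unknown-year documents are excluded
    and reported in the table metadata."""
    if year_min > year_max:
        raise ValueError(f"year_min {year_min} > year_max {year_max}")
    labels = np.asarray(labels)
    if len(labels) != len(corpus):
        raise ValueError("labels are not aligned with the corpus")
    clusters = sorted(set(int(c) for c in labels))
    years = range(year_min, year_max + 1)
    counts = pd.DataFrame(0, index=list(years), columns=clusters)
    counts.index.name = "year"
    n_unknown = n_outside = 0
    for doc, lab in zip(corpus, labels):
        if doc.year is None:
            n_unknown += 1
        elif not year_min <= doc.year <= year_max:
            n_outside += 1
        else:
            counts.loc[doc.year, int(lab)] += 1
    return TrendTable(counts=counts, n_unknown_year=n_unknown, n_outside_range=n_outside)


@dataclass(frozen=True)
class Projection2D:
    """Documents and centroids projected on the top-2 principal axes."""

    doc_xy: np.ndarray        # (n_docs, 2)
    centroid_xy: np.ndarray   # (k, 2)
    explained_variance: tuple[float, float]
    explained_variance_ratio: tuple[float, float]


def pca_2d(X, centroids: np.ndarray | None = None) -> Projection2D:
    """Exact (full-SVD) PCA of the row-centered matrix, projecting optional
    centroids with the same centering and axes."""
    A = getattr(X, "weights", X)
    if sp.issparse(A):
        A = A.toarray()
    A = np.asarray(A, dtype=np.float64)
    if A.shape[0] < 2 or A.shape[1] < 2:
        raise ValueError("pca_2d needs at least 2 documents and 2 terms")
    pca = PCA(n_components=2, svd_solver="full")
    doc_xy = pca.fit_transform(A)
    centroid_xy = (
        pca.transform(np.asarray(centroids, dtype=np.float64))
        if centroids is not None
        else np.empty((0, 2))
    )
    return Projection2D(
        doc_xy=doc_xy,
        centroid_xy=centroid_xy,
        explained_variance=tuple(float(v) for v in pca.explained_variance_),
        explained_variance_ratio=tuple(float(v) for v in pca.explained_variance_ratio_),
    )


@dataclass(frozen=True)
class OverlapReport:
    """Intersection of two top-n word lists, with ranks of the differences."""

    n: int
    common_terms: frozenset[str]
    only_a: tuple[tuple[str, int], ...]  # (term, rank in A)
    only_b: tuple[tuple[str, int], ...]
    common_count: int


def topn_overlap(
    table_a: WordFrequencyTable, table_b: WordFrequencyTable, n: int = 20
) -> OverlapReport:
    """How many of the top-n terms two frequency tables share."""
    top_a = list(table_a.terms[:n])
    top_b = list(table_b.terms[:n])
    common = frozenset(top_a) & frozenset(top_b)
    only_a = tuple((t, i + 1) for i, t in enumerate(top_a) if t not in common)
    only_b = tuple((t, i + 1) for i, t in enumerate(top_b) if t not in common)
    return OverlapReport(
        n=n, common_terms=common, only_a=only_a, only_b=only_b,
        common_count=len(common),
    )


class CitationStats(NamedTuple):
    min: int
    max: int
    mean: float
    median: float


def citation_stats(corpus: Corpus) -> CitationStats:
    """Min / max / mean / median citation counts of a corpus."""
    cites = [d.citations for d in corpus]
    if not cites:
        raise ValueError("empty corpus")
    if any(c is None for c in cites):
        raise ValueError("citations unknown for some documents")
    return CitationStats(
        min=min(cites), max=max(cites), mean=fmean(cites), median=float(median(cites))
    )
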