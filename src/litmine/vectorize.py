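"""Vocabulary construction and TF-IDF weighting of tokenized documents.

Weights follow the smoothed formulation: for term t and document d,

    w(d, t) = tf(t, d) * idf(t),      idf(t) = ln((1 + N) / (1 + df(t))) + 1

with tf the raw count of t in d and df the number of documents containing t;
each nonempty row is then scaled to unit Euclidean norm, so all weights lie
in [0, 1].  This is the weighting scheme used by scikit-learn's
``TfidfTransformer`` defaults, which performs the computation here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from scipy.io import mmwrite
from sklearn.feature_extraction.text import TfidfTransformer

from .preprocess import TokenizedDoc

logger = logging.getLogger(__name__)

__all__ = ["Vocabulary", "TfidfMatrix", "fit_vocabulary", "tfidf"]


@dataclass(frozen=True)
class Vocabulary:
    """Lexicographically ordered term universe with column positions."""

    terms: tuple[str, ...]

    def __post_init__(self) -> None:
        if list(self.terms) != sorted(set(self.terms)):
            raise ValueError("terms must be unique and lexicographically sorted")

    @property
    def index(self) -> dict[str, int]:
        return {t: i for i, t in enumerate(self.terms)}

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term: str) -> bool:
        return term in self.index


@dataclass(frozen=True)
class TfidfMatrix:
    """Documents x terms weight matrix with row labels and vocabulary."""

    weights: sp.csr_matrix
    doc_ids: tuple[str, ...]
    vocabulary: Vocabulary

    @property
    def n_docs(self) -> int:
        return self.weights.shape[0]

    @property
    def n_terms(self) -> int:
        return self.weights.shape[1]

    def toarray(self) -> np.ndarray:
        return self.weights.toarray()

    def export_mtx(self, prefix: str | Path) -> None:
        """Write Matrix Market file plus sidecar row-id and term lists."""
        prefix = Path(prefix)
        mmwrite(str(prefix.with_suffix(".mtx")), self.weights)
        prefix.with_suffix(".docs.txt").write_text("\n".join(self.doc_ids) + "\n")
        prefix.with_suffix(".terms.txt").write_text("\n".join(self.vocabulary.terms) + "\n")


def fit_vocabulary(docs: Sequence[TokenizedDoc], min_df: int = 1) -> Vocabulary:
    """Terms appearing in at least ``min_df`` documents, sorted."""
    if not docs:
        raise ValueError("no documents")
    if min_df < 1:
        raise ValueError("min_df must be >= 1")
    df: dict[str, int] = {}
    for doc in docs:
        for term in set(doc.tokens):
            df[term] = df.get(term, 0) + 1
    terms = sorted(t for t, n in df.items() if n >= min_df)
    if not terms:
        raise ValueError("empty vocabulary: all documents are empty or below min_df")
    return Vocabulary(terms=tuple(terms))


def _count_matrix(docs: Sequence[TokenizedDoc], vocab: Vocabulary) -> sp.csr_matrix:
    index = vocab.index
    data, indices, indptr = [], [], [0]
    n_unknown = 0
    for doc in docs:
        counts: dict[int, int] = {}
        for tok in doc.tokens:
            j = index.get(tok)
            if j is None:
                n_unknown += 1
                continue
            counts[j] = counts.get(j, 0) + 1
        for j in sorted(counts):
            indices.append(j)
            data.append(counts[j])
        indptr.append(len(indices))
    if n_unknown:
        logger.warning("%d token occurrence(s) outside the vocabulary ignored", n_unknown)
    return sp.csr_matrix(
        (np.asarray(data, dtype=np.float64), indices, indptr),
        shape=(len(docs), len(vocab)),
    )


def tfidf(docs: Sequence[TokenizedDoc], vocab: Vocabulary) -> TfidfMatrix:
    """TF-IDF weights for ``docs`` over ``vocab``.

    Tokens absent from the vocabulary are ignored (logged); documents with no
    in-vocabulary tokens become all-zero rows.
    """
    if not docs:
        raise ValueError("no documents")
    counts = _count_matrix(docs, vocab)
    transformer = TfidfTransformer(norm="l2", smooth_idf=True, sublinear_tf=False)
    weights = transformer.fit_transform(counts)
    return TfidfMatrix(
        weights=weights.tocsr(),
        doc_ids=tuple(d.id for d in docs),
        vocabulary=vocab,
    )
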