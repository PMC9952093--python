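"""Word frequencies, trends, PCA projection, overlaps and citation stats."""

import numpy as np
import pytest

from litmine.analyze import (
    citation_stats,
    pca_2d,
    top_words,
    topn_overlap,
    trend_by_year,
    wordcloud_data,
)
from litmine.corpus import Corpus, Document
from litmine.preprocess import TokenizedDoc


def docs_from(token_lists):
    return [TokenizedDoc(id=f"d{i}", tokens=tuple(t)) for i, t in enumerate(token_lists)]


def test_top_words_counts_and_relative_frequency():
    table = top_words(docs_from([["a", "a", "b"]]), n=2)
    assert list(table.table["term"]) == ["a", "b"]
    assert list(table.table["relative_frequency"]) == pytest.approx([2 / 3, 1 / 3])
    assert list(table.table["rank"]) == [1, 2]


def test_top_words_tie_breaks_alphabetically():
    table = top_words(docs_from([["c", "a", "b"]]), n=3)
    assert list(table.table["term"]) == ["a", "b", "c"]


def test_top_words_n_larger_than_vocabulary():
    table = top_words(docs_from([["a", "b"]]), n=50)
    assert len(table) == 2


def test_top_words_empty_pool():
    assert len(top_words(docs_from([[]]), n=5)) == 0


def test_top_words_document_mode():
    table = top_words(docs_from([["a", "a"], ["a", "b"]]), n=2, mode="document")
    row = table.table.set_index("term")
    assert row.loc["a", "count"] == 2  # two documents, despite three tokens
    assert row.loc["a", "relative_frequency"] == pytest.approx(1.0)


def test_relative_frequencies_sum_to_one_unrestricted(rng):
    token_lists = [
        [f"w{j}" for j in rng.integers(0, 30, size=rng.integers(1, 40))] for _ in range(10)
    ]
    table = top_words(docs_from(token_lists), n=10_000)
    assert table.table["relative_frequency"].sum() == pytest.approx(1.0, abs=1e-9)


def test_wordcloud_defaults_and_determinism():
    docs = docs_from([[f"w{j}" for j in range(10)]])
    a, b = wordcloud_data(docs), wordcloud_data(docs)
    assert len(a) == 10
    assert a.table.equals(b.table)
    assert np.allclose(a.table["relative_frequency"], 0.1)


def test_trend_by_year_counts():
    corpus = Corpus(
        [
            Document(id="a", year=2001),
            Document(id="b", year=2001),
            Document(id="c", year=2002),
        ]
    )
    trend = trend_by_year(corpus, [0, 0, 0], 2001, 2002)
    assert trend.counts.loc[2001, 0] == 2
    assert trend.counts.loc[2002, 0] == 1
    assert trend.n_unknown_year == 0


def test_trend_by_year_excludes_unknown_and_out_of_range():
    corpus = Corpus(
        [Document(id="a", year=None), Document(id="b", year=1990), Document(id="c", year=2005)]
    )
    trend = trend_by_year(corpus, [0, 0, 0], 2001, 2010)
    assert trend.n_unknown_year == 1
    assert trend.n_outside_range == 1
    assert trend.counts.to_numpy().sum() == 1


def test_trend_by_year_column_sums_match_cluster_counts():
    corpus = Corpus([Document(id=f"d{i}", year=2001 + i % 3) for i in range(12)])
    labels = [i % 2 for i in range(12)]
    trend = trend_by_year(corpus, labels, 2001, 2003)
    assert trend.counts[0].sum() == labels.count(0)
    assert trend.counts[1].sum() == labels.count(1)


def test_trend_by_year_invalid_range():
    with pytest.raises(ValueError):
        trend_by_year(Corpus([Document(id="a")]), [0], 2010, 2001)


def test_pca_collinear_second_component_vanishes():
    X = np.outer(np.arange(5.0), [1.0, 2.0, 3.0])
    proj = pca_2d(X)
    assert proj.explained_variance[1] == pytest.approx(0.0, abs=1e-12)
    assert proj.explained_variance[0] >= proj.explained_variance[1]


def test_pca_matches_eigendecomposition_oracle(rng):
    X = rng.normal(size=(6, 3))
    proj = pca_2d(X)
    centered = X - X.mean(axis=0)
    cov = centered.T @ centered / (len(X) - 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    expected = centered @ eigvecs[:, order[:2]]
    for j in range(2):
        assert np.allclose(proj.doc_xy[:, j], expected[:, j], atol=1e-9) or np.allclose(
            proj.doc_xy[:, j], -expected[:, j], atol=1e-9
        )
    assert proj.explained_variance == pytest.approx(tuple(eigvals[order[:2]]), abs=1e-9)


def test_pca_grand_centroid_projects_to_origin(rng):
    X = rng.normal(size=(8, 4))
    proj = pca_2d(X, centroids=X.mean(axis=0, keepdims=True))
    assert np.allclose(proj.centroid_xy, 0.0, atol=1e-9)


def test_pca_requires_two_documents():
    with pytest.raises(ValueError):
        pca_2d(np.ones((1, 3)))


def _freq_table(terms):
    return top_words(docs_from([[t] * (len(terms) - i) for i, t in enumerate(terms)]), n=len(terms))


def test_overlap_identical_and_disjoint():
    ta = _freq_table(["a", "b", "c"])
    assert topn_overlap(ta, ta, n=3).common_count == 3
    tb = _freq_table(["x", "y", "z"])
    assert topn_overlap(ta, tb, n=3).common_count == 0


def test_overlap_partial_with_ranks():
    ta = _freq_table(["a", "b", "c", "d", "e"])
    tb = _freq_table(["a", "b", "c", "x", "y"])
    report = topn_overlap(ta, tb, n=5)
    assert report.common_count == 3
    assert report.only_a == (("d", 4), ("e", 5))
    assert report.only_b == (("x", 4), ("y", 5))


def test_overlap_common_count_symmetric():
    ta = _freq_table(["a", "b", "c", "d"])
    tb = _freq_table(["c", "d", "e", "f"])
    assert topn_overlap(ta, tb, n=4).common_count == topn_overlap(tb, ta, n=4).common_count


def test_citation_stats_examples():
    corpus = Corpus([Document(id=f"d{i}", citations=c) for i, c in enumerate([1, 2, 3, 4])])
    stats = citation_stats(corpus)
    assert (stats.mean, stats.median) == (2.5, 2.5)

    corpus = Corpus([Document(id=f"d{i}", citations=c) for i, c in enumerate([0, 9, 60, 620])])
    stats = citation_stats(corpus)
    assert (stats.min, stats.max) == (0, 620)
    assert stats.mean == pytest.approx(172.25)
    assert stats.median == pytest.approx(34.5)


def test_citation_stats_single_and_empty():
    single = citation_stats(Corpus([Document(id="a", citations=7)]))
    assert single.min == single.max == single.mean == single.median == 7
    with pytest.raises(ValueError):
        citation_stats(Corpus([]))
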