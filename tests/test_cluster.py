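"""K-means, silhouettes, k selection and subclustering."""

import itertools
import math

import numpy as np
import pytest

from litmine.cluster import (
    ClusteringResult,
    KSelectionReport,
    kmeans_fit,
    select_k,
    silhouette_values,
    subcluster,
    sweep_k,
)
from litmine.corpus import Corpus, Document
from litmine.synthetic import GeneratorConfig, generate_labeled_corpus


def brute_force_min_wcss(X, k):
    """Exhaustive minimum within-cluster sum of squares over all k-partitions."""
    n = len(X)
    best = math.inf
    for assignment in itertools.product(range(k), repeat=n):
        if len(set(assignment)) < k:
            continue
        wcss = 0.0
        for c in range(k):
            pts = X[[i for i, a in enumerate(assignment) if a == c]]
            wcss += ((pts - pts.mean(axis=0)) ** 2).sum()
        best = min(best, wcss)
    return best


def test_two_separated_pairs_forced_optimum():
    X = np.array([[0.0, 0.0], [0.0, 1.0], [10.0, 0.0], [10.0, 1.0]])
    res = kmeans_fit(X, 2, seed=0, n_init=10)
    assert res.labels[0] == res.labels[1] != res.labels[2] == res.labels[3]
    # each pair's centroid sits mid-gap: 4 points at squared distance 0.25
    assert res.wcss == pytest.approx(1.0, abs=1e-12)


def test_kmeans_matches_exhaustive_partitions(rng):
    hits = 0
    trials = 20
    for _ in range(trials):
        n = int(rng.integers(4, 9))
        k = int(rng.integers(2, 4))
        X = rng.normal(size=(n, 2))
        res = kmeans_fit(X, k, seed=0, n_init=10)
        best = brute_force_min_wcss(X, k)
        assert res.wcss >= best - 1e-9  # can never beat the optimum
        hits += res.wcss <= best + 1e-7
    assert hits >= 0.9 * trials


def test_kmeans_deterministic(rng):
    X = rng.normal(size=(30, 4))
    a = kmeans_fit(X, 3, seed=7, n_init=10)
    b = kmeans_fit(X, 3, seed=7, n_init=10)
    assert (a.labels == b.labels).all()
    assert a.wcss == b.wcss


def test_kmeans_is_fixed_point(rng):
    X = rng.normal(size=(40, 3))
    res = kmeans_fit(X, 4, seed=0, n_init=10)
    dists = ((X[:, None, :] - res.centroids[None, :, :]) ** 2).sum(axis=2)
    assert (dists.argmin(axis=1) == res.labels).all()


@pytest.mark.parametrize("k", [1, 0, 100])
def test_kmeans_k_domain(k, rng):
    with pytest.raises(ValueError):
        kmeans_fit(rng.normal(size=(10, 2)), k)


def test_silhouette_hand_example():
    """Four points in two pairs: a(i)=1 for all, b(i)=(10+sqrt(101))/2."""
    X = np.array([[0.0, 0.0], [0.0, 1.0], [10.0, 0.0], [10.0, 1.0]])
    labels = [0, 0, 1, 1]
    b = (10.0 + math.sqrt(101.0)) / 2.0
    expected = (b - 1.0) / b
    s = silhouette_values(X, labels)
    np.testing.assert_allclose(s, expected, atol=1e-12)


def test_silhouette_tight_far_clusters(rng):
    X = np.vstack(
        [rng.normal(scale=0.01, size=(10, 2)), rng.normal(scale=0.01, size=(10, 2)) + 50]
    )
    s = silhouette_values(X, [0] * 10 + [1] * 10)
    assert (s >= 0.9).all()


def test_silhouette_midway_point_is_zero():
    X = np.array([[-1.0, 0.0], [-1.0, 2.0], [1.0, 0.0], [1.0, 2.0], [0.0, 1.0]])
    s = silhouette_values(X, [0, 0, 1, 1, 0])
    assert s[4] == pytest.approx(0.0, abs=1e-12)


def test_silhouette_singleton_cluster_is_zero():
    X = np.array([[0.0, 0.0], [0.0, 0.1], [5.0, 5.0]])
    s = silhouette_values(X, [0, 0, 1])
    assert s[2] == 0.0


def test_silhouette_single_cluster_rejected():
    with pytest.raises(ValueError):
        silhouette_values(np.zeros((3, 2)), [0, 0, 0])


def test_silhouette_range_and_beats_permutation(rng):
    corpus, labels = generate_labeled_corpus(
        GeneratorConfig(n_docs=60, k_topics=3, tokens_per_doc=30, seed=0)
    )
    from litmine.preprocess import preprocess_corpus
    from litmine.vectorize import fit_vocabulary, tfidf

    toks = preprocess_corpus(corpus)
    X = tfidf(toks, fit_vocabulary(toks))
    s_true = silhouette_values(X, labels)
    assert ((s_true >= -1) & (s_true <= 1)).all()
    permuted = rng.permutation(labels)
    assert s_true.mean() > silhouette_values(X, permuted).mean()


def test_sweep_reports_all_ks(rng):
    X = np.vstack([rng.normal(size=(8, 2)) + c * 20 for c in range(3)])
    report = sweep_k(X, k_min=2, k_max=3, seed=0, n_init=10)
    assert report.tested_ks == (2, 3)
    assert set(report.mean_silhouette) == {2, 3}
    assert report.chosen_k == 3  # three well-separated blobs


def test_sweep_single_k(rng):
    X = rng.normal(size=(10, 2))
    report = sweep_k(X, k_min=2, k_max=2, seed=0, n_init=5)
    assert report.tested_ks == (2,)
    assert report.chosen_k == 2


def test_sweep_k_max_exceeds_documents(rng):
    with pytest.raises(ValueError, match="exceeds"):
        sweep_k(rng.normal(size=(5, 2)), k_min=2, k_max=6)


def _report(per_k):
    """Build a KSelectionReport by hand from {k: (mean, maxes, sizes)}."""
    return KSelectionReport(
        tested_ks=tuple(per_k),
        mean_silhouette={k: v[0] for k, v in per_k.items()},
        cluster_max_silhouette={k: v[1] for k, v in per_k.items()},
        cluster_sizes={k: v[2] for k, v in per_k.items()},
        results={},
    )


def test_select_k_single_feasible():
    report = _report(
        {
            2: (0.5, (0.4, 0.9), (5, 5)),       # one cluster never reaches the mean
            3: (0.3, (0.5, 0.4, 0.6), (4, 3, 3)),
        }
    )
    assert select_k(report) == 3
    assert report.feasible_ks == (3,)
    assert not report.fallback


def test_select_k_tie_breaks_to_smaller():
    report = _report(
        {
            2: (0.2, (0.5, 0.5), (5, 5)),
            4: (0.2, (0.5, 0.5, 0.5, 0.5), (5, 5, 5, 5)),  # same CV = 0
        }
    )
    assert select_k(report) == 2


def test_select_k_prefers_balanced_sizes():
    report = _report(
        {
            2: (0.2, (0.5, 0.5), (9, 1)),
            3: (0.2, (0.5, 0.5, 0.5), (4, 3, 3)),
        }
    )
    assert select_k(report) == 3


def test_select_k_fallback_flags():
    report = _report({2: (0.5, (0.2, 0.3), (5, 5)), 3: (0.6, (0.1, 0.2, 0.3), (4, 3, 3))})
    assert select_k(report) == 3  # highest mean silhouette
    assert report.fallback


def test_select_k_empty_report():
    with pytest.raises(ValueError):
        select_k(_report({}))


def _mini_corpus_and_result():
    docs = [
        Document(id=f"d{i}", abstract=text)
        for i, text in enumerate(
            ["kbb kbb kcc", "kbb kcc kcc", "pff pff pgg", "pff pgg pgg", "zrr zrr zrr"]
        )
    ]
    corpus = Corpus(docs)
    result = ClusteringResult(
        k=3,
        labels=np.array([0, 0, 1, 1, 2]),
        centroids=np.zeros((3, 2)),
        wcss=0.0,
        silhouettes=np.zeros(5),
        seed=0,
        n_init=1,
    )
    return corpus, result


def test_subcluster_unused_label():
    corpus, result = _mini_corpus_and_result()
    with pytest.raises(ValueError, match="unused"):
        subcluster(corpus, result, 7)


def test_subcluster_singleton_cluster():
    corpus, result = _mini_corpus_and_result()
    with pytest.raises(ValueError, match="cannot subcluster"):
        subcluster(corpus, result, 2)


def test_subcluster_deterministic():
    corpus, result = _mini_corpus_and_result()
    sub1, _, res1 = subcluster(corpus, result, 0, k_max=2, seed=0)
    sub2, _, res2 = subcluster(corpus, result, 0, k_max=2, seed=0)
    assert [d.id for d in sub1] == [d.id for d in sub2] == ["d0", "d1"]
    assert (res1.labels == res2.labels).all()


def test_wcss_nonincreasing_in_k(rng):
    X = rng.normal(size=(40, 3))
    report = sweep_k(X, 2, 6, seed=0, n_init=10)
    wcss = [report.results[k].wcss for k in report.tested_ks]
    assert all(a >= b - 1e-9 for a, b in zip(wcss, wcss[1:]))
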