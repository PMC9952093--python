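"""K-means clustering, silhouette evaluation and k selection.

Distances are Euclidean on the L2-normalized TF-IDF rows, which on the unit
sphere orders pairs identically to cosine dissimilarity; the same metric is
used for clustering and for silhouettes.

The number of clusters is chosen by sweeping k and inspecting per-cluster
silhouette profiles the way an analyst reads a silhouette plot: a k is
*feasible* when every cluster's silhouette peak reaches the dashed
average-silhouette line (cluster max >= overall mean), and among feasible
ks the one whose cluster sizes are most balanced (smallest coefficient of
variation) wins, smaller k breaking ties.  The choice is advisory — the
pipeline accepts an explicit k override.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_samples

from .corpus import Corpus

logger = logging.getLogger(__name__)

__all__ = [
    "ClusteringResult",
    "KSelectionReport",
    "kmeans_fit",
    "silhouette_values",
    "sweep_k",
    "select_k",
    "subcluster",
]


def _as_array(X) -> np.ndarray | sp.spmatrix:
    """Accept a TfidfMatrix, a sparse matrix or a dense array."""
    weights = getattr(X, "weights", X)
    if sp.issparse(weights):
        return weights.tocsr()
    return np.asarray(weights, dtype=np.float64)


@dataclass(frozen=True)
class ClusteringResult:
    """One k-means fit: labels, centroids, inertia and silhouettes."""

    k: int
    labels: np.ndarray
    centroids: np.ndarray
    wcss: float
    silhouettes: np.ndarray
    seed: int
    n_init: int

    @property
    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k)


@dataclass
class KSelectionReport:
    """Silhouette summaries over a k sweep and the chosen k."""

    tested_ks: tuple[int, ...]
    mean_silhouette: dict[int, float]
    cluster_max_silhouette: dict[int, tuple[float, ...]]
    cluster_sizes: dict[int, tuple[int, ...]]
    results: dict[int, ClusteringResult]
    feasible_ks: tuple[int, ...] = ()
    chosen_k: int | None = None
    fallback: bool = False

    def summary(self) -> dict:
        return {
            "tested_ks": list(self.tested_ks),
            "mean_silhouette": {str(k): self.mean_silhouette[k] for k in self.tested_ks},
            "cluster_sizes": {str(k): list(self.cluster_sizes[k]) for k in self.tested_ks},
            "feasible_ks": list(self.feasible_ks),
            "chosen_k": self.chosen_k,
            "fallback": self.fallback,
        }


def kmeans_fit(X, k: int, seed: int = 0, n_init: int = 10) -> ClusteringResult:
    """Lloyd iterations from k-means++ starts, best of ``n_init`` by WCSS."""
    A = _as_array(X)
    n = A.shape[0]
    if not 2 <= k <= n:
        raise ValueError(f"k must be in [2, {n}], got {k}")
    km = KMeans(
        n_clusters=k, init="k-means++", n_init=n_init,
        random_state=seed, algorithm="lloyd",
    ).fit(A)
    labels = km.labels_.astype(np.int64)
    return ClusteringResult(
        k=k,
        labels=labels,
        centroids=km.cluster_centers_,
        wcss=float(km.inertia_),
        silhouettes=silhouette_values(A, labels),
        seed=seed,
        n_init=n_init,
    )


def silhouette_values(X, labels: Sequence[int]) -> np.ndarray:
    """Per-point silhouette s(i) = (b - a) / max(a, b), Euclidean metric.

    a(i) is the mean distance to co-members, b(i) the smallest mean distance
    to another cluster; singletons get s(i) = 0.
    """
    A = _as_array(X)
    labels = np.asarray(labels)
    n_labels = np.unique(labels).size
    if n_labels < 2:
        raise ValueError("silhouettes need at least 2 clusters")
    if n_labels == len(labels):
        # every cluster is a singleton: s(i) = 0 by the singleton rule
        return np.zeros(len(labels))
    return silhouette_samples(A, labels, metric="euclidean")


def sweep_k(
    X, k_min: int = 2, k_max: int = 16, seed: int = 0, n_init: int = 10
) -> KSelectionReport:
    """Fit k-means for every k in [k_min, k_max] and summarize silhouettes."""
    A = _as_array(X)
    n = A.shape[0]
    if k_min < 2 or k_max < k_min:
        raise ValueError(f"need 2 <= k_min <= k_max, got [{k_min}, {k_max}]")
    if k_max > n:
        raise ValueError(f"k_max={k_max} exceeds number of documents ({n})")
    results: dict[int, ClusteringResult] = {}
    mean_sil: dict[int, float] = {}
    cluster_max: dict[int, tuple[float, ...]] = {}
    sizes: dict[int, tuple[int, ...]] = {}
    for k in range(k_min, k_max + 1):
        res = kmeans_fit(A, k, seed=seed, n_init=n_init)
        results[k] = res
        mean_sil[k] = float(res.silhouettes.mean())
        cluster_max[k] = tuple(
            float(res.silhouettes[res.labels == c].max()) for c in range(k)
        )
        sizes[k] = tuple(int(s) for s in res.sizes)
    report = KSelectionReport(
        tested_ks=tuple(range(k_min, k_max + 1)),
        mean_silhouette=mean_sil,
        cluster_max_silhouette=cluster_max,
        cluster_sizes=sizes,
        results=results,
    )
    select_k(report)
    return report


def select_k(report: KSelectionReport) -> int:
    """Choose k from a sweep report; fills the report's feasibility fields.

    Feasible ks are those where every cluster's maximum silhouette reaches
    that k's mean silhouette; among them the k minimizing the coefficient of
    variation of cluster sizes wins, ties going to the smaller k.  If no k is
    feasible the k with the highest mean silhouette is returned with the
    report flagged ``fallback``.
    """
    if not report.tested_ks:
        raise ValueError("empty k-selection report")
    feasible = [
        k
        for k in report.tested_ks
        if all(m >= report.mean_silhouette[k] for m in report.cluster_max_silhouette[k])
    ]
    report.feasible_ks = tuple(feasible)
    if feasible:
        def size_cv(k: int) -> float:
            s = np.asarray(report.cluster_sizes[k], dtype=float)
            return float(s.std() / s.mean())

        chosen = min(feasible, key=lambda k: (size_cv(k), k))
        report.fallback = False
    else:
        chosen = max(report.tested_ks, key=lambda k: report.mean_silhouette[k])
        report.fallback = True
        logger.warning("no feasible k; falling back to best mean silhouette (k=%d)", chosen)
    report.chosen_k = chosen
    return chosen


def subcluster(
    corpus: Corpus,
    result: ClusteringResult,
    target_label: int,
    *,
    policy=None,
    min_df: int = 1,
    k_min: int = 2,
    k_max: int = 16,
    seed: int = 0,
    n_init: int = 10,
    k: int | None = None,
) -> tuple[Corpus, KSelectionReport, ClusteringResult]:
    """Re-run the whole pipeline on the documents of one cluster.

    The subset corpus is re-preprocessed and re-vectorized (its own
    vocabulary and document frequencies), then swept over k.  ``k_max`` is
    clipped to the subset size; pass ``k`` to override the selection.
    """
    from .preprocess import preprocess_corpus
    from .vectorize import fit_vocabulary, tfidf

    labels = np.asarray(result.labels)
    if len(labels) != len(corpus):
        raise ValueError("labels are not aligned with the corpus")
    if target_label not in labels:
        raise ValueError(f"cluster label {target_label} is unused")
    members = [d for d, lab in zip(corpus, labels) if lab == target_label]
    sub = Corpus(members, provenance=f"{corpus.provenance} [cluster {target_label}]")
    if len(sub) < 2:
        raise ValueError(f"cluster {target_label} has {len(sub)} document(s); cannot subcluster")
    toks = preprocess_corpus(sub, policy)
    X = tfidf(toks, fit_vocabulary(toks, min_df=min_df))
    report = sweep_k(X, k_min=k_min, k_max=min(k_max, len(sub)), seed=seed, n_init=n_init)
    final_k = k if k is not None else report.chosen_k
    final = report.results.get(final_k) or kmeans_fit(X, final_k, seed=seed, n_init=n_init)
    return sub, report, final
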