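"""Embedding-quality metrics.

Label-based scores built on a k-nearest-neighbor classifier (majority vote of
the k closest samples, Euclidean distance in the 3-D spherical coordinates):

* local score (L) — 3NN subpopulation accuracy on the training embedding,
  each sample excluded from its own neighbor set;
* global score (G) — subpopulation centroids (mean 3-D coordinates) classified
  into superpopulations by 3NN among the centroids;
* generalization score (GE) — 3NN accuracy of held-out samples against the
  training samples' labels.

Label-agnostic scores compare neighborhoods in genotype space (Manhattan
distance) against the embedding (Euclidean):

* neighbor overlap — mean fraction of shared members of the two k-NN sets;
* rank-RMSE — for each sample's n-th genotype-space neighbor, the root mean
  square difference between n and that neighbor's embedding-space rank.

Ties (equal distances, split votes) are broken deterministically: neighbor
ties by stable sort on sample index, vote ties by smaller mean neighbor
distance and then lexicographic label order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.spatial.distance import cdist


@dataclass
class KNNQuery:
    """One KNN classification problem."""

    reference: np.ndarray
    reference_labels: np.ndarray
    query: np.ndarray
    k: int = 3
    exclude_self: bool = False
    query_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.reference = np.asarray(self.reference, dtype=float)
        self.query = np.asarray(self.query, dtype=float)
        self.reference_labels = np.asarray(self.reference_labels)
        if self.k < 1:
            raise ValueError("k must be >= 1")
        available = len(self.reference) - (1 if self.exclude_self else 0)
        if self.k > available:
            raise ValueError(f"k={self.k} exceeds {available} available "
                             "reference samples")


@dataclass
class MetricReport:
    """Named embedding-quality scores plus the settings that produced them."""

    scores: dict[str, float] = field(default_factory=dict)
    curves: dict[str, dict[int, float]] = field(default_factory=dict)
    settings: dict[str, Any] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {"scores": self.scores,
                "curves": {name: {str(k): v for k, v in curve.items()}
                           for name, curve in self.curves.items()},
                "settings": self.settings}


def _neighbor_order(dist: np.ndarray, exclude_self: bool) -> np.ndarray:
    """Stable ordering of reference indices by distance for each query row.

    With ``exclude_self`` the diagonal (query i vs reference i) is pushed to
    the end; callers then ignore it by taking fewer columns.
    """
    dist = dist.copy()
    if exclude_self:
        np.fill_diagonal(dist, np.inf)
    return np.argsort(dist, axis=1, kind="stable")


def _majority_vote(neighbor_labels: np.ndarray, neighbor_dists: np.ndarray,
                   classes: np.ndarray) -> Any:
    """Majority vote over one neighbor set: argmax of summed one-hot labels,
    ties broken by smaller mean distance then lexicographic label."""
    counts = np.array([(neighbor_labels == c).sum() for c in classes])
    best = counts.max()
    tied = [c for c, n in zip(classes, counts) if n == best]
    if len(tied) == 1:
        return tied[0]
    means = {c: neighbor_dists[neighbor_labels == c].mean() for c in tied}
    lowest = min(means.values())
    closest = sorted(c for c, m in means.items()
                     if np.isclose(m, lowest, rtol=0, atol=1e-12))
    return closest[0]


def knn_predict(query: KNNQuery):
    """Predicted labels for each query point, plus accuracy when the true
    query labels are known (None otherwise)."""
    dist = cdist(query.query, query.reference)
    order = _neighbor_order(dist, query.exclude_self)
    classes = np.unique(query.reference_labels)
    neigh = order[:, :query.k]
    preds = np.array([
        _majority_vote(query.reference_labels[neigh[i]],
                       dist[i, neigh[i]], classes)
        for i in range(len(query.query))])
    accuracy = None
    if query.query_labels is not None:
        accuracy = float((preds == np.asarray(query.query_labels)).mean())
    return preds, accuracy


def local_score(embedding: np.ndarray, sublabels: np.ndarray,
                k: int = 3) -> float:
    """(L): kNN subpopulation accuracy on the embedding itself, leaving each
    sample out of its own neighbor set."""
    _, acc = knn_predict(KNNQuery(
        reference=embedding, reference_labels=sublabels, query=embedding,
        k=k, exclude_self=True, query_labels=sublabels))
    return acc


def subpopulation_centroids(embedding: np.ndarray, sublabels: np.ndarray,
                            superlabels: np.ndarray):
    """Mean 3-D coordinates per subpopulation and the superpopulation each
    subpopulation belongs to."""
    sublabels = np.asarray(sublabels)
    superlabels = np.asarray(superlabels)
    subs = np.unique(sublabels)
    centroids = np.stack([embedding[sublabels == s].mean(axis=0)
                          for s in subs])
    supers = []
    for s in subs:
        owners = np.unique(superlabels[sublabels == s])
        if len(owners) != 1:
            raise ValueError(f"subpopulation {s} under several "
                             f"superpopulations: {owners.tolist()}")
        supers.append(owners[0])
    return subs, centroids, np.array(supers)


def global_score(embedding: np.ndarray, sublabels: np.ndarray,
                 superlabels: np.ndarray, k: int = 3) -> float:
    """(G): kNN superpopulation accuracy among subpopulation centroids."""
    _, centroids, supers = subpopulation_centroids(embedding, sublabels,
                                                   superlabels)
    if len(centroids) < k + 1:
        raise ValueError(f"{len(centroids)} subpopulation centroids cannot "
                         f"support {k}NN with self-exclusion")
    if len(np.unique(supers)) < 2:
        raise ValueError("global score needs at least 2 superpopulations")
    _, acc = knn_predict(KNNQuery(
        reference=centroids, reference_labels=supers, query=centroids,
        k=k, exclude_self=True, query_labels=supers))
    return acc


def generalization_score(train_embedding: np.ndarray, train_labels: np.ndarray,
                         val_embedding: np.ndarray, val_labels: np.ndarray,
                         k: int = 3) -> float:
    """(GE): kNN accuracy of held-out samples against training labels."""
    _, acc = knn_predict(KNNQuery(
        reference=train_embedding, reference_labels=train_labels,
        query=val_embedding, k=k, query_labels=val_labels))
    return acc


def accuracy_vs_k(embedding: np.ndarray, labels: np.ndarray,
                  k_values) -> dict[int, float]:
    """Self-excluded KNN accuracy over a range of neighbor counts k."""
    embedding = np.asarray(embedding, dtype=float)
    labels = np.asarray(labels)
    dist = cdist(embedding, embedding)
    order = _neighbor_order(dist, exclude_self=True)
    classes = np.unique(labels)
    curve: dict[int, float] = {}
    for k in k_values:
        if k >= len(embedding):
            raise ValueError(f"k={k} must be < {len(embedding)} samples")
        preds = np.array([
            _majority_vote(labels[order[i, :k]], dist[i, order[i, :k]],
                           classes)
            for i in range(len(embedding))])
        curve[int(k)] = float((preds == labels).mean())
    return curve


def _genotype_distances(genotypes: np.ndarray) -> np.ndarray:
    genotypes = np.asarray(genotypes)
    if (genotypes == -1).any():
        raise ValueError("genotype matrix contains missing calls; "
                         "impute before computing genotype-space distances")
    return cdist(genotypes.astype(float), genotypes.astype(float),
                 metric="cityblock")


def neighbor_overlap(genotypes: np.ndarray, embedding: np.ndarray,
                     k_values) -> dict[int, float]:
    """Mean overlap ratio of k-NN sets in genotype (Manhattan) and embedding
    (Euclidean) space, per k."""
    g_order = _neighbor_order(_genotype_distances(genotypes),
                              exclude_self=True)
    e_order = _neighbor_order(cdist(embedding, embedding), exclude_self=True)
    n = len(g_order)
    curve: dict[int, float] = {}
    for k in k_values:
        if k >= n:
            raise ValueError(f"k={k} must be < {n} samples")
        overlaps = [
            len(np.intersect1d(g_order[i, :k], e_order[i, :k])) / k
            for i in range(n)]
        curve[int(k)] = float(np.mean(overlaps))
    return curve


def rank_rmse(genotypes: np.ndarray, embedding: np.ndarray,
              n_values) -> dict[int, float]:
    """Root mean square difference between genotype-space neighbor rank n and
    that same neighbor's rank in the embedding, per n."""
    g_order = _neighbor_order(_genotype_distances(genotypes),
                              exclude_self=True)
    e_order = _neighbor_order(cdist(embedding, embedding), exclude_self=True)
    n_samples = len(g_order)
    # embedding rank of reference j from anchor i (1-based, self excluded)
    e_rank = np.empty((n_samples, n_samples), dtype=np.int64)
    rows = np.arange(n_samples)[:, None]
    e_rank[rows, e_order] = np.arange(n_samples)[None, :] + 1
    curve: dict[int, float] = {}
    for n in n_values:
        if n >= n_samples:
            raise ValueError(f"n={n} must be < {n_samples} samples")
        j = g_order[:, n - 1]
        re = e_rank[np.arange(n_samples), j]
        curve[int(n)] = float(np.sqrt(np.mean((n - re) ** 2.0)))
    return curve
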