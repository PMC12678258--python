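"""Tangent-space clustering of indicator embeddings and cluster-count selection.

Ball points are projected to the tangent space at the origin (see
:func:`resilmine.hyperbolic.log_map_origin`), where ordinary k-means with
Euclidean distances applies.  Cluster counts from a candidate range are
scored by three internal metrics — silhouette coefficient (higher better),
Davies-Bouldin index (lower better), and a topic-coherence score (mean
add-one-smoothed NPMI of within-cluster phrase pairs; higher better) — and
the winning k takes the majority of the three votes, smaller k on ties.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hyperbolic import EmbeddingSet, log_map_origin

__all__ = [
    "ClusteringResult",
    "tangent_project",
    "kmeans",
    "silhouette",
    "davies_bouldin",
    "topic_coherence",
    "select_k",
]


@dataclass
class ClusteringResult:
    k: int
    labels: np.ndarray
    centroids: np.ndarray
    inertia: float
    seed: int


def tangent_project(emb: EmbeddingSet) -> np.ndarray:
    """Pointwise origin log-map; Euclidean embeddings pass through unchanged."""
    if emb.space == "euclidean":
        return emb.points.copy()
    return log_map_origin(emb.points)


def _pairwise(points: np.ndarray) -> np.ndarray:
    diff = points[:, None, :] - points[None, :, :]
    return np.linalg.norm(diff, axis=-1)


def _farthest_point_init(points: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = len(points)
    first = int(rng.integers(n))
    chosen = [first]
    d = np.linalg.norm(points - points[first], axis=1)
    for _ in range(k - 1):
        nxt = int(np.argmax(d))
        chosen.append(nxt)
        d = np.minimum(d, np.linalg.norm(points - points[nxt], axis=1))
    return points[chosen].copy()


def kmeans(
    points: np.ndarray, k: int, seed: int = 0, restarts: int = 10, max_iter: int = 100
) -> ClusteringResult:
    """Lloyd's algorithm, best of ``restarts`` seeded farthest-point inits.

    An emptied cluster is re-seeded at the point farthest from its assigned
    centroid.  Deterministic for a fixed seed.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    if k > n:
        raise ValueError(f"k={k} exceeds number of points {n}")
    best: ClusteringResult | None = None
    ss = np.random.SeedSequence(seed)
    for child in ss.spawn(restarts):
        rng = np.random.default_rng(child)
        centroids = _farthest_point_init(points, k, rng)
        labels = np.full(n, -1, dtype=int)
        for it in range(max_iter):
            d = np.linalg.norm(points[:, None, :] - centroids[None, :, :], axis=-1)
            new_labels = np.argmin(d, axis=1)
            for c in range(k):
                if not np.any(new_labels == c):  # re-seed empty cluster
                    far = int(np.argmax(d[np.arange(n), new_labels]))
                    centroids[c] = points[far]
                    new_labels[far] = c
            if np.array_equal(new_labels, labels):
                break
            labels = new_labels
            for c in range(k):
                centroids[c] = points[labels == c].mean(axis=0)
        inertia = float(np.sum((points - centroids[labels]) ** 2))
        if best is None or inertia < best.inertia:
            best = ClusteringResult(
                k=k, labels=labels.copy(), centroids=centroids.copy(), inertia=inertia, seed=seed
            )
    assert best is not None
    return best


def silhouette(points: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette (b - a) / max(a, b); singletons contribute 0, and a
    point with a = b = 0 (coincident degenerate clusters) contributes 0."""
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    ks = np.unique(labels)
    if len(ks) < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    D = _pairwise(points)
    n = len(points)
    s = np.zeros(n)
    for i in range(n):
        own = labels == labels[i]
        n_own = own.sum()
        if n_own == 1:
            s[i] = 0.0
            continue
        a = D[i, own].sum() / (n_own - 1)
        b = min(D[i, labels == c].mean() for c in ks if c != labels[i])
        m = max(a, b)
        s[i] = 0.0 if m == 0 else (b - a) / m
    return float(s.mean())


def davies_bouldin(points: np.ndarray, labels: np.ndarray) -> float:
    """(1/k) sum_i max_{j!=i} (s_i + s_j) / d(c_i, c_j) with centroid scatters s."""
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    ks = np.unique(labels)
    if len(ks) < 2:
        raise ValueError("Davies-Bouldin requires at least 2 clusters")
    cents = np.stack([points[labels == c].mean(axis=0) for c in ks])
    scat = np.array(
        [np.linalg.norm(points[labels == c] - cents[i], axis=1).mean() for i, c in enumerate(ks)]
    )
    total = 0.0
    for i in range(len(ks)):
        ratios = []
        for j in range(len(ks)):
            if i == j:
                continue
            d = np.linalg.norm(cents[i] - cents[j])
            if d == 0:
                raise ValueError(
                    f"coincident centroids for clusters {ks[i]} and {ks[j]}"
                )
            ratios.append((scat[i] + scat[j]) / d)
        total += max(ratios)
    return float(total / len(ks))


def topic_coherence(
    labels: np.ndarray,
    phrase_doc_sets: list[set[int]],
    n_docs: int,
) -> float:
    """Mean add-one-smoothed NPMI of within-cluster phrase pairs.

    ``phrase_doc_sets[i]`` is the set of document indices containing phrase i
    (aligned with ``labels``).  With smoothing, p(i) = (df_i + 1)/(N + 1) and
    p(i,j) = (df_ij + 1)/(N + 1); NPMI = ln(p_ij / (p_i p_j)) / (-ln p_ij).
    Cluster scores are pair means; the result averages over clusters with at
    least one scoreable pair.  Phrases with zero document frequency are
    excluded with a warning.
    """
    labels = np.asarray(labels)
    keep = np.array([len(s) > 0 for s in phrase_doc_sets])
    if not keep.all():
        warnings.warn("excluding phrases with zero document frequency from coherence")
    cluster_scores = []
    for c in np.unique(labels):
        idx = [i for i in np.flatnonzero(labels == c) if keep[i]]
        pair_scores = []
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                i, j = idx[a], idx[b]
                pair_scores.append(_npmi(phrase_doc_sets[i], phrase_doc_sets[j], n_docs))
        if pair_scores:
            cluster_scores.append(float(np.mean(pair_scores)))
    if not cluster_scores:
        return float("nan")
    return float(np.mean(cluster_scores))


def _npmi(docs_i: set[int], docs_j: set[int], n_docs: int) -> float:
    p_i = (len(docs_i) + 1) / (n_docs + 1)
    p_j = (len(docs_j) + 1) / (n_docs + 1)
    p_ij = (len(docs_i & docs_j) + 1) / (n_docs + 1)
    pmi = math.log(p_ij / (p_i * p_j))
    denom = -math.log(p_ij)
    if denom == 0:  # both phrases in every document
        return 1.0
    return pmi / denom


def select_k(
    points: np.ndarray,
    k_range: range = range(3, 8),
    phrase_doc_sets: list[set[int]] | None = None,
    n_docs: int | None = None,
    seed: int = 0,
    restarts: int = 10,
) -> tuple[int, pd.DataFrame]:
    """Score each k by the three metrics; the majority vote picks the winner.

    Per-metric winners are max silhouette, min Davies-Bouldin, and max
    coherence, each resolved toward the smaller k on ties; the k with the
    most metric wins is returned (again smaller k on ties).  Coherence is
    skipped (NaN column) when no phrase/document co-occurrence data is given.
    """
    rows = []
    labelings: dict[int, np.ndarray] = {}
    for k in k_range:
        res = kmeans(points, k, seed=seed, restarts=restarts)
        labelings[k] = res.labels
        row = {
            "k": k,
            "silhouette": silhouette(points, res.labels),
            "davies_bouldin": davies_bouldin(points, res.labels),
            "coherence": float("nan"),
        }
        if phrase_doc_sets is not None and n_docs is not None:
            row["coherence"] = topic_coherence(res.labels, phrase_doc_sets, n_docs)
        rows.append(row)
    table = pd.DataFrame(rows, columns=["k", "silhouette", "davies_bouldin", "coherence"])

    votes: dict[int, int] = {k: 0 for k in k_range}

    def winner(col: str, maximize: bool) -> int | None:
        vals = table[col].to_numpy()
        if np.all(np.isnan(vals)):
            return None
        best = np.nanmax(vals) if maximize else np.nanmin(vals)
        ks = table["k"].to_numpy()[np.isclose(vals, best)]
        return int(ks.min())

    for col, maximize in (("silhouette", True), ("davies_bouldin", False), ("coherence", True)):
        w = winner(col, maximize)
        if w is not None:
            votes[w] += 1
    top = max(votes.values())
    best_k = min(k for k, v in votes.items() if v == top)
    return best_k, table
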