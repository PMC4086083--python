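"""K-means grouping of a hit list.

A retrieved hit list is partitioned into a predefined number of clusters
with Lloyd's algorithm (k-means++ initialization, explicit seed) in any of
the four fingerprint spaces — searching and clustering are separate steps
and may use different spaces. Euclidean distance on the raw fingerprint
vectors is used inside K-means so that cluster means are well-defined.

Clusters are numbered 1..k by decreasing member count, and each cluster's
representative is the member nearest its mean ("centroid" in the browser),
shown first when the clustering is saved.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import kmeans_plusplus

from .fingerprints import Space, fingerprint_matrix
from .index import SearchResult

#: Lloyd iteration cap; convergence is declared when assignments stop changing.
MAX_ITER = 100


@dataclass
class ClusterResult:
    """Assignments, size-ordered cluster labels and centroid representatives.

    Labels are 1-based and already ordered: cluster 1 is the largest. The
    ``inertia_history`` diagnostic records the within-cluster sum of squared
    distances after every Lloyd iteration (non-increasing).
    """

    k: int
    assignments: dict[str, int]
    cluster_order: list[int]
    representatives: dict[int, str]
    inertia_history: list[float]
    n_iter: int


def lloyd_kmeans(
    X: np.ndarray, k: int, seed: int
) -> tuple[np.ndarray, np.ndarray, list[float], int]:
    """Seeded k-means++ / Lloyd iteration on the rows of ``X``.

    Returns (labels, centers, inertia history, iterations). An empty
    cluster arising during iteration is re-seeded with the point currently
    farthest from its assigned center.
    """
    X = np.asarray(X, dtype=np.float64)
    n = X.shape[0]
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of points ({n})")
    centers, _ = kmeans_plusplus(X, n_clusters=k, random_state=seed)
    labels = np.full(n, -1, dtype=np.int64)
    inertia_history: list[float] = []
    n_iter = 0
    for n_iter in range(1, MAX_ITER + 1):
        sq_dists = cdist(X, centers, metric="sqeuclidean")
        new_labels = sq_dists.argmin(axis=1)
        point_sq = sq_dists[np.arange(n), new_labels]
        for empty in np.setdiff1d(np.arange(k), new_labels):
            farthest = int(point_sq.argmax())
            new_labels[farthest] = empty
            centers[empty] = X[farthest]
            point_sq[farthest] = 0.0
        inertia_history.append(float(point_sq.sum()))
        if (new_labels == labels).all():
            break
        labels = new_labels
        for j in range(k):
            centers[j] = X[labels == j].mean(axis=0)
    return labels, centers, inertia_history, n_iter


def kmeans_cluster(
    hits: SearchResult, space: Space | str, k: int, seed: int
) -> ClusterResult:
    """Cluster the hit list into ``k`` groups in the chosen space.

    Representative ties (two members equidistant from the mean) are broken
    by smaller CBD to the original query, then by id.
    """
    space = Space(space)
    records = hits.records
    if not records:
        raise ValueError("cannot cluster an empty hit list")
    X = fingerprint_matrix(records, space).astype(np.float64)
    raw_labels, centers, inertia_history, n_iter = lloyd_kmeans(X, k, seed)

    members: dict[int, list[int]] = {}
    for i, lab in enumerate(raw_labels):
        members.setdefault(int(lab), []).append(i)
    # Renumber 1..k' by decreasing size (ties by smallest member id), so the
    # returned labels themselves carry the cluster order.
    ordered = sorted(
        members,
        key=lambda lab: (-len(members[lab]), min(records[i].id for i in members[lab])),
    )
    relabel = {old: rank for rank, old in enumerate(ordered, start=1)}

    assignments = {records[i].id: relabel[int(lab)] for i, lab in enumerate(raw_labels)}
    representatives: dict[int, str] = {}
    cbd_of = {record.id: dist for record, dist in hits.hits}
    for old in ordered:
        idx = members[old]
        dists = np.linalg.norm(X[idx] - centers[old], axis=1)
        best = min(
            range(len(idx)),
            key=lambda j: (dists[j], cbd_of[records[idx[j]].id], records[idx[j]].id),
        )
        representatives[relabel[old]] = records[idx[best]].id
    return ClusterResult(
        k=k,
        assignments=assignments,
        cluster_order=[relabel[old] for old in ordered],
        representatives=representatives,
        inertia_history=inertia_history,
        n_iter=n_iter,
    )


def save_clusters(
    result: ClusterResult, hits: SearchResult, path: str | Path
) -> Path:
    """Write hits grouped by cluster: smiles, id, cbd, cluster.

    Rows are grouped in cluster order (largest first) with each cluster's
    representative on its first row, remaining members by (cbd, id).
    """
    path = Path(path)
    by_id = {record.id: (record, dist) for record, dist in hits.hits}
    with path.open("w") as fh:
        fh.write("smiles\tid\tcbd\tcluster\n")
        for label in result.cluster_order:
            member_ids = [i for i, lab in result.assignments.items() if lab == label]
            rep = result.representatives[label]
            rest = sorted(
                (i for i in member_ids if i != rep),
                key=lambda i: (by_id[i][1], i),
            )
            for mol_id in [rep] + rest:
                record, dist = by_id[mol_id]
                fh.write(f"{record.smiles}\t{record.id}\t{dist}\t{label}\n")
    return path
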