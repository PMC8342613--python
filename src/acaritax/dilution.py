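"""Library dilution: single-linkage divergence clustering and
silhouette-optimal representative selection.

A library is partitioned into clusters separated by at least a divergence
cutoff (connected components of the graph with an edge wherever
``d < threshold``; chaining is intentional — this is the single-linkage
dendrogram cut).  Within each cluster the member with the highest
silhouette score represents the cluster, producing the diluted library.
Applying the procedure sequentially at 5% then 10% yields the DIV5/DIV10
coverage series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .distances import DistanceMatrix, distance_matrix
from .io import ReferenceLibrary


@dataclass
class ClusterPartition:
    """Assignment of ids to clusters at a divergence cutoff.

    Cluster labels are contiguous integers starting at 1, ordered by the
    lexicographically smallest member id.
    """

    threshold: float
    ids: list[str]
    labels: np.ndarray  # 1-based ints, aligned with ids

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) if len(self.labels) else 0

    @property
    def assignment(self) -> dict[str, int]:
        return dict(zip(self.ids, (int(x) for x in self.labels)))

    def members(self, label: int) -> list[str]:
        return [i for i, l in zip(self.ids, self.labels) if l == label]


def single_linkage_clusters(D: DistanceMatrix, threshold: float) -> ClusterPartition:
    """Connected components of the graph with an edge wherever
    ``d < threshold`` (strict), so between-cluster divergence is always
    >= threshold.  Undefined (NaN) distances contribute no edge — they are
    treated as "far", with a warning."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold {threshold} outside (0, 1]")
    if D.has_undefined:
        warnings.warn(
            "distance matrix has undefined pairs; treating them as >= threshold",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore"):
        adj = D.d < threshold  # NaN compares False
    n_comp, comp = connected_components(csr_matrix(adj), directed=False)
    # relabel components 1..k ordered by smallest member id
    min_id = {}
    for rid, c in zip(D.ids, comp):
        if c not in min_id or rid < min_id[c]:
            min_id[c] = rid
    order = sorted(min_id, key=lambda c: min_id[c])
    remap = {c: k + 1 for k, c in enumerate(order)}
    labels = np.array([remap[c] for c in comp], dtype=np.int64)
    return ClusterPartition(threshold, list(D.ids), labels)


def silhouette_scores(D: DistanceMatrix, partition: ClusterPartition) -> dict[str, float]:
    """Classic silhouette per sequence: a(i) = mean distance to own
    cluster (self excluded), b(i) = smallest mean distance to another
    cluster, s(i) = (b - a) / max(a, b).  Singletons score 0; a partition
    with a single cluster yields all zeros (b undefined) with a warning."""
    if partition.ids != D.ids:
        raise ValueError("partition ids do not match distance matrix ids")
    n = len(D.ids)
    k = partition.n_clusters
    if k <= 1:
        warnings.warn("single-cluster partition: all silhouettes 0", stacklevel=2)
        return {rid: 0.0 for rid in D.ids}
    onehot = np.zeros((n, k))
    onehot[np.arange(n), partition.labels - 1] = 1.0
    counts = onehot.sum(axis=0)  # (k,)
    sums = D.d @ onehot  # (n, k) sums of distances to each cluster
    scores: dict[str, float] = {}
    for i, rid in enumerate(D.ids):
        c = partition.labels[i] - 1
        size_own = counts[c]
        if size_own <= 1:
            scores[rid] = 0.0
            continue
        a = sums[i, c] / (size_own - 1)  # d[i,i] = 0 contributes nothing
        with np.errstate(invalid="ignore"):
            means_other = sums[i] / counts
        means_other[c] = np.inf
        b = float(means_other.min())
        denom = max(a, b)
        scores[rid] = float((b - a) / denom) if denom > 0 else 0.0
    return scores


@dataclass
class DilutionResult:
    """Chosen representatives (one per cluster) and the diluted library."""

    representatives: list[str]
    diluted_library: ReferenceLibrary


def select_representatives(
    partition: ClusterPartition,
    scores: dict[str, float],
    lib: ReferenceLibrary,
) -> DilutionResult:
    """Per cluster, the member with the highest silhouette; ties broken by
    longest effective length, then smallest id.  Representatives are listed
    in cluster-label order."""
    missing = [i for i in partition.ids if i not in scores]
    if missing:
        raise ValueError(f"silhouette scores missing for: {missing[:5]}")
    by_id = {r.id: r for r in lib.records}
    reps: list[str] = []
    for label in range(1, partition.n_clusters + 1):
        members = partition.members(label)
        reps.append(
            min(
                members,
                key=lambda i: (-scores[i], -by_id[i].effective_length, i),
            )
        )
    return DilutionResult(reps, lib.subset(reps))


@dataclass
class DilutionLevel:
    """One level of the dilution series with its full provenance."""

    threshold: float
    partition: ClusterPartition
    scores: dict[str, float]
    representatives: list[str]
    library: ReferenceLibrary


def dilute(
    lib: ReferenceLibrary,
    threshold: float,
    D: DistanceMatrix | None = None,
) -> DilutionLevel:
    """One dilution step on ``lib`` (distances computed on ``lib`` itself
    unless a matching matrix is supplied)."""
    if D is None:
        D = distance_matrix(lib)
    elif D.ids != lib.ids:
        raise ValueError("supplied distance matrix does not match library")
    part = single_linkage_clusters(D, threshold)
    scores = silhouette_scores(D, part)
    res = select_representatives(part, scores, lib)
    return DilutionLevel(threshold, part, scores, res.representatives, res.diluted_library)


def dilute_series(
    lib: ReferenceLibrary,
    thresholds: tuple[float, ...] = (0.05, 0.10),
    sequential: bool = True,
) -> list[DilutionLevel]:
    """Dilute at successive thresholds.

    In sequential mode (the default, and the construction used for the
    DIV5 -> DIV10 series) each level clusters the previous level's
    representative library on that library's own distance matrix.  In
    independent mode every level starts from the input library.
    """
    if list(thresholds) != sorted(thresholds) or len(set(thresholds)) != len(thresholds):
        raise ValueError("thresholds must be strictly increasing")
    levels: list[DilutionLevel] = []
    current = lib
    for t in thresholds:
        source = current if sequential else lib
        level = dilute(source, t)
        levels.append(level)
        current = level.library
    return levels


def membership_table(levels: list[DilutionLevel]):
    """Tidy per-level cluster membership (id, level threshold, cluster,
    silhouette, is_representative) as a DataFrame."""
    import pandas as pd

    rows = []
    for lev in levels:
        reps = set(lev.representatives)
        for rid, lab in zip(lev.partition.ids, lev.partition.labels):
            rows.append(
                (rid, lev.threshold, int(lab), lev.scores[rid], rid in reps)
            )
    return pd.DataFrame(
        rows, columns=["id", "threshold", "cluster", "silhouette", "is_representative"]
    )
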