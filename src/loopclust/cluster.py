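"""Two-stage clustering of loop embeddings: K-means then agglomerative.

K is selected by sweeping a grid of candidates with seeded K-means and
scoring each partition by silhouette, Davies-Bouldin index, and the
Single Motif Cluster Ratio (SMCR: fraction of clusters holding exactly
one loop).  Candidates violating the SMCR constraint (< 5% by default)
are excluded; among the rest the highest silhouette wins, ties broken by
lower DBI, then by smaller K.  Each K-means cluster is afterwards refined
independently by hierarchical agglomerative clustering cut at a distance
threshold, so structurally heterogeneous clusters split into subclusters
while tight ones stay whole.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import AgglomerativeClustering, KMeans
from sklearn.metrics import (
    adjusted_mutual_info_score,
    adjusted_rand_score,
    davies_bouldin_score,
    silhouette_score,
)
from sklearn.preprocessing import StandardScaler

DEFAULT_SMCR_MAX = 0.05
DEFAULT_DISTANCE_THRESHOLD = 6.0


def smcr(labels) -> float:
    """Single Motif Cluster Ratio: singleton clusters / total clusters."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty assignment")
    _, counts = np.unique(labels, return_counts=True)
    return float(np.sum(counts == 1) / len(counts))


def default_k_grid(n_samples: int, n_steps: int = 10) -> list[int]:
    """Candidate K sweep: every K from 2 to 10, then geometric up to ~n/4.

    Dense coverage at small K matters because the silhouette landscape is
    sharp there; beyond that a geometric tail scaled to the corpus size
    suffices.
    """
    if n_samples < 3:
        raise ValueError("need at least 3 samples to sweep K")
    hi = max(3, n_samples // 4)
    dense = np.arange(2, min(10, hi) + 1)
    tail = np.round(np.geomspace(max(2, min(10, hi)), hi, num=n_steps)).astype(int)
    ks = np.unique(np.concatenate([dense, tail]))
    return [int(k) for k in ks if 2 <= k < n_samples]


def kmeans_cluster(features: np.ndarray, k: int, seed: int = 0) -> np.ndarray:
    """Seeded K-means partition (deterministic for fixed inputs and seed)."""
    features = np.asarray(features, dtype=float)
    n = features.shape[0]
    if k > n:
        raise ValueError(f"K={k} exceeds the number of samples ({n})")
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    return km.fit_predict(features)


@dataclass
class KSelectionReport:
    """Per-candidate metrics and the chosen number of clusters."""

    table: pd.DataFrame        # columns: k, silhouette, davies_bouldin, smcr
    chosen_k: int
    smcr_max: float
    constraint_met: bool

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def select_k(
    features: np.ndarray,
    k_grid=None,
    smcr_max: float = DEFAULT_SMCR_MAX,
    seed: int = 0,
) -> KSelectionReport:
    """Sweep candidate K values and pick one under the SMCR constraint.

    Among candidates with SMCR < ``smcr_max``: maximize silhouette, break
    ties by minimum Davies-Bouldin, then by smallest K.  If no candidate
    satisfies the constraint, the minimum-SMCR candidate is returned with
    ``constraint_met=False``.
    """
    features = np.asarray(features, dtype=float)
    n = features.shape[0]
    if k_grid is None:
        k_grid = default_k_grid(n)
    k_grid = sorted(set(int(k) for k in k_grid))
    if not k_grid:
        raise ValueError("k_grid is empty")
    if any(k >= n or k < 1 for k in k_grid):
        raise ValueError("every candidate K must satisfy 1 <= K < n_samples")

    rows = []
    for k in k_grid:
        labels = kmeans_cluster(features, k, seed=seed)
        n_found = len(np.unique(labels))
        sil = silhouette_score(features, labels) if n_found > 1 else float("nan")
        dbi = davies_bouldin_score(features, labels) if n_found > 1 else float("nan")
        rows.append(
            {"k": k, "silhouette": sil, "davies_bouldin": dbi, "smcr": smcr(labels)}
        )
    table = pd.DataFrame(rows)

    ok = table[table["smcr"] < smcr_max]
    if len(ok):
        best = ok.sort_values(
            ["silhouette", "davies_bouldin", "k"], ascending=[False, True, True]
        ).iloc[0]
        return KSelectionReport(table, int(best["k"]), smcr_max, True)
    fallback = table.sort_values(["smcr", "k"]).iloc[0]
    return KSelectionReport(table, int(fallback["k"]), smcr_max, False)


@dataclass
class ClusterAssignment:
    """loop -> (cluster, subcluster) mapping with the settings that made it."""

    loop_ids: list[str]
    cluster: np.ndarray
    subcluster: np.ndarray      # subcluster index within each cluster
    k: int
    seed: int
    linkage: str = "average"
    distance_threshold: float = DEFAULT_DISTANCE_THRESHOLD
    diagnostics: KSelectionReport | None = None

    def __post_init__(self) -> None:
        if not (len(self.loop_ids) == len(self.cluster) == len(self.subcluster)):
            raise ValueError("assignment arrays must share one length")

    @property
    def subcluster_keys(self) -> list[tuple[int, int]]:
        """Global (cluster, subcluster) key per loop."""
        return list(zip(self.cluster.tolist(), self.subcluster.tolist()))

    @property
    def n_subclusters(self) -> int:
        return len(set(self.subcluster_keys))

    def members(self) -> dict[tuple[int, int], list[int]]:
        out: dict[tuple[int, int], list[int]] = {}
        for idx, key in enumerate(self.subcluster_keys):
            out.setdefault(key, []).append(idx)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "loop_id": self.loop_ids,
                "cluster": self.cluster,
                "subcluster": self.subcluster,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, k: int | None = None, seed: int = 0) -> "ClusterAssignment":
        df = pd.read_csv(path)
        cluster = df["cluster"].to_numpy()
        return cls(
            loop_ids=df["loop_id"].astype(str).tolist(),
            cluster=cluster,
            subcluster=df["subcluster"].to_numpy(),
            k=int(k if k is not None else len(np.unique(cluster))),
            seed=seed,
        )


def subcluster(
    features: np.ndarray,
    cluster_labels: np.ndarray,
    linkage: str = "average",
    distance_threshold: float = DEFAULT_DISTANCE_THRESHOLD,
) -> np.ndarray:
    """Refine each cluster by agglomerative clustering at a distance cutoff.

    Returns a per-sample subcluster index *within its cluster*; clusters
    whose members all sit within the threshold stay single subclusters.
    """
    if distance_threshold <= 0:
        raise ValueError("distance_threshold must be positive")
    features = np.asarray(features, dtype=float)
    cluster_labels = np.asarray(cluster_labels)
    sub = np.zeros(len(cluster_labels), dtype=int)
    for c in np.unique(cluster_labels):
        members = np.flatnonzero(cluster_labels == c)
        if len(members) < 2:
            continue
        agg = AgglomerativeClustering(
            n_clusters=None,
            distance_threshold=distance_threshold,
            linkage=linkage,
            metric="euclidean",
        )
        sub[members] = agg.fit_predict(features[members])
    return sub


def compare_clusterings(pred, truth) -> tuple[float, float]:
    """Adjusted Rand index and adjusted mutual information of two partitions."""
    pred, truth = np.asarray(pred), np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("partitions must cover the same items")
    return (
        float(adjusted_rand_score(truth, pred)),
        float(adjusted_mutual_info_score(truth, pred)),
    )


class TwoStageClustering(BaseEstimator, ClusterMixin):
    """K-means (with automatic K selection) followed by agglomerative refinement.

    Parameters mirror the pipeline defaults: ``k=None`` sweeps
    ``k_grid`` (default: geometric 2..n/4) under the SMCR constraint;
    ``distance_threshold`` cuts the within-cluster dendrograms.  After
    ``fit``: ``k_``, ``labels_`` (K-means clusters), ``subcluster_labels_``
    (within-cluster indices), ``k_report_``.
    """

    def __init__(
        self,
        k: int | None = None,
        k_grid=None,
        smcr_max: float = DEFAULT_SMCR_MAX,
        linkage: str = "average",
        distance_threshold: float = DEFAULT_DISTANCE_THRESHOLD,
        standardize: bool = False,
        seed: int = 0,
    ):
        self.k = k
        self.k_grid = k_grid
        self.smcr_max = smcr_max
        self.linkage = linkage
        self.distance_threshold = distance_threshold
        self.standardize = standardize
        self.seed = seed

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be a 2-D feature matrix")
        feats = StandardScaler().fit_transform(X) if self.standardize else X
        if self.k is None:
            report = select_k(feats, self.k_grid, self.smcr_max, seed=self.seed)
            self.k_report_ = report
            self.k_ = report.chosen_k
        else:
            self.k_report_ = None
            self.k_ = int(self.k)
        self.labels_ = kmeans_cluster(feats, self.k_, seed=self.seed)
        self.subcluster_labels_ = subcluster(
            feats, self.labels_, self.linkage, self.distance_threshold
        )
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_

    def assignment(self, loop_ids) -> ClusterAssignment:
        if not hasattr(self, "labels_"):
            raise RuntimeError("clusterer is not fitted")
        return ClusterAssignment(
            loop_ids=list(loop_ids),
            cluster=self.labels_,
            subcluster=self.subcluster_labels_,
            k=self.k_,
            seed=self.seed,
            linkage=self.linkage,
            distance_threshold=self.distance_threshold,
            diagnostics=self.k_report_,
        )
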