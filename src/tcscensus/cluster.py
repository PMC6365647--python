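"""K-means clustering of genomes in (HPK density, genome size) space.

Genomes are clustered on two features — histidine kinases per 100
protein-coding genes and genome size in bp — after rescaling to remove the
six-orders-of-magnitude mismatch between the two axes. The number of
clusters is chosen by maximizing the mean silhouette coefficient over a k
range, ties broken toward the smaller (more parsimonious) k.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_samples

__all__ = [
    "FeatureMatrix",
    "ClusteringResult",
    "build_feature_matrix",
    "scale_features",
    "kmeans_cluster",
    "select_k_by_silhouette",
]

SCALING_METHODS = ("minmax", "zscore", "sample_unit_norm")


@dataclass
class FeatureMatrix:
    """Ordered genome ids plus an n×2 feature matrix and its scaling record.

    ``scaling_record`` holds the method and per-column parameters applied,
    enough to invert the transform (`{"method": "minmax", "min": [...],
    "range": [...]}` etc.); ``{"method": "none"}`` for raw features.
    """

    genome_ids: list[str]
    features: np.ndarray
    feature_names: tuple[str, str] = ("hpk_per_100_genes", "genome_size_bp")
    scaling_record: dict = field(default_factory=lambda: {"method": "none"})

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D matrix")
        if len(self.genome_ids) != self.features.shape[0]:
            raise ValueError("genome_ids and features row count differ")
        if np.isnan(self.features).any():
            raise ValueError("feature matrix contains missing values")


@dataclass
class ClusteringResult:
    k: int
    assignments: dict[str, int]
    centroids: np.ndarray
    mean_silhouette: float
    per_k_silhouettes: dict[int, float]
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.assignments.items()), columns=["genome_id", "cluster"]
        )


def build_feature_matrix(summaries: pd.DataFrame, metadata: pd.DataFrame) -> FeatureMatrix:
    """Join summaries with metadata genome sizes into the raw 2-feature matrix.

    Genomes missing either feature are dropped (clustering admits no missing
    values); genome size comes from metadata so real and synthetic inputs
    behave identically.
    """
    df = summaries[["genome_id", "hpk_per_100_genes"]].merge(
        metadata[["genome_id", "genome_size_bp"]], on="genome_id", how="inner"
    )
    df = df.dropna(subset=["hpk_per_100_genes", "genome_size_bp"])
    return FeatureMatrix(
        genome_ids=df["genome_id"].tolist(),
        features=df[["hpk_per_100_genes", "genome_size_bp"]].to_numpy(dtype=float),
    )


def scale_features(matrix: FeatureMatrix, method: str = "minmax") -> FeatureMatrix:
    """Rescale the feature matrix; the applied transform is recorded.

    ``minmax`` maps each column to [0, 1]; ``zscore`` to mean 0 / sd 1
    (ddof=1); ``sample_unit_norm`` rescales each row to unit Euclidean
    length. Constant columns make minmax/zscore ill-defined and raise,
    naming the column.
    """
    X = matrix.features
    if X.shape[0] < 2:
        raise ValueError("scaling requires n >= 2")
    if method == "minmax":
        lo, hi = X.min(axis=0), X.max(axis=0)
        span = hi - lo
        for j in np.flatnonzero(span == 0):
            raise ValueError(f"constant column {matrix.feature_names[j]!r} under minmax scaling")
        scaled = (X - lo) / span
        record = {"method": "minmax", "min": lo.tolist(), "range": span.tolist()}
    elif method == "zscore":
        mu, sd = X.mean(axis=0), X.std(axis=0, ddof=1)
        for j in np.flatnonzero(sd == 0):
            raise ValueError(f"constant column {matrix.feature_names[j]!r} under zscore scaling")
        scaled = (X - mu) / sd
        record = {"method": "zscore", "mean": mu.tolist(), "sd": sd.tolist()}
    elif method == "sample_unit_norm":
        norms = np.linalg.norm(X, axis=1, keepdims=True)
        if (norms == 0).any():
            raise ValueError("zero-norm row under sample_unit_norm scaling")
        scaled = X / norms
        record = {"method": "sample_unit_norm", "norms": norms.ravel().tolist()}
    else:
        raise ValueError(f"unknown scaling method {method!r}; choose from {SCALING_METHODS}")
    return FeatureMatrix(
        genome_ids=list(matrix.genome_ids),
        features=scaled,
        feature_names=matrix.feature_names,
        scaling_record=record,
    )


def kmeans_cluster(
    matrix: FeatureMatrix, k: int, seed: int, n_init: int = 10
) -> tuple[dict[str, int], np.ndarray]:
    """Lloyd's K-means with k-means++ init, best of ``n_init`` restarts.

    Deterministic under a fixed seed. Identical points collapsing clusters
    produce a warning, not an error.
    """
    n = matrix.features.shape[0]
    if not 2 <= k < n:
        raise ValueError(f"k must satisfy 2 <= k < n (k={k}, n={n})")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init, random_state=seed, algorithm="lloyd")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sklearn warns on duplicate points
        labels = km.fit_predict(matrix.features)
    if len(set(labels)) < k:
        warnings.warn(f"degenerate clustering: only {len(set(labels))} of {k} clusters populated")
    assignments = {gid: int(lab) for gid, lab in zip(matrix.genome_ids, labels)}
    return assignments, km.cluster_centers_


def mean_silhouette(features: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette coefficient, Euclidean metric.

    s(i) = (b(i) − a(i)) / max(a(i), b(i)) with a the mean intra-cluster
    distance and b the smallest mean distance to another cluster; singleton
    clusters receive s(i) = 0 by convention.
    """
    return float(np.mean(silhouette_samples(features, labels, metric="euclidean")))


def select_k_by_silhouette(
    matrix: FeatureMatrix,
    k_range: range | list[int] = range(2, 11),
    seed: int = 0,
    n_init: int = 10,
) -> ClusteringResult:
    """Run K-means per k and keep the k maximizing mean silhouette.

    Ties (within floating-point exactness) break toward the smaller k. Each
    k reuses the same seed so the selection is invariant to row order under
    a fixed seed protocol.
    """
    ks = [k for k in k_range if 2 <= k < matrix.features.shape[0]]
    if not ks:
        raise ValueError("empty usable k range")
    per_k: dict[int, float] = {}
    results: dict[int, tuple[dict[str, int], np.ndarray]] = {}
    order = {gid: i for i, gid in enumerate(matrix.genome_ids)}
    for k in ks:
        assignments, centroids = kmeans_cluster(matrix, k, seed=seed, n_init=n_init)
        labels = np.array([assignments[g] for g in sorted(assignments, key=order.get)])
        per_k[k] = mean_silhouette(matrix.features, labels)
        results[k] = (assignments, centroids)
    best_k = max(sorted(per_k), key=lambda k: per_k[k])  # sorted => ties to smaller k
    assignments, centroids = results[best_k]
    return ClusteringResult(
        k=best_k,
        assignments=assignments,
        centroids=centroids,
        mean_silhouette=per_k[best_k],
        per_k_silhouettes=per_k,
        seed=seed,
    )
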