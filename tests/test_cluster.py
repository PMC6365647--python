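import itertools

import numpy as np
import pytest

from tcscensus.cluster import (
    FeatureMatrix,
    build_feature_matrix,
    kmeans_cluster,
    mean_silhouette,
    scale_features,
    select_k_by_silhouette,
)


def _fm(X, ids=None):
    X = np.asarray(X, dtype=float)
    ids = ids or [f"g{i}" for i in range(X.shape[0])]
    return FeatureMatrix(genome_ids=ids, features=X)


def brute_force_mean_silhouette(X, labels):
    """Textbook silhouette from the all-pairs distance matrix:
    s(i) = (b-a)/max(a,b); singleton clusters get s(i)=0."""
    X = np.asarray(X, dtype=float)
    n = len(labels)
    d = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    svals = []
    for i in range(n):
        mine = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not mine:
            svals.append(0.0)
            continue
        a = np.mean([d[i, j] for j in mine])
        b = min(
            np.mean([d[i, j] for j in range(n) if labels[j] == lab])
            for lab in set(labels)
            if lab != labels[i]
        )
        svals.append((b - a) / max(a, b))
    return float(np.mean(svals))


def _blobs(k, n_per, sep=10.0, noise=1.0, seed=0):
    rng = np.random.default_rng(seed)
    centers = rng.uniform(0, sep * k, size=(k, 2))
    # enforce separation by spreading centers on a grid
    centers = np.array([[sep * i, sep * ((i * 7) % k)] for i in range(k)], dtype=float)
    X = np.vstack([c + rng.normal(0, noise, size=(n_per, 2)) for c in centers])
    labels = np.repeat(np.arange(k), n_per)
    return X, labels


def test_minmax_endpoints():
    fm = scale_features(_fm([[1, 10], [2, 20], [3, 30]]), "minmax")
    assert np.allclose(fm.features[:, 0], [0, 0.5, 1])
    assert fm.scaling_record["method"] == "minmax"


def test_zscore_symmetric():
    fm = scale_features(_fm([[1, 10], [2, 20], [3, 30]]), "zscore")
    assert np.allclose(fm.features[:, 0], [-1, 0, 1])


def test_sample_unit_norm_345():
    fm = scale_features(_fm([[3, 4], [6, 8]]), "sample_unit_norm")
    assert np.allclose(fm.features, [[0.6, 0.8], [0.6, 0.8]])


def test_constant_column_rejected_by_name():
    with pytest.raises(ValueError, match="hpk_per_100_genes"):
        scale_features(_fm([[1, 10], [1, 20]]), "minmax")
    with pytest.raises(ValueError, match="unknown scaling"):
        scale_features(_fm([[1, 10], [2, 20]]), "bogus")


def test_scaling_record_inverts_transform():
    X = np.array([[1.0, 1e6], [2.0, 3e6], [4.0, 2e6]])
    fm = scale_features(_fm(X), "minmax")
    rec = fm.scaling_record
    back = fm.features * np.array(rec["range"]) + np.array(rec["min"])
    assert np.allclose(back, X)


def test_kmeans_recovers_separated_blobs():
    X, truth = _blobs(2, 20, sep=50, noise=1.0, seed=1)
    fm = _fm(X)
    assignments, _ = kmeans_cluster(fm, 2, seed=0)
    labels = np.array([assignments[g] for g in fm.genome_ids])
    agreement = max(
        np.mean(labels == perm) for perm in ([0] * 20 + [1] * 20, [1] * 20 + [0] * 20)
    )
    assert agreement == 1.0


def test_kmeans_deterministic_and_bounds():
    X, _ = _blobs(3, 10, seed=2)
    fm = _fm(X)
    a1, c1 = kmeans_cluster(fm, 3, seed=5)
    a2, c2 = kmeans_cluster(fm, 3, seed=5)
    assert a1 == a2 and np.allclose(c1, c2)
    with pytest.raises(ValueError):
        kmeans_cluster(fm, 1, seed=0)
    with pytest.raises(ValueError):
        kmeans_cluster(fm, 30, seed=0)


def test_kmeans_degenerate_identical_points_warns():
    fm = _fm(np.ones((6, 2)))
    with pytest.warns(UserWarning, match="degenerate"):
        kmeans_cluster(fm, 2, seed=0)


def test_silhouette_matches_brute_force_oracle():
    """sklearn-backed silhouette equals the all-pairs textbook formula on
    every 2-labelling of small random configurations."""
    rng = np.random.default_rng(3)
    for _ in range(10):
        n = int(rng.integers(4, 7))
        X = rng.uniform(0, 10, size=(n, 2))
        for labs in itertools.product([0, 1], repeat=n):
            labs = np.array(labs)
            if len(set(labs.tolist())) < 2:
                continue
            assert mean_silhouette(X, labs) == pytest.approx(
                brute_force_mean_silhouette(X, labs), abs=1e-12
            )


def test_silhouette_values_in_range():
    X, labels = _blobs(3, 8, seed=4)
    assert -1.0 <= mean_silhouette(X, labels) <= 1.0


@pytest.mark.parametrize("k_true", [2, 3, 4])
def test_select_k_recovers_planted_blobs(k_true):
    X, _ = _blobs(k_true, 15, sep=30, noise=1.0, seed=k_true)
    res = select_k_by_silhouette(_fm(X), range(2, 8), seed=0)
    assert res.k == k_true
    assert res.mean_silhouette == max(res.per_k_silhouettes.values())
    assert -1 <= res.mean_silhouette <= 1


def test_select_k_duplicated_point_groups():
    X = np.array([[0.0, 0.0]] * 5 + [[1.0, 1.0]] * 5)
    res = select_k_by_silhouette(_fm(X), range(2, 5), seed=0)
    assert res.k == 2
    assert res.mean_silhouette == pytest.approx(1.0)


def test_select_k_row_order_invariant():
    X, _ = _blobs(3, 10, sep=25, seed=6)
    fm = _fm(X)
    perm = np.random.default_rng(0).permutation(X.shape[0])
    fm_perm = FeatureMatrix(genome_ids=[fm.genome_ids[i] for i in perm], features=X[perm])
    r1 = select_k_by_silhouette(fm, range(2, 6), seed=9)
    r2 = select_k_by_silhouette(fm_perm, range(2, 6), seed=9)
    assert r1.k == r2.k


def test_select_k_empty_range_errors():
    X, _ = _blobs(2, 5, seed=0)
    with pytest.raises(ValueError):
        select_k_by_silhouette(_fm(X), [], seed=0)


def test_build_feature_matrix_drops_missing():
    import pandas as pd

    sdf = pd.DataFrame({"genome_id": ["a", "b", "c"], "hpk_per_100_genes": [1.0, np.nan, 2.0]})
    mdf = pd.DataFrame({"genome_id": ["a", "b", "c"], "genome_size_bp": [1e6, 2e6, 3e6]})
    fm = build_feature_matrix(sdf, mdf)
    assert fm.genome_ids == ["a", "c"]
    assert fm.features.shape == (2, 2)
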