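"""Data mining on elemental maps: k-means, PCA, correlations, cluster stats.

k-means is a small deterministic Lloyd implementation (k-means++ seeding,
best of ``n_init`` restarts, lowest-index tie-break) that records the
inertia trace of every iteration; PCA delegates to scikit-learn with a
fixed sign convention. Cluster statistics include the ratio helper used for
the stroma-vs-cell Pt contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.decomposition import PCA as _SKPCA


@dataclass
class FeatureMatrix:
    X: np.ndarray                      # n_pixels x n_elements
    elements: tuple
    map_shape: tuple
    scaling: str = "zscore"
    constant_columns: tuple = ()

    @property
    def n_pixels(self) -> int:
        return self.X.shape[0]


@dataclass
class ClusterMap:
    labels: np.ndarray                 # 2-D int
    k: int
    centroids: np.ndarray              # k x n_features
    inertia: float
    inertia_trace: list = field(default_factory=list)


@dataclass
class PCAResult:
    loadings: np.ndarray               # n_elements x n_components
    scores: np.ndarray                 # n_pixels x n_components
    explained: np.ndarray              # variance fractions, nonincreasing
    elements: tuple = ()


def build_feature_matrix(maps: dict, scaling: str = "zscore",
                         elements=None) -> FeatureMatrix:
    """Stack element maps into a row-major (n_pixels x n_elements) matrix."""
    elements = tuple(elements) if elements is not None else tuple(maps)
    shapes = {maps[el].shape for el in elements}
    if len(shapes) != 1:
        raise ValueError(f"maps have mismatched shapes: {shapes}")
    shape = shapes.pop()
    X = np.stack([np.asarray(maps[el], dtype=float).ravel() for el in elements], axis=1)
    const = []
    if scaling == "zscore":
        mu, sd = X.mean(axis=0), X.std(axis=0)
        for j, el in enumerate(elements):
            if sd[j] == 0:
                const.append(el)       # left unscaled, flagged
            else:
                X[:, j] = (X[:, j] - mu[j]) / sd[j]
    elif scaling == "unit-max":
        mx = np.abs(X).max(axis=0)
        for j, el in enumerate(elements):
            if mx[j] == 0:
                const.append(el)
            else:
                X[:, j] = X[:, j] / mx[j]
    elif scaling != "none":
        raise ValueError(f"unknown scaling {scaling!r}")
    return FeatureMatrix(X, elements, shape, scaling, tuple(const))


def _kmeans_pp_init(X, k, rng):
    n = X.shape[0]
    centers = [X[rng.integers(n)]]
    for _ in range(1, k):
        d2 = np.min(((X[:, None, :] - np.array(centers)[None]) ** 2).sum(-1), axis=1)
        total = d2.sum()
        if total == 0:
            centers.append(X[rng.integers(n)])
            continue
        centers.append(X[rng.choice(n, p=d2 / total)])
    return np.array(centers)


def _lloyd(X, centers, max_iter=300):
    trace = []
    labels = None
    for _ in range(max_iter):
        d2 = ((X[:, None, :] - centers[None]) ** 2).sum(-1)
        new_labels = d2.argmin(axis=1)           # argmin -> lowest index on ties
        inertia = float(d2[np.arange(len(X)), new_labels].sum())
        if trace and inertia > trace[-1] + 1e-9 * max(trace[-1], 1.0):
            raise AssertionError("k-means inertia increased")
        trace.append(inertia)
        if labels is not None and np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for j in range(len(centers)):
            members = X[labels == j]
            if len(members):
                centers[j] = members.mean(axis=0)
            else:                                # re-seed empty cluster
                centers[j] = X[d2[np.arange(len(X)), labels].argmax()]
    return labels, centers, trace


def kmeans_cluster(features: FeatureMatrix, k: int, seed: int = 0,
                   n_init: int = 10) -> ClusterMap:
    """Lloyd k-means with k-means++ seeding, best of n_init restarts."""
    X = features.X
    if not 1 <= k <= len(X):
        raise ValueError("k must be in [1, n_pixels]")
    if k > len(np.unique(X, axis=0)):
        raise ValueError("k exceeds the number of distinct points")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_init):
        centers = _kmeans_pp_init(X, k, rng)
        labels, centers, trace = _lloyd(X, centers.copy())
        if best is None or trace[-1] < best[2][-1]:
            best = (labels, centers, trace)
    labels, centers, trace = best
    return ClusterMap(labels.reshape(features.map_shape).astype(np.int32), k,
                      centers, trace[-1], trace)


def pca(features: FeatureMatrix) -> PCAResult:
    """Centered PCA; sign fixed so each component's largest loading is positive."""
    X = features.X
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("PCA needs at least 2 pixels and 2 features")
    n_comp = min(X.shape)
    sk = _SKPCA(n_components=n_comp, svd_solver="full")
    scores = sk.fit_transform(X)
    loadings = sk.components_.T          # n_features x n_comp
    for j in range(n_comp):
        imax = np.abs(loadings[:, j]).argmax()
        if loadings[imax, j] < 0:
            loadings[:, j] = -loadings[:, j]
            scores[:, j] = -scores[:, j]
    return PCAResult(loadings, scores, sk.explained_variance_ratio_.copy(),
                     features.elements)


def correlation_matrix(maps: dict) -> tuple[pd.DataFrame, list]:
    """Pearson correlations between element maps; constant maps flagged, r=0."""
    elements = list(maps)
    shapes = {maps[el].shape for el in elements}
    if len(shapes) != 1:
        raise ValueError("maps have mismatched shapes")
    X = np.stack([np.asarray(maps[el], float).ravel() for el in elements])
    sd = X.std(axis=1)
    flagged = [el for el, s in zip(elements, sd) if s == 0]
    # constant maps get r = 0 off-diagonal (flagged); diagonal stays 1
    R = np.zeros((len(elements), len(elements)))
    ok = sd > 0
    if ok.sum() >= 2:
        R[np.ix_(ok, ok)] = np.corrcoef(X[ok])
    np.fill_diagonal(R, 1.0)
    return pd.DataFrame(R, index=elements, columns=elements), flagged


@dataclass
class ClusterStats:
    table: pd.DataFrame                # index (cluster, element): mean, sd, count
    labels: np.ndarray
    maps: dict

    def ratio(self, labels_a, labels_b, element: str) -> float:
        """Mean concentration over label set A divided by set B."""
        a = np.isin(self.labels, list(labels_a))
        b = np.isin(self.labels, list(labels_b))
        if not a.any() or not b.any():
            raise ValueError("empty label set in ratio")
        m = np.asarray(self.maps[element], float)
        return float(m[a].mean() / m[b].mean())


def cluster_statistics(cluster_labels, maps: dict) -> ClusterStats:
    """Per-cluster, per-element mean/SD/pixel-count table."""
    labels = cluster_labels.labels if hasattr(cluster_labels, "labels") else cluster_labels
    labels = np.asarray(labels)
    shapes = {np.asarray(maps[el]).shape for el in maps}
    if shapes != {labels.shape}:
        raise ValueError("label map and element maps must share one shape")
    rows = []
    for cl in np.unique(labels):
        mask = labels == cl
        for el in maps:
            vals = np.asarray(maps[el], float)[mask]
            rows.append({"cluster": int(cl), "element": el,
                         "mean": float(vals.mean()), "sd": float(vals.std()),
                         "count": int(mask.sum())})
    table = pd.DataFrame(rows).set_index(["cluster", "element"])
    return ClusterStats(table, labels, dict(maps))


def match_clusters(cluster_labels: np.ndarray, truth_labels: np.ndarray):
    """Optimal (Hungarian) matching of cluster ids to ground-truth groups.

    Returns (mapping cluster->truth group, pixel agreement fraction).
    """
    cl = np.asarray(cluster_labels).ravel()
    gt = np.asarray(truth_labels).ravel()
    cids, gids = np.unique(cl), np.unique(gt)
    overlap = np.zeros((len(cids), len(gids)))
    for i, c in enumerate(cids):
        for j, g in enumerate(gids):
            overlap[i, j] = np.sum((cl == c) & (gt == g))
    ri, cj = linear_sum_assignment(-overlap)
    mapping = {int(cids[i]): int(gids[j]) for i, j in zip(ri, cj)}
    agreement = overlap[ri, cj].sum() / len(cl)
    return mapping, float(agreement)
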