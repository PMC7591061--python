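"""Clustering and the clusterability / label-overlap statistics.

Clustering wraps established implementations with the parameterizations used
throughout this workflow: HDBSCAN with minimum cluster size set to 1% of the
dataset, k-means at a known k, and a full-covariance Gaussian mixture on
note features.  The statistics — Hopkins clusterability, silhouette,
homogeneity/completeness/V-measure, and their permutation/rank-test
comparisons — are implemented here directly from their definitions, with
every intermediate quantity (u/w distances, a/b distances, entropies)
exposed for inspection.

Hopkins convention used here: statistic = sum(w_i^d) / (sum(u_i^d) + sum(w_i^d)),
where w are within-data nearest-neighbor distances and u are distances from
uniformly sampled reference points to the data.  Values near 0 mean
clustered; values near 0.5 mean indistinguishable from uniform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import Delaunay
from scipy.spatial.distance import cdist
from scipy.stats import kruskal

NOISE_LABEL = -1


@dataclass
class ClusterLabels:
    labels: np.ndarray
    method: str
    params: dict
    noise_value: int | None = None

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_clusters(self) -> int:
        labs = set(self.labels.tolist())
        if self.noise_value is not None:
            labs.discard(self.noise_value)
        return len(labs)


@dataclass
class HopkinsResult:
    statistic: float
    u: np.ndarray
    w: np.ndarray
    d: int
    m: int
    seed: int
    y_sample: np.ndarray
    x_indices: np.ndarray
    sampling: str          # "convex_hull" or "bounding_box"
    degenerate: bool = False


@dataclass
class SilhouetteResult:
    coefficients: np.ndarray
    a: np.ndarray
    b: np.ndarray
    score: float


@dataclass
class OverlapResult:
    homogeneity: float
    completeness: float
    v_measure: float
    h_classes: float
    h_clusters: float
    h_classes_given_clusters: float
    h_clusters_given_classes: float


@dataclass
class GroupComparison:
    statistic: float
    dof: int
    p_value: float
    group_sizes: tuple


# ---------------------------------------------------------------- clustering

def cluster_hdbscan(Z, min_cluster_frac: float = 0.01) -> ClusterLabels:
    """Density-based hierarchical clustering; min cluster size = 1% of N.

    Unassigned (noise) points carry the label -1.
    """
    from sklearn.cluster import HDBSCAN

    X = _as_matrix(Z)
    n = X.shape[0]
    if n < 1.0 / min_cluster_frac:
        raise ValueError(
            f"need at least {int(np.ceil(1 / min_cluster_frac))} points for "
            f"min_cluster_frac={min_cluster_frac}"
        )
    min_cluster_size = max(2, int(round(min_cluster_frac * n)))
    # allow_single_cluster: a dataset that IS one cluster must be reportable
    # as such, not forced apart into children of the condensed-tree root
    labels = HDBSCAN(min_cluster_size=min_cluster_size,
                     allow_single_cluster=True).fit_predict(X)
    return ClusterLabels(labels=labels, method="hdbscan",
                         params={"min_cluster_frac": min_cluster_frac,
                                 "min_cluster_size": min_cluster_size},
                         noise_value=NOISE_LABEL)


def cluster_kmeans(X, k: int, seed: int = 0, n_init: int = 10) -> ClusterLabels:
    from sklearn.cluster import KMeans

    X = _as_matrix(X)
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds the number of points {X.shape[0]}")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(X)
    return ClusterLabels(labels=km.labels_, method="kmeans",
                         params={"k": k, "seed": seed, "n_init": n_init})


def cluster_gmm(F, n_components: int, seed: int = 0, n_init: int = 5) -> ClusterLabels:
    """Full-covariance Gaussian mixture on a (small) feature matrix."""
    from sklearn.mixture import GaussianMixture

    F = _as_matrix(F)
    if F.shape[0] <= n_components:
        raise ValueError("need more points than mixture components")
    gm = GaussianMixture(n_components=n_components, covariance_type="full",
                         random_state=seed, n_init=n_init).fit(F)
    if not gm.converged_:
        raise RuntimeError("Gaussian mixture fit did not converge")
    result = ClusterLabels(labels=gm.predict(F), method="gmm",
                           params={"n_components": n_components, "seed": seed})
    result.means_ = gm.means_
    return result


def pca_reduce(X, n_components: int = 100) -> np.ndarray:
    """First principal-component scores, truncated to the available rank."""
    from sklearn.decomposition import PCA

    X = _as_matrix(X)
    k = min(n_components, X.shape[0], X.shape[1])
    return PCA(n_components=k).fit_transform(X)


def _as_matrix(Z) -> np.ndarray:
    if hasattr(Z, "Z"):
        Z = Z.Z
    elif hasattr(Z, "X"):
        Z = Z.X
    X = np.asarray(Z, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected an N x d matrix")
    return X


# ------------------------------------------------------------ clusterability

def _sample_convex(X: np.ndarray, m: int, rng: np.random.Generator):
    """m uniform points over the convex hull of X (d <= 3), else bounding box."""
    n, d = X.shape
    lo, hi = X.min(axis=0), X.max(axis=0)
    span = hi - lo
    if np.all(span == 0):
        return np.tile(lo, (m, 1)), "degenerate"
    if d > 3:
        return rng.uniform(lo, hi, size=(m, d)), "bounding_box"
    try:
        tri = Delaunay(X)
    except Exception:  # collinear/degenerate cloud: fall back to the box
        return rng.uniform(lo, hi, size=(m, d)), "bounding_box"
    out = np.empty((m, d))
    filled = 0
    while filled < m:
        batch = rng.uniform(lo, hi, size=(max(2 * (m - filled), 64), d))
        inside = batch[tri.find_simplex(batch) >= 0]
        take = min(len(inside), m - filled)
        out[filled:filled + take] = inside[:take]
        filled += take
    return out, "convex_hull"


def hopkins(X, m: int | None = None, seed: int = 0,
            y_sample: np.ndarray | None = None) -> HopkinsResult:
    """Hopkins clusterability statistic, sum(w^d) / (sum(u^d) + sum(w^d)).

    Y is sampled uniformly over the convex hull of X (rejection sampling, for
    d <= 3) or over the axis-aligned bounding box (d > 3, recorded in
    ``sampling``).  w is computed over an m-subsample of X without
    replacement (all of X when m == N), nearest neighbor excluding self.
    ``y_sample`` lets tests inject a fixed reference set.
    """
    from sklearn.neighbors import NearestNeighbors

    X = _as_matrix(X)
    n, d = X.shape
    if n < 2:
        raise ValueError("need at least two points")
    if m is None:
        m = n
    if not 1 <= m <= n:
        raise ValueError("m must be in [1, N]")
    # spawn-key derivation: the reference sampler must not replay the stream
    # of a data generator that happens to share the same seed
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                       spawn_key=(1,)))

    if y_sample is not None:
        Y = np.asarray(y_sample, dtype=float)
        sampling = "injected"
        m = Y.shape[0]
        x_idx = (rng.choice(n, size=m, replace=False) if m < n else np.arange(n))
    else:
        x_idx = (rng.choice(n, size=m, replace=False) if m < n else np.arange(n))
        Y, sampling = _sample_convex(X, m, rng)
        if sampling == "degenerate":
            zeros = np.zeros(m)
            return HopkinsResult(statistic=0.0, u=zeros, w=zeros, d=d, m=m,
                                 seed=seed, y_sample=Y, x_indices=x_idx,
                                 sampling=sampling, degenerate=True)

    nn = NearestNeighbors(n_neighbors=2).fit(X)
    u = nn.kneighbors(Y, n_neighbors=1)[0][:, 0]
    w = nn.kneighbors(X[x_idx], n_neighbors=2)[0][:, 1]  # exclude self

    sw = float(np.sum(w ** d))
    su = float(np.sum(u ** d))
    denom = su + sw
    stat = 0.0 if denom == 0 else sw / denom
    return HopkinsResult(statistic=stat, u=u, w=w, d=d, m=m, seed=seed,
                         y_sample=Y, x_indices=x_idx, sampling=sampling,
                         degenerate=denom == 0)


# -------------------------------------------------------------- silhouette

def silhouette(X, labels) -> SilhouetteResult:
    """Silhouette coefficients and their mean (euclidean distance).

    a_i is the mean distance to other points of i's cluster; b_i the smallest
    mean distance to another cluster.  Points in singleton clusters get
    s_i = 0 by convention.
    """
    X = _as_matrix(X)
    labels = np.asarray(labels)
    if len(labels) != X.shape[0]:
        raise ValueError("labels must align with rows of X")
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("silhouette requires at least two clusters")

    D = cdist(X, X)
    n = X.shape[0]
    masks = {c: labels == c for c in uniq}
    sizes = {c: int(masks[c].sum()) for c in uniq}
    a = np.zeros(n)
    b = np.zeros(n)
    s = np.zeros(n)
    for i in range(n):
        own = labels[i]
        if sizes[own] > 1:
            a[i] = D[i, masks[own]].sum() / (sizes[own] - 1)
        other_means = [D[i, masks[c]].mean() for c in uniq if c != own]
        b[i] = min(other_means)
        if sizes[own] == 1:
            s[i] = 0.0
        else:
            denom = max(a[i], b[i])
            s[i] = 0.0 if denom == 0 else (b[i] - a[i]) / denom
    return SilhouetteResult(coefficients=s, a=a, b=b, score=float(s.mean()))


# ------------------------------------------------------------ label overlap

def _entropy_bits(counts: np.ndarray) -> float:
    counts = counts[counts > 0].astype(float)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def overlap(classes, clusters) -> OverlapResult:
    """Homogeneity, completeness and V-measure between two labelings.

    Entropies are computed in bits from the joint contingency table.
    Conventions: homogeneity is 1 when the class labeling carries no entropy,
    completeness is 1 when the cluster labeling carries none, and V is 0
    when homogeneity + completeness is 0.
    """
    classes = np.asarray(classes)
    clusters = np.asarray(clusters)
    if classes.shape != clusters.shape:
        raise ValueError("labelings must have equal length")
    if classes.size == 0:
        raise ValueError("need at least one point")
    _, ci = np.unique(classes, return_inverse=True)
    _, ki = np.unique(clusters, return_inverse=True)
    table = np.zeros((ci.max() + 1, ki.max() + 1))
    np.add.at(table, (ci, ki), 1.0)
    n = table.sum()

    h_classes = _entropy_bits(table.sum(axis=1))
    h_clusters = _entropy_bits(table.sum(axis=0))
    # H(classes | clusters) = sum_k p(k) H(classes | k)
    h_c_given_k = sum(
        (table[:, k].sum() / n) * _entropy_bits(table[:, k])
        for k in range(table.shape[1]) if table[:, k].sum() > 0
    )
    h_k_given_c = sum(
        (table[c].sum() / n) * _entropy_bits(table[c])
        for c in range(table.shape[0]) if table[c].sum() > 0
    )
    h = 1.0 if h_classes == 0 else 1.0 - h_c_given_k / h_classes
    c = 1.0 if h_clusters == 0 else 1.0 - h_k_given_c / h_clusters
    v = 0.0 if h + c == 0 else 2.0 * h * c / (h + c)
    return OverlapResult(homogeneity=h, completeness=c, v_measure=v,
                         h_classes=h_classes, h_clusters=h_clusters,
                         h_classes_given_clusters=float(h_c_given_k),
                         h_clusters_given_classes=float(h_k_given_c))


def permutation_null_vmeasure(classes, clusters, n_perm: int = 10000,
                              seed: int = 0) -> tuple[float, float]:
    """Chance level of V-measure under label permutation, plus a p-value.

    Permutes the cluster labeling n_perm times; returns the mean null V and
    p = (1 + #{null >= observed}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    clusters = np.asarray(clusters)
    observed = overlap(classes, clusters).v_measure
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = overlap(classes, rng.permutation(clusters)).v_measure
    p = (1.0 + float(np.sum(null >= observed))) / (n_perm + 1.0)
    return float(null.mean()), p


def compare_silhouette_kruskal(*groups) -> GroupComparison:
    """Kruskal-Wallis H-test across groups of silhouette coefficients."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) == 0 for g in groups):
        raise ValueError("each group needs at least one value")
    flat = np.concatenate(groups)
    if np.all(flat == flat[0]):
        return GroupComparison(statistic=0.0, dof=len(groups) - 1, p_value=1.0,
                               group_sizes=tuple(len(g) for g in groups))
    stat, p = kruskal(*groups)
    return GroupComparison(statistic=float(stat), dof=len(groups) - 1,
                           p_value=float(p),
                           group_sizes=tuple(len(g) for g in groups))


def drop_noise(labels_true, cluster_labels: ClusterLabels):
    """Mask out density-clustering noise points from a pair of labelings."""
    labs = cluster_labels.labels
    if cluster_labels.noise_value is None:
        return np.asarray(labels_true), labs
    keep = labs != cluster_labels.noise_value
    return np.asarray(labels_true)[keep], labs[keep]
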