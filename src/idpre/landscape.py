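"""Reduced-dimension conformational landscape: features, embedding, clusters.

The disordered chain is divided into consecutive 4-residue segments (the final
partial segment retained), and for every segment pair separated by more than
two intervening segments the per-frame minimum Cα–Cα distance is recorded; a
311-residue chain gives 78 segments and 2775 such distances.  These features
feed a PCA (top 50 components), a 2-D UMAP embedding trained on a seeded 10%
subsample with the remaining frames projected in, and graph-community
clustering (Louvain on a K-nearest-neighbor graph over the PC coordinates).
Weighted cluster contributions rank the clusters under the refined ensemble
weights; a K-means clustering of the embedding with matching k, compared by
ARI/AMI against permutation null distributions, validates the partition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import networkx as nx
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import adjusted_mutual_info_score, adjusted_rand_score
from sklearn.neighbors import kneighbors_graph

__all__ = [
    "SegmentFeatureSet",
    "EmbeddingModel",
    "ClusterAssignment",
    "ValidationReport",
    "segment_windows",
    "segment_pairs",
    "segment_features",
    "reduce_pca",
    "embed_umap",
    "cluster_conformations",
    "cluster_contributions",
    "validate_clustering",
    "radius_of_gyration",
    "weighted_quantile",
]


def segment_windows(n_residues: int, window: int = 4) -> list[tuple[int, int]]:
    """Consecutive non-overlapping windows as 0-based half-open index ranges.

    The final partial window is retained, so 311 residues give 78 segments.
    """
    if n_residues < window:
        raise ValueError(f"chain of {n_residues} residues shorter than one window")
    return [(s, min(s + window, n_residues)) for s in range(0, n_residues, window)]


def segment_pairs(n_segments: int, min_separation: int = 4) -> np.ndarray:
    """Segment index pairs (a, b) with b − a ≥ ``min_separation``.

    ``min_separation=4`` keeps pairs with more than two segments strictly in
    between; 78 segments give 2775 pairs.
    """
    pairs = [
        (a, b)
        for a in range(n_segments)
        for b in range(a + min_separation, n_segments)
    ]
    return np.array(pairs, dtype=int).reshape(-1, 2)


@dataclass
class SegmentFeatureSet:
    """Per-frame minimum inter-segment Cα distances for retained pairs."""

    windows: list[tuple[int, int]]
    pairs: np.ndarray            # (n_features, 2) segment index pairs
    features: np.ndarray         # (n_frames, n_features) distances in Å

    @property
    def n_features(self) -> int:
        return self.pairs.shape[0]


def _segment_min_distance_matrix(coords: np.ndarray,
                                 windows: list[tuple[int, int]]) -> np.ndarray:
    """(F, n_seg, n_seg) min Cα distance between every window pair per frame."""
    f, n, _ = coords.shape
    n_seg = len(windows)
    w = windows[0][1] - windows[0][0]
    pad = n_seg * w - n
    if pad:
        big = np.full((f, n + pad, 3), 1e6)
        big[:, :n] = coords
        coords = big
    d = np.linalg.norm(
        coords[:, :, None, :] - coords[:, None, :, :], axis=-1
    )  # (F, N, N)
    d = d.reshape(f, n_seg, w, n_seg, w)
    return d.min(axis=(2, 4))


def segment_features(ensemble, chain: str = "A", window: int = 4,
                     min_separation: int = 4,
                     chunk: int = 100) -> SegmentFeatureSet:
    """Minimum inter-segment Cα distances for all retained segment pairs.

    Pairs must have more than two segments strictly between them
    (``min_separation=4`` in segment indices).
    """
    coords = ensemble.ca_coords(chain)
    n = coords.shape[1]
    windows = segment_windows(n, window)
    pairs = segment_pairs(len(windows), min_separation)
    feats = np.empty((coords.shape[0], pairs.shape[0]))
    for lo in range(0, coords.shape[0], chunk):
        hi = min(lo + chunk, coords.shape[0])
        mat = _segment_min_distance_matrix(coords[lo:hi], windows)
        feats[lo:hi] = mat[:, pairs[:, 0], pairs[:, 1]]
    return SegmentFeatureSet(windows=windows, pairs=pairs, features=feats)


@dataclass
class EmbeddingModel:
    """PCA basis plus (optionally) a 2-D embedding of all frames."""

    pca: PCA
    pc_coords: np.ndarray                 # (n_frames, n_components)
    kept_features: np.ndarray             # indices of non-constant features
    train_idx: np.ndarray | None = None   # frames used to train the embedding
    embedding: np.ndarray | None = None   # (n_frames, 2)
    reducer: object | None = None

    @property
    def explained_variance(self) -> np.ndarray:
        return self.pca.explained_variance_


def reduce_pca(features: SegmentFeatureSet | np.ndarray,
               n_components: int = 50) -> EmbeddingModel:
    """Centered PCA of the feature matrix, constant features dropped."""
    x = features.features if isinstance(features, SegmentFeatureSet) else features
    x = np.asarray(x, dtype=float)
    if x.shape[0] < 2:
        raise ValueError("PCA needs at least 2 frames")
    keep = np.flatnonzero(x.std(axis=0) > 1e-12)
    if keep.size == 0:
        # fully degenerate input (all frames identical): one zero component
        x = np.zeros((x.shape[0], 1))
        keep = np.array([], dtype=int)
    else:
        x = x[:, keep]
    n_components = max(1, min(n_components, x.shape[0] - 1, x.shape[1]))
    pca = PCA(n_components=n_components, svd_solver="full")
    pc = pca.fit_transform(x)
    return EmbeddingModel(pca=pca, pc_coords=pc, kept_features=keep)


def embed_umap(model: EmbeddingModel, subsample_fraction: float = 0.1,
               seed: int = 0, n_neighbors: int = 15,
               min_dist: float = 0.1) -> EmbeddingModel:
    """2-D UMAP trained on a seeded random subsample, rest projected in.

    Training frames keep their fitted coordinates; the remaining frames are
    projected into the trained space.  A subsample below 50 frames raises the
    fraction with a warning.  Deterministic under fixed ``seed``.
    """
    import warnings

    from umap import UMAP

    nf = model.pc_coords.shape[0]
    n_train = int(round(subsample_fraction * nf))
    if n_train < 50:
        n_train = min(nf, 50)
        warnings.warn("UMAP training subset below 50 frames; fraction raised")
    rng = np.random.default_rng(seed)
    train_idx = np.sort(rng.choice(nf, size=n_train, replace=False))
    reducer = UMAP(
        n_components=2,
        n_neighbors=min(n_neighbors, n_train - 1),
        min_dist=min_dist,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fitted = reducer.fit_transform(model.pc_coords[train_idx])
        embedding = np.empty((nf, 2))
        embedding[train_idx] = fitted
        rest = np.setdiff1d(np.arange(nf), train_idx)
        if rest.size:
            embedding[rest] = reducer.transform(model.pc_coords[rest])
    model.train_idx = train_idx
    model.embedding = embedding
    model.reducer = reducer
    return model


@dataclass
class ClusterAssignment:
    """Cluster label per frame with weighted contributions."""

    labels: np.ndarray
    method: str
    contributions: pd.DataFrame | None = None      # cluster, contribution (desc)
    representatives: dict[int, int] = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.labels))


def cluster_conformations(model: EmbeddingModel, k_neighbors: int = 15,
                          resolution: float = 1.0,
                          seed: int = 0) -> ClusterAssignment:
    """Louvain community detection on a KNN graph over PC coordinates.

    A disconnected graph simply yields communities per component; fully
    degenerate input (all frames coincident) is one cluster.  Deterministic
    under ``seed``.
    """
    x = model.pc_coords
    if np.ptp(x, axis=0).max() < 1e-8:
        return ClusterAssignment(
            labels=np.zeros(x.shape[0], dtype=int), method="knn-louvain"
        )
    k = min(k_neighbors, x.shape[0] - 1)
    adj = kneighbors_graph(x, n_neighbors=k, mode="connectivity")
    adj = adj.maximum(adj.T)
    graph = nx.from_scipy_sparse_array(adj)
    communities = nx.community.louvain_communities(
        graph, resolution=resolution, seed=seed
    )
    labels = np.empty(x.shape[0], dtype=int)
    for c, members in enumerate(
        sorted(communities, key=lambda s: -len(s))
    ):
        labels[list(members)] = c
    assignment = ClusterAssignment(labels=labels, method="knn-louvain")
    if model.embedding is not None:
        for c in np.unique(labels):
            idx = np.flatnonzero(labels == c)
            centroid = model.embedding[idx].mean(axis=0)
            d = np.linalg.norm(model.embedding[idx] - centroid, axis=1)
            assignment.representatives[int(c)] = int(idx[np.argmin(d)])
    return assignment


def cluster_contributions(assignment: ClusterAssignment, weights: np.ndarray,
                          threshold: float = 0.01) -> pd.DataFrame:
    """Weighted contribution per cluster, descending, with a top-cluster flag.

    ``contribution(c) = Σ_{j∈c} w_j``; clusters above ``threshold`` are the
    top set, and the cumulative share of that set is attached as metadata in
    the ``top`` column / ``cumulative`` field of the returned frame.
    """
    weights = np.asarray(weights, dtype=float)
    if not np.isclose(weights.sum(), 1.0):
        raise ValueError("weights must be normalized")
    ser = pd.Series(weights).groupby(pd.Series(assignment.labels)).sum()
    df = (
        ser.rename("contribution")
        .rename_axis("cluster")
        .reset_index()
        .sort_values("contribution", ascending=False, kind="mergesort")
        .reset_index(drop=True)
    )
    df["top"] = df["contribution"] > threshold
    df.attrs["top_set_share"] = float(df.loc[df["top"], "contribution"].sum())
    assignment.contributions = df
    return df


@dataclass
class ValidationReport:
    """Agreement between two clusterings against permutation nulls."""

    ari: float
    ami: float
    null_ari_mean: float
    null_ari_sd: float
    null_ami_mean: float
    null_ami_sd: float
    p_ari: float
    p_ami: float
    n_shuffles: int
    degenerate: bool = False


def validate_clustering(labels_a: np.ndarray, labels_b: np.ndarray,
                        n_shuffles: int = 10_000,
                        seed: int = 0) -> ValidationReport:
    """ARI/AMI between two partitions plus permutation null distributions.

    The null is built by shuffling ``labels_a``; under permutation both
    chance-corrected indices have expectation ~0.  Degenerate single-cluster
    input is flagged (indices undefined).
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("label vectors differ in length")
    if len(np.unique(a)) < 2 or len(np.unique(b)) < 2:
        return ValidationReport(
            ari=np.nan, ami=np.nan, null_ari_mean=np.nan, null_ari_sd=np.nan,
            null_ami_mean=np.nan, null_ami_sd=np.nan, p_ari=np.nan,
            p_ami=np.nan, n_shuffles=0, degenerate=True,
        )
    ari = adjusted_rand_score(a, b)
    ami = adjusted_mutual_info_score(a, b)
    rng = np.random.default_rng(seed)
    null_ari = np.empty(n_shuffles)
    null_ami = np.empty(n_shuffles)
    for i in range(n_shuffles):
        perm = rng.permutation(a)
        null_ari[i] = adjusted_rand_score(perm, b)
        null_ami[i] = adjusted_mutual_info_score(perm, b)
    return ValidationReport(
        ari=float(ari),
        ami=float(ami),
        null_ari_mean=float(null_ari.mean()),
        null_ari_sd=float(null_ari.std()),
        null_ami_mean=float(null_ami.mean()),
        null_ami_sd=float(null_ami.std()),
        p_ari=float((np.sum(null_ari >= ari) + 1) / (n_shuffles + 1)),
        p_ami=float((np.sum(null_ami >= ami) + 1) / (n_shuffles + 1)),
        n_shuffles=n_shuffles,
    )


def kmeans_on_embedding(model: EmbeddingModel, k: int,
                        seed: int = 0) -> ClusterAssignment:
    """K-means partition of the 2-D embedding (validation counterpart)."""
    if model.embedding is None:
        raise ValueError("embedding not computed")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    return ClusterAssignment(labels=km.fit_predict(model.embedding),
                             method="kmeans-embedding")


def weighted_quantile(values: np.ndarray, weights: np.ndarray,
                      q) -> np.ndarray:
    """Weighted quantiles by inverting the weighted empirical CDF."""
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cdf = np.cumsum(w) - 0.5 * w
    cdf /= np.sum(w)
    return np.interp(np.atleast_1d(q), cdf, v)


def radius_of_gyration(ensemble, weights: np.ndarray | None = None,
                       chains: list[str] | None = None,
                       per_state: bool = False):
    """Per-frame Rg (unit bead masses) with weighted summary statistics.

    Returns ``(rg, summary)`` where ``rg`` is per-frame and ``summary`` maps
    label → dict with weighted mean, quartiles and 1.5·IQR outlier count.
    With ``per_state=True`` summaries are computed per state label by
    restricting and renormalizing the weights.
    """
    if chains is None:
        chains = ensemble.chain_ids
    if not chains:
        raise ValueError("empty chain selection")
    coords = np.concatenate([ensemble.chains[c] for c in chains], axis=1)
    center = coords.mean(axis=1, keepdims=True)
    rg = np.sqrt(np.mean(np.sum((coords - center) ** 2, axis=2), axis=1))
    if weights is None:
        weights = ensemble.prior_weights
    weights = np.asarray(weights, dtype=float)

    def summarize(vals, w):
        w = w / w.sum()
        q1, med, q3 = weighted_quantile(vals, w, [0.25, 0.5, 0.75])
        iqr = q3 - q1
        outliers = int(np.sum((vals < q1 - 1.5 * iqr) | (vals > q3 + 1.5 * iqr)))
        return {
            "mean": float(np.sum(w * vals)),
            "q1": float(q1),
            "median": float(med),
            "q3": float(q3),
            "n_outliers": outliers,
        }

    summary = {"all": summarize(rg, weights)}
    if per_state:
        for s in np.unique(ensemble.states):
            mask = ensemble.states == s
            if weights[mask].sum() <= 0:
                raise ValueError(f"state {s} has zero total weight")
            summary[str(s)] = summarize(rg[mask], weights[mask])
    return rg, summary
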