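"""Consensus cell-type classification from intrinsic-feature tables.

The classification combines two unsupervised views of the normalized feature
matrix — Ward hierarchical clustering and graph-based community detection on
a shared-nearest-neighbor (SNN) graph — computed on the first four principal
components.  Cells assigned to corresponding clusters by both methods keep a
consensus label; all others are discarded.  Agreement with a reference
labeling is summarized as percent accuracy after optimal label matching,
with a shuffle-based chance level.

Estimator-style API (scikit-learn conventions): :class:`FeatureNormalizer`
is a transformer, :class:`ConsensusClusterer` a clusterer with ``fit`` /
``fit_predict`` and trailing-underscore fitted attributes.
"""

from __future__ import annotations

import warnings

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import linear_sum_assignment
from sklearn.base import BaseEstimator, ClusterMixin, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE
from sklearn.neighbors import NearestNeighbors
from sklearn.utils.validation import check_is_fitted

from .errors import InsufficientDataError

__all__ = [
    "DISCARDED",
    "FeatureNormalizer",
    "normalize_features",
    "ConsensusClusterer",
    "consensus_cluster",
    "clustering_accuracy",
    "embed_2d",
    "soma_scores",
]

#: Label assigned to cells on which the two clustering methods disagree.
DISCARDED = -1


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


class FeatureNormalizer(TransformerMixin, BaseEstimator):
    """Dataset-level normalization of an intrinsic-parameter matrix.

    Column-wise, in order: shift positive by the column minimum; divide by the
    column sum (of the shifted values across the entire dataset) and scale by
    10,000; apply log(1 + x); z-score.  Columns that are constant after the
    shift would produce 0/0 — they are set to all-zero with a warning.
    """

    def __init__(self, scale: float = 10_000.0):
        self.scale = scale

    def fit(self, X, y=None):
        X = self._validate(X)
        self.min_ = X.min(axis=0)
        shifted = X - self.min_
        self.colsum_ = shifted.sum(axis=0)
        self.constant_ = self.colsum_ <= 0
        with np.errstate(divide="ignore", invalid="ignore"):
            logged = np.log1p(shifted / np.where(self.constant_, 1.0, self.colsum_)
                              * self.scale)
        self.mean_ = logged.mean(axis=0)
        self.std_ = logged.std(axis=0)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "min_")
        X = self._validate(X)
        if np.any(self.constant_):
            warnings.warn("constant feature columns set to zero after normalization")
        shifted = X - self.min_
        logged = np.log1p(shifted / np.where(self.constant_, 1.0, self.colsum_)
                          * self.scale)
        std = np.where(self.std_ > 0, self.std_, 1.0)
        z = (logged - self.mean_) / std
        z[:, self.constant_ | (self.std_ <= 0)] = 0.0
        return z

    @staticmethod
    def _validate(X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.size == 0:
            raise InsufficientDataError("feature matrix must be 2-D and non-empty")
        if np.isnan(X).any():
            raise ValueError("feature matrix contains missing values; impute or drop upstream")
        return X


def normalize_features(X) -> np.ndarray:
    """Functional wrapper over :class:`FeatureNormalizer` (fit on X itself)."""
    return FeatureNormalizer().fit_transform(X)


# ---------------------------------------------------------------------------
# consensus clustering
# ---------------------------------------------------------------------------


def _deterministic_pca(X: np.ndarray, n_components: int) -> np.ndarray:
    """PCA scores with a deterministic sign convention: the largest-magnitude
    loading of every component is made positive."""
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    for j in range(scores.shape[1]):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, j] *= -1.0
    return scores


def _snn_graph(pcs: np.ndarray, k: int) -> ig.Graph:
    """Shared-nearest-neighbor graph: nodes are cells, edges weighted by the
    Jaccard overlap of k-NN sets (self included, Seurat-style); zero-overlap
    edges are pruned.  Neighbor ties resolve by index order (stable kd-tree)."""
    nn = NearestNeighbors(n_neighbors=k).fit(pcs)
    _, idx = nn.kneighbors(pcs)
    n = pcs.shape[0]
    sets = [set(row) for row in idx]
    edges, weights = [], []
    for i in range(n):
        for j in idx[i]:
            j = int(j)
            if j <= i:
                continue
            inter = len(sets[i] & sets[j])
            union = len(sets[i] | sets[j])
            w = inter / union
            if w > 0:
                edges.append((i, j))
                weights.append(w)
    g = ig.Graph(n=n, edges=edges)
    g.es["weight"] = weights
    return g


def _match_labels(a: np.ndarray, b: np.ndarray) -> dict:
    """Maximum-overlap assignment from labels of ``b`` to labels of ``a``
    via the Hungarian algorithm on the contingency table."""
    ua, ub = np.unique(a), np.unique(b)
    cont = np.zeros((len(ub), len(ua)))
    for i, lb in enumerate(ub):
        for j, la in enumerate(ua):
            cont[i, j] = np.sum((b == lb) & (a == la))
    rows, cols = linear_sum_assignment(-cont)
    return {int(ub[r]): int(ua[c]) for r, c in zip(rows, cols)}


class ConsensusClusterer(ClusterMixin, BaseEstimator):
    """Consensus of Ward hierarchical clustering and SNN-graph community
    detection on the leading principal components of normalized features.

    Parameters
    ----------
    n_clusters : flat cluster count for the Ward tree (default 6 types).
    n_neighbors : k of the SNN graph (default 20).
    resolution : resolution of the modularity partition (default 1.5).
    n_pcs : number of principal components retained (default 4).
    random_state : seeds the community-detection initialization.

    Attributes (after ``fit``)
    --------------------------
    ``labels_`` — consensus label per cell, ``DISCARDED`` (−1) on disagreement;
    ``hier_labels_``, ``graph_labels_`` — the two method labelings;
    ``pc_scores_`` — retained PC scores; ``n_discarded_``.
    """

    def __init__(self, n_clusters: int = 6, n_neighbors: int = 20,
                 resolution: float = 1.5, n_pcs: int = 4,
                 random_state: int | None = 0):
        self.n_clusters = n_clusters
        self.n_neighbors = n_neighbors
        self.resolution = resolution
        self.n_pcs = n_pcs
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.shape[0] < self.n_neighbors + 1:
            raise InsufficientDataError(
                f"need at least n_neighbors+1={self.n_neighbors + 1} cells, got {X.shape[0]}")
        pcs = _deterministic_pca(X, min(self.n_pcs, X.shape[1]))
        self.pc_scores_ = pcs
        # method 1: Ward tree cut at n_clusters
        self.hier_labels_ = fcluster(linkage(pcs, method="ward"),
                                     t=self.n_clusters, criterion="maxclust") - 1
        # method 2: SNN graph + modularity communities
        g = _snn_graph(pcs, self.n_neighbors)
        seed = self.random_state if self.random_state is not None else 0
        part = leidenalg.find_partition(
            g, leidenalg.RBConfigurationVertexPartition,
            weights="weight", resolution_parameter=self.resolution, seed=int(seed))
        self.graph_labels_ = np.asarray(part.membership)
        # align graph labels onto hierarchical labels; keep agreements
        mapping = _match_labels(self.hier_labels_, self.graph_labels_)
        mapped = np.array([mapping.get(int(l), DISCARDED) for l in self.graph_labels_])
        consensus = np.where(mapped == self.hier_labels_, self.hier_labels_, DISCARDED)
        self.labels_ = consensus
        self.n_discarded_ = int(np.sum(consensus == DISCARDED))
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def consensus_cluster(features, n_clusters: int = 6, n_neighbors: int = 20,
                      resolution: float = 1.5, seed: int | None = 0,
                      reference=None, n_shuffles: int = 10_000,
                      embed: bool = False, perplexity: float = 30.0) -> dict:
    """Run the full typing pipeline on a normalized feature matrix.

    Returns a dict with per-cell labels from both methods and the consensus,
    PC scores, optionally a 2-D embedding, and — when a ``reference``
    labeling is given — accuracy and shuffle-chance percentages.
    """
    cc = ConsensusClusterer(n_clusters=n_clusters, n_neighbors=n_neighbors,
                            resolution=resolution, random_state=seed).fit(features)
    out = {
        "hier_labels": cc.hier_labels_,
        "graph_labels": cc.graph_labels_,
        "consensus_labels": cc.labels_,
        "pc_scores": cc.pc_scores_,
        "n_discarded": cc.n_discarded_,
    }
    if embed:
        out["embedding"] = embed_2d(cc.pc_scores_, perplexity=perplexity, seed=seed)
    if reference is not None:
        acc = clustering_accuracy(cc.labels_, np.asarray(reference),
                                  n_shuffles=n_shuffles, seed=seed)
        out.update(acc)
    return out


def clustering_accuracy(labels, reference, n_shuffles: int = 10_000,
                        seed: int | None = 0) -> dict:
    """Percent agreement with a reference labeling, after optimal matching.

    Cells labeled ``DISCARDED`` are excluded.  The chance level is the mean
    agreement of ``n_shuffles`` random permutations of the labels, evaluated
    under the label correspondence fitted on the unshuffled data (so that for
    independent labelings the expectation is the closed form Σᵢ pᵢ qᵢ).
    """
    labels = np.asarray(labels)
    reference = np.asarray(reference)
    keep = labels != DISCARDED
    labels, reference = labels[keep], reference[keep]
    if len(labels) == 0:
        raise InsufficientDataError("no overlapping (non-discarded) cells")
    mapping = _match_labels(reference, labels)
    mapped = np.array([mapping.get(int(l), -999) for l in labels])
    accuracy = 100.0 * np.mean(mapped == reference)
    rng = np.random.default_rng(seed)
    n = len(labels)
    hits = 0
    for _ in range(n_shuffles):
        hits += int(np.sum(mapped[rng.permutation(n)] == reference))
    chance = 100.0 * hits / (n_shuffles * n)
    return {"accuracy_pct": float(accuracy), "chance_pct": float(chance),
            "n_cells": int(n)}


def embed_2d(pc_scores, perplexity: float = 30.0, seed: int | None = 0) -> np.ndarray:
    """2-D t-SNE of the PC scores (reporting only; deterministic per seed).

    Falls back to the first two PCs with a warning when there are too few
    points for the requested perplexity.
    """
    pcs = np.asarray(pc_scores, dtype=float)
    n = pcs.shape[0]
    if n <= perplexity * 3:
        warnings.warn(f"{n} points is too few for perplexity {perplexity}; "
                      "falling back to PC1/PC2")
        if pcs.shape[1] < 2:
            return np.column_stack([pcs[:, 0], np.zeros(n)])
        return pcs[:, :2].copy()
    ts = TSNE(n_components=2, perplexity=perplexity, init="pca",
              random_state=seed if seed is not None else 0)
    return ts.fit_transform(pcs)


# ---------------------------------------------------------------------------
# soma morphometry
# ---------------------------------------------------------------------------


def soma_scores(X, Y, Ymajor, Yminor) -> pd.DataFrame:
    """Elliptical and triangular soma scores with the joint shape rule.

    E = X/Y (two perpendicular major axes), T = Ymajor/Yminor (25% and 75%
    perpendicular axes).  Classes: T ≥ 1.2 → triangular; otherwise E ≥ 1.8 →
    elongated, E < 1.8 → round.
    """
    X, Y = np.atleast_1d(np.asarray(X, float)), np.atleast_1d(np.asarray(Y, float))
    Ymaj = np.atleast_1d(np.asarray(Ymajor, float))
    Ymin = np.atleast_1d(np.asarray(Yminor, float))
    if np.any(X <= 0) or np.any(Y <= 0) or np.any(Ymaj <= 0) or np.any(Ymin <= 0):
        raise ValueError("soma axes must be positive lengths")
    e = X / Y
    t = Ymaj / Ymin
    shape = np.where(t >= 1.2, "triangular", np.where(e >= 1.8, "elongated", "round"))
    return pd.DataFrame({"E": e, "T": t, "shape": shape})
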