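"""Per-cell QC, log-normalization, HVG selection, embedding and graph clustering.

Mirrors a Seurat-style workflow: per-sample QC thresholds flag low-quality
cells, clusters containing more than a configurable fraction (default 33%) of
low-quality cells are excluded wholesale, expression is library-size
log-normalized, highly variable genes are ranked by a variance-stabilizing
transformation, and cells are clustered with Leiden communities on a
shared-nearest-neighbor graph built in PC space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.base import BaseEstimator, ClusterMixin, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "QCThresholds",
    "compute_qc",
    "apply_thresholds",
    "drop_low_quality_clusters",
    "LogNormalizer",
    "log_normalize",
    "VSTGeneSelector",
    "select_hvg",
    "scale_genes",
    "VariancePCA",
    "pca_embed",
    "SNNLeidenClustering",
    "knn_leiden",
]


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

@dataclass
class QCThresholds:
    """Per-sample QC bounds; cells violating any bound are flagged low-quality."""

    min_umi: float = 500.0
    max_umi: float = np.inf
    min_genes: float = 200.0
    max_genes: float = np.inf
    max_mito: float = 0.15
    cluster_lowq_cutoff: float = 0.33

    def __post_init__(self):
        if self.min_umi > self.max_umi or self.min_genes > self.max_genes:
            raise ValueError("min bound exceeds max bound")


def compute_qc(counts, mito_flags) -> pd.DataFrame:
    """Per-cell totals, detected genes and mitochondrial fraction.

    All-zero cells get mito fraction 0 and are marked ``degenerate``.  The
    ``low_quality`` flag is left unset; :func:`apply_thresholds` sets it.
    """
    counts = sp.csr_matrix(counts)
    if counts.nnz and (counts.data < 0).any():
        raise ValueError("counts must be non-negative")
    mito_flags = np.asarray(mito_flags, dtype=bool)
    if mito_flags.shape[0] != counts.shape[1]:
        raise ValueError("mito flag length does not match gene count")
    total = np.asarray(counts.sum(axis=1)).ravel()
    n_genes = np.asarray((counts > 0).sum(axis=1)).ravel()
    mito = np.asarray(counts[:, mito_flags].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, mito / np.maximum(total, 1), 0.0)
    return pd.DataFrame({
        "total_counts": total,
        "n_genes": n_genes,
        "mito_frac": frac,
        "degenerate": total == 0,
        "low_quality": False,
    })


def apply_thresholds(qc: pd.DataFrame, t: QCThresholds) -> pd.DataFrame:
    """Set ``low_quality`` true iff any bound is violated (degenerate cells too)."""
    out = qc.copy()
    bad = (
        (out["total_counts"] < t.min_umi)
        | (out["total_counts"] > t.max_umi)
        | (out["n_genes"] < t.min_genes)
        | (out["n_genes"] > t.max_genes)
        | (out["mito_frac"] > t.max_mito)
        | out["degenerate"]
    )
    out["low_quality"] = bad.to_numpy()
    return out


def drop_low_quality_clusters(labels, low_quality, cutoff: float = 0.33) -> np.ndarray:
    """Boolean mask of retained cells.

    A cluster whose low-quality fraction exceeds ``cutoff`` (strictly) is
    removed entirely; flagged cells in retained clusters are removed
    individually.
    """
    labels = np.asarray(labels)
    lowq = np.asarray(low_quality, dtype=bool)
    if labels.shape != lowq.shape:
        raise ValueError("labels and flags not aligned")
    keep = ~lowq
    for lab in np.unique(labels):
        mask = labels == lab
        if lowq[mask].mean() > cutoff:
            keep[mask] = False
    return keep


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

class LogNormalizer(BaseEstimator, TransformerMixin):
    """Library-size normalization to ``scale`` counts per cell, then log1p.

    A pure row operation: entry -> ln(1 + count * scale / cell_total).
    Stateless (fit is a no-op kept for pipeline compatibility).
    """

    def __init__(self, scale: float = 1e4):
        self.scale = scale

    def fit(self, X, y=None):
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = sp.csr_matrix(X, dtype=float)
        totals = np.asarray(X.sum(axis=1)).ravel()
        if (totals == 0).any():
            bad = np.flatnonzero(totals == 0)
            raise ValueError(f"cells with zero total counts: rows {bad[:10].tolist()}")
        out = X.copy()
        row_scale = self.scale / totals
        out.data = np.log1p(out.data * np.repeat(row_scale, np.diff(out.indptr)))
        return out


def log_normalize(counts, scale: float = 1e4) -> sp.csr_matrix:
    return LogNormalizer(scale=scale).fit(counts).transform(counts)


# ---------------------------------------------------------------------------
# HVG (variance-stabilizing transformation ranking)
# ---------------------------------------------------------------------------

class VSTGeneSelector(BaseEstimator, TransformerMixin):
    """Rank genes by standardized variance, Seurat-VST style.

    A degree-2 polynomial is fit to log10(variance) vs log10(mean) of the raw
    counts; each gene's counts are standardized by the predicted sd with
    clipping at sqrt(n_cells); genes are ranked by the variance of the
    standardized values.  Deterministic.
    """

    def __init__(self, n_top: int = 2000):
        self.n_top = n_top

    def fit(self, X, y=None):
        X = sp.csr_matrix(X, dtype=float)
        n, g = X.shape
        if self.n_top > g:
            raise ValueError(f"n_top={self.n_top} exceeds number of genes ({g})")
        mean = np.asarray(X.mean(axis=0)).ravel()
        sq = np.asarray(X.multiply(X).mean(axis=0)).ravel()
        var = (sq - mean**2) * n / max(n - 1, 1)
        var[var < 1e-12] = 0.0  # guard the catastrophic-cancellation dust

        fit_mask = (var > 0) & (mean > 0)
        std_var = np.zeros(g)
        if fit_mask.sum() < 3:
            # too few variable genes for a curve fit: rank by raw variance
            std_var = var.copy()
        elif fit_mask.sum() >= 3:
            coef = np.polyfit(np.log10(mean[fit_mask]), np.log10(var[fit_mask]), 2)
            pred_sd = np.sqrt(10 ** np.polyval(coef, np.log10(np.maximum(mean, 1e-12))))
            clip = np.sqrt(n)
            Xc = X.tocsc()
            for j in np.flatnonzero(fit_mask):
                col = Xc.getcol(j)
                vals = col.toarray().ravel()
                z = np.clip((vals - mean[j]) / pred_sd[j], -clip, clip)
                std_var[j] = z.var(ddof=1)
        self.standardized_variance_ = std_var
        order = np.argsort(-std_var, kind="stable")
        self.ranks_ = order
        self.support_ = np.zeros(g, dtype=bool)
        self.support_[order[: self.n_top]] = True
        return self

    def transform(self, X):
        return X[:, self.support_]


def select_hvg(norm, counts, n_top: int = 2000) -> np.ndarray:
    """Indices of the ``n_top`` most variable genes (ranking uses raw counts)."""
    sel = VSTGeneSelector(n_top=n_top).fit(counts)
    return np.flatnonzero(sel.support_)


def scale_genes(X, max_value: float = 10.0) -> np.ndarray:
    """Zero-mean unit-variance gene scaling with clipping (dense output)."""
    X = np.asarray(X.todense() if sp.issparse(X) else X, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    return np.clip((X - mu) / sd, -max_value, max_value)


# ---------------------------------------------------------------------------
# PCA with an explained-variance cutoff
# ---------------------------------------------------------------------------

class VariancePCA(BaseEstimator, TransformerMixin):
    """Keep principal components individually explaining >= ``variance_fraction``.

    At least two components are always returned.  Component signs are fixed so
    the largest-magnitude loading is positive, for determinism.
    """

    def __init__(self, variance_fraction: float = 0.015, max_components: int = 50):
        self.variance_fraction = variance_fraction
        self.max_components = max_components

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.shape[0] < 2:
            raise ValueError("need at least 2 cells")
        n_comp = min(self.max_components, X.shape[0] - 1, X.shape[1])
        pca = PCA(n_components=n_comp, svd_solver="full")
        pca.fit(X)
        ratios = pca.explained_variance_ratio_
        keep = max(2, int((ratios >= self.variance_fraction).sum()))
        keep = min(keep, n_comp)
        comps = pca.components_[:keep].copy()
        signs = np.sign(comps[np.arange(keep), np.abs(comps).argmax(axis=1)])
        signs[signs == 0] = 1.0
        self.components_ = comps * signs[:, None]
        self.mean_ = pca.mean_
        self.explained_variance_ratio_ = ratios[:keep]
        self.n_components_ = keep
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return (X - self.mean_) @ self.components_.T


def pca_embed(X_scaled, variance_fraction: float = 0.015) -> np.ndarray:
    return VariancePCA(variance_fraction=variance_fraction).fit(X_scaled).transform(X_scaled)


# ---------------------------------------------------------------------------
# SNN graph + Leiden
# ---------------------------------------------------------------------------

def _snn_graph(embedding: np.ndarray, k: int, prune: float = 1.0 / 15.0) -> ig.Graph:
    """Shared-nearest-neighbor graph: Jaccard overlap of k-NN sets, pruned.

    Any pair of cells whose neighbor sets (including self) overlap with
    Jaccard >= ``prune`` is connected, not only kNN pairs, matching the
    community-standard SNN construction.
    """
    n = embedding.shape[0]
    nn = NearestNeighbors(n_neighbors=k + 1).fit(embedding)
    _, ind = nn.kneighbors(embedding)
    rows = np.repeat(np.arange(n), k + 1)
    adj = sp.csr_matrix(
        (np.ones((k + 1) * n), (rows, ind.ravel())), shape=(n, n))
    adj = ((adj + sp.eye(n)) > 0).astype(float)  # ensure self-membership
    set_size = np.asarray(adj.sum(axis=1)).ravel()
    shared = (adj @ adj.T).tocoo()
    union = set_size[shared.row] + set_size[shared.col] - shared.data
    jaccard = shared.data / union
    mask = (jaccard >= prune) & (shared.row < shared.col)
    g = ig.Graph(n=n, edges=list(zip(shared.row[mask], shared.col[mask])))
    g.es["weight"] = jaccard[mask].tolist()
    return g


class SNNLeidenClustering(BaseEstimator, ClusterMixin):
    """Leiden communities on a shared-nearest-neighbor graph in embedding space."""

    def __init__(self, k: int = 15, resolution: float = 1.0, seed: int = 0):
        self.k = k
        self.resolution = resolution
        self.seed = seed

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if self.k >= X.shape[0]:
            raise ValueError(f"k={self.k} must be < number of cells ({X.shape[0]})")
        graph = _snn_graph(X, self.k)
        part = leidenalg.find_partition(
            graph,
            leidenalg.RBConfigurationVertexPartition,
            weights="weight",
            resolution_parameter=self.resolution,
            seed=self.seed,
            n_iterations=-1,
        )
        self.labels_ = np.asarray(part.membership)
        self.modularity_ = graph.modularity(part.membership, weights="weight")
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def knn_leiden(embedding, k: int = 15, resolution: float = 1.0, seed: int = 0) -> np.ndarray:
    return SNNLeidenClustering(k=k, resolution=resolution, seed=seed).fit_predict(embedding)
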