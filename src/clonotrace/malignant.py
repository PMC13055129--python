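"""Cluster-level cell typing and malignant-cell identification.

Clusters are annotated by the highest mean expression of canonical marker
sets.  Malignant (lymphoma) clusters are called by two joint criteria:
a high fraction of cells expressing the malignancy marker (CCND1-like) above
a log-expression threshold, and immunoglobulin light-chain restriction — a
large absolute difference between the cluster-mean kappa and lambda
log-expression, reflecting the clonal exclusion of one chain.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = ["score_cell_types", "call_malignant"]


def _cluster_mean(norm, mask, gene_idx) -> float:
    sub = norm[mask][:, gene_idx]
    return float(np.asarray(sub.mean(axis=0)).mean()) if sub.shape[0] else np.nan


def score_cell_types(norm, clusters, markers: dict, gene_names) -> dict:
    """Assign each cluster the type with the highest mean marker expression.

    ``markers`` maps type label -> list of marker gene ids.  Ties are broken
    by label order with a warning.
    """
    if not markers:
        raise ValueError("markers must be non-empty")
    gene_names = list(gene_names)
    name_to_idx = {g: i for i, g in enumerate(gene_names)}
    marker_idx = {}
    for label, genes in markers.items():
        missing = [g for g in genes if g not in name_to_idx]
        if missing:
            raise ValueError(f"marker genes absent for {label!r}: {missing}")
        marker_idx[label] = np.array([name_to_idx[g] for g in genes], dtype=int)

    clusters = np.asarray(clusters)
    norm = sp.csr_matrix(norm)
    out = {}
    for cl in np.unique(clusters):
        mask = clusters == cl
        if not mask.any():
            raise ValueError(f"empty cluster {cl!r}")
        scores = {label: _cluster_mean(norm, mask, gi) for label, gi in marker_idx.items()}
        best = max(scores.values())
        winners = [lab for lab in markers if scores[lab] == best]
        if len(winners) > 1:
            warnings.warn(
                f"cluster {cl!r}: marker-score tie among {winners}; "
                f"taking {winners[0]!r} by label order"
            )
        out[cl] = winners[0]
    return out


def call_malignant(
    norm,
    clusters,
    gene_names,
    marker_gene: str,
    kappa_gene: str,
    lambda_gene: str,
    expr_threshold: float = 1.0,
    fraction_threshold: float = 0.5,
    restriction_threshold: float = 1.0,
) -> pd.DataFrame:
    """Per-cluster malignancy calls.

    ``marker_fraction`` is the share of cluster cells with marker
    log-expression above ``expr_threshold``; ``restriction_index`` is the
    absolute difference of cluster-mean kappa vs lambda log1p expression
    (symmetric in the two chains).  A cluster is malignant iff both the
    fraction and the restriction index reach their thresholds.
    """
    gene_names = list(gene_names)
    trio = {marker_gene, kappa_gene, lambda_gene}
    if len(trio) != 3:
        raise ValueError("marker, kappa and lambda genes must be distinct")
    missing = trio - set(gene_names)
    if missing:
        raise ValueError(f"genes absent from matrix: {sorted(missing)}")
    name_to_idx = {g: i for i, g in enumerate(gene_names)}
    mi, ki, li = (name_to_idx[g] for g in (marker_gene, kappa_gene, lambda_gene))

    norm = sp.csr_matrix(norm)
    clusters = np.asarray(clusters)
    marker_col = np.asarray(norm[:, mi].todense()).ravel()
    kappa_col = np.asarray(norm[:, ki].todense()).ravel()
    lambda_col = np.asarray(norm[:, li].todense()).ravel()

    rows = []
    for cl in np.unique(clusters):
        mask = clusters == cl
        frac = float((marker_col[mask] > expr_threshold).mean())
        restriction = float(abs(kappa_col[mask].mean() - lambda_col[mask].mean()))
        rows.append((
            cl, frac, restriction,
            frac >= fraction_threshold and restriction >= restriction_threshold,
        ))
    return pd.DataFrame(rows, columns=[
        "cluster", "marker_fraction", "restriction_index", "malignant",
    ])
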