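"""Subclone detection and longitudinal dynamics.

Malignant cells from diagnosis and relapse are clustered jointly on their
smoothed CNV residual profiles, so subclone labels are shared across
timepoints.  Subclones are then classified by the change in their sample
proportions: a subclone whose relapse share is at least ``theta`` times its
diagnostic share (continuity-corrected) is therapy-resistant (expanded or
persistent), otherwise therapy-sensitive (depleted or reduced); subclones
absent at diagnosis are relapse-specific.  Minor diagnostic subclones are
linked to dominant relapse clones by the Jaccard overlap of
direction-concordant non-diploid 100 kb bins, and inferred subclone segments
can be validated against bulk segment calls by direction concordance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.base import BaseEstimator, ClusterMixin

from .preprocess import SNNLeidenClustering, VariancePCA

__all__ = [
    "SubcloneClusterer",
    "cluster_subclones",
    "composition_table",
    "classify_resistance",
    "PrecursorMatch",
    "match_precursor",
    "validate_subclone_cnv",
]


class SubcloneClusterer(BaseEstimator, ClusterMixin):
    """Joint CNV-profile clustering of diagnosis + relapse malignant cells.

    method "leiden": SNN-Leiden on a PCA embedding of the smoothed residuals.
    method "ward": Ward-linkage hierarchical clustering cut at ``n_clusters``.

    Clusters smaller than ``min_cluster_size`` (outlier cells whose graph
    edges were pruned) are dissolved into the nearest large cluster by
    centroid distance, and labels are renumbered by decreasing cluster size.
    """

    def __init__(
        self,
        method: str = "leiden",
        k: int = 15,
        resolution: float = 1.0,
        n_clusters: int = 4,
        n_pcs: int = 20,
        min_cluster_size: int = 10,
        seed: int = 0,
    ):
        self.method = method
        self.k = k
        self.resolution = resolution
        self.n_clusters = n_clusters
        self.n_pcs = n_pcs
        self.min_cluster_size = min_cluster_size
        self.seed = seed

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.shape[0] < 2:
            raise ValueError("need at least 2 cells")
        if not np.isfinite(X).all():
            raise ValueError("profiles must be finite")
        if self.method == "leiden":
            pca = VariancePCA(variance_fraction=0.0, max_components=self.n_pcs).fit(X)
            emb = pca.transform(X)[:, : self.n_pcs]
            labels = SNNLeidenClustering(
                k=min(self.k, X.shape[0] - 1),
                resolution=self.resolution,
                seed=self.seed,
            ).fit_predict(emb)
        elif self.method == "ward":
            Z = linkage(X, method="ward")
            labels = fcluster(Z, t=self.n_clusters, criterion="maxclust") - 1
        else:
            raise ValueError(f"unknown method {self.method!r}")
        self.labels_ = self._dissolve_small(X, np.asarray(labels))
        return self

    def _dissolve_small(self, X: np.ndarray, labels: np.ndarray) -> np.ndarray:
        uniq, counts = np.unique(labels, return_counts=True)
        min_size = min(self.min_cluster_size, X.shape[0])
        big = uniq[counts >= min_size]
        if big.size == 0:
            big = uniq[np.argsort(-counts)][:1]
        centroids = np.stack([X[labels == u].mean(axis=0) for u in big])
        out = labels.copy()
        for u in uniq:
            if u in big:
                continue
            for i in np.flatnonzero(labels == u):
                d = ((centroids - X[i]) ** 2).sum(axis=1)
                out[i] = big[int(d.argmin())]
        # renumber by decreasing size for stable, readable labels
        uniq, counts = np.unique(out, return_counts=True)
        order = uniq[np.argsort(-counts, kind="stable")]
        remap = {u: i for i, u in enumerate(order)}
        return np.array([remap[u] for u in out])

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def cluster_subclones(
    profiles,
    method: str = "leiden",
    k: int = 15,
    resolution: float = 1.0,
    n_clusters: int = 4,
    seed: int = 0,
) -> np.ndarray:
    return SubcloneClusterer(
        method=method, k=k, resolution=resolution, n_clusters=n_clusters, seed=seed
    ).fit_predict(profiles)


# ---------------------------------------------------------------------------
# composition and resistance
# ---------------------------------------------------------------------------

def composition_table(assignment, samples) -> pd.DataFrame:
    """Cross-tabulated counts and per-sample proportions.

    Returns a long table (subclone, sample, count, proportion); absent
    combinations appear with count 0.
    """
    df = pd.DataFrame({"subclone": np.asarray(assignment), "sample": np.asarray(samples)})
    counts = df.groupby(["subclone", "sample"], sort=True).size().unstack(fill_value=0)
    props = counts.div(counts.sum(axis=0), axis=1)
    long = counts.stack().rename("count").to_frame()
    long["proportion"] = props.stack()
    return long.reset_index()


def classify_resistance(
    composition: pd.DataFrame,
    timepoints: dict,
    theta: float = 0.8,
    eps: float | None = None,
    combine_relapse: str = "mean",
) -> pd.DataFrame:
    """Label subclones resistant / sensitive / relapse_specific.

    ``timepoints`` maps sample id -> "diagnosis" | "relapse".  With multiple
    relapse compartments, proportions are averaged by default
    (``combine_relapse="mean"``); with ``"any"`` a subclone is resistant if it
    is resistant in any compartment.  r = (p_rel + eps)/(p_dg + eps);
    resistant iff r >= theta.  eps defaults to half a cell's worth of the
    diagnostic sample.
    """
    dg_samples = [s for s, t in timepoints.items() if t == "diagnosis"]
    rel_samples = [s for s, t in timepoints.items() if t == "relapse"]
    if len(dg_samples) != 1 or not rel_samples:
        raise ValueError("need exactly one diagnosis and at least one relapse sample")
    dg = dg_samples[0]

    wide_c = composition.pivot(index="subclone", columns="sample", values="count").fillna(0)
    wide_p = composition.pivot(index="subclone", columns="sample", values="proportion").fillna(0)
    n_dg = wide_c[dg].sum()
    if eps is None:
        eps = 1.0 / (2.0 * n_dg)

    rows = []
    for sub in wide_p.index:
        p_dg = float(wide_p.loc[sub, dg])
        rel_props = [float(wide_p.loc[sub, s]) for s in rel_samples]
        if wide_c.loc[sub, dg] == 0:
            label, r = "relapse_specific", np.nan
        else:
            if combine_relapse == "any":
                rs = [(p + eps) / (p_dg + eps) for p in rel_props]
                r = max(rs)
            else:
                p_rel = float(np.mean(rel_props))
                r = (p_rel + eps) / (p_dg + eps)
            label = "resistant" if r >= theta else "sensitive"
        rows.append((sub, p_dg, float(np.mean(rel_props)), r, label))
    return pd.DataFrame(rows, columns=[
        "subclone", "p_diagnosis", "p_relapse", "ratio", "label",
    ])


# ---------------------------------------------------------------------------
# precursor matching
# ---------------------------------------------------------------------------

@dataclass
class PrecursorMatch:
    diagnostic_subclone: str
    best_relapse_subclone: str | None
    score: float
    shared_bins: int
    call: bool


def _jaccard_direction(a: pd.Series, b: pd.Series, tol: float = 0.25) -> tuple:
    """Jaccard of direction-concordant non-diploid bins of two binned profiles.

    A bin is non-diploid when |value - 2| > tol.  Returns (score, n_shared);
    symmetric in its arguments.
    """
    common = a.index.intersection(b.index)
    av = a.loc[common].to_numpy(dtype=float)
    bv = b.loc[common].to_numpy(dtype=float)
    ok = ~(np.isnan(av) | np.isnan(bv))
    av, bv = av[ok], bv[ok]
    da = np.where(np.abs(av - 2) > tol, np.sign(av - 2), 0)
    db = np.where(np.abs(bv - 2) > tol, np.sign(bv - 2), 0)
    union = (da != 0) | (db != 0)
    agree = (da != 0) & (da == db)
    if union.sum() == 0:
        return np.nan, 0
    return float(agree.sum() / union.sum()), int(agree.sum())


def match_precursor(
    diagnostic_profile: pd.Series,
    relapse_profiles: dict,
    min_score: float = 0.5,
    tol: float = 0.25,
) -> PrecursorMatch:
    """Best direction-concordant relapse subclone for one diagnostic subclone.

    Profiles are binned copy-number series on a common genomic grid (see
    ``concordance.bin_segments``).  A fully diploid diagnostic profile yields
    an undefined score and a negative call with a warning.
    """
    diag_nondiploid = (np.abs(diagnostic_profile.dropna() - 2) > tol).sum()
    if diag_nondiploid == 0:
        warnings.warn("diagnostic profile fully diploid; precursor score undefined")
        return PrecursorMatch("diagnostic", None, np.nan, 0, False)
    best, best_score, best_shared = None, -np.inf, 0
    for name, prof in relapse_profiles.items():
        score, shared = _jaccard_direction(diagnostic_profile, prof, tol=tol)
        if not np.isnan(score) and score > best_score:
            best, best_score, best_shared = name, score, shared
    if best is None:
        return PrecursorMatch("diagnostic", None, np.nan, 0, False)
    return PrecursorMatch("diagnostic", best, best_score, best_shared,
                          best_score >= min_score)


# ---------------------------------------------------------------------------
# bulk validation
# ---------------------------------------------------------------------------

def validate_subclone_cnv(
    subclone_segments: pd.DataFrame,
    bulk_segments: pd.DataFrame,
    tol: float = 0.0,
) -> pd.DataFrame:
    """Retain subclone segments concordant in direction with overlapping bulk calls.

    A subclone gain (copy > 2) survives iff it shares at least one bp with a
    bulk segment whose value exceeds 2 + tol; losses symmetrically.  Diploid
    subclone rows are dropped (they are not events).
    """
    kept = []
    for _, seg in subclone_segments.iterrows():
        direction = np.sign(seg["copy_number"] - 2)
        if direction == 0:
            continue
        over = bulk_segments[
            (bulk_segments["chromosome"] == seg["chromosome"])
            & (bulk_segments["start"] <= seg["end"])
            & (bulk_segments["end"] >= seg["start"])
        ]
        bulk_dir = np.sign(np.where(np.abs(over["copy_number"] - 2) > tol,
                                    over["copy_number"] - 2, 0))
        if (bulk_dir == direction).any():
            kept.append(seg)
    if not kept:
        return subclone_segments.iloc[0:0]
    return pd.DataFrame(kept).reset_index(drop=True)
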