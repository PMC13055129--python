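"""Downstream statistics for subclone comparisons.

Wilcoxon rank-sum differential expression with expression-fraction and
fold-change pre-filters, Benjamini-Hochberg correction, preranked gene-set
enrichment (weighted Kolmogorov-Smirnov running sum with a gene-label
permutation null), expression-bin-matched module scoring for cell-cycle
programs, phase assignment, and the per-patient chi-square phase-shift test.

Log fold changes are differences of mean log2(1 + normalized expression);
input matrices hold natural-log log1p values, converted internally.
"""

from __future__ import annotations

import math
import warnings
from functools import lru_cache

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "wilcoxon_de",
    "significant_genes",
    "bh_adjust",
    "exact_ranksum_pvalue",
    "preranked_gsea",
    "gsea_running_sum",
    "module_score",
    "assign_phase",
    "phase_shift_test",
]

LN2 = math.log(2.0)
_MAX_EXACT = 200_000  # largest C(n, nA) enumerated exactly


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------

def exact_ranksum_pvalue(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact rank-sum p by full enumeration (ties via average ranks).

    The null distribution of the group-A rank sum over all assignments of the
    pooled (tied) ranks is built by dynamic programming over doubled ranks
    (average ranks are half-integers); the two-sided p is the null mass at
    least as far from the mean as the observed sum.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    d = np.round(2 * ranks).astype(int)  # doubled ranks are integers
    nA, n = len(x), len(pooled)
    obs = int(d[:nA].sum())

    # dp[k][s] = number of size-k subsets of d with doubled-rank sum s
    max_sum = int(d.sum())
    dp = np.zeros((nA + 1, max_sum + 1), dtype=float)
    dp[0, 0] = 1.0
    for di in d:
        for k in range(min(nA, n), 0, -1):
            dp[k, di:] += dp[k - 1, : max_sum + 1 - di]
    dist = dp[nA]
    total = dist.sum()
    sums = np.arange(max_sum + 1)
    p_le = dist[sums <= obs].sum() / total
    p_ge = dist[sums >= obs].sum() / total
    # standard two-sided convention: twice the smaller one-sided p, capped
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def _ranksum_pvalue(x, y, method: str = "auto") -> float:
    nA, nB = len(x), len(y)
    if method == "auto":
        method = "exact" if math.comb(nA + nB, nA) <= _MAX_EXACT else "asymptotic"
    if method == "exact":
        return exact_ranksum_pvalue(np.asarray(x), np.asarray(y))
    return float(sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue)


def wilcoxon_de(
    norm,
    group_a,
    group_b,
    gene_names=None,
    min_lfc: float = 0.25,
    min_frac: float = 0.10,
    method: str = "auto",
) -> pd.DataFrame:
    """Wilcoxon rank-sum differential expression between two cell groups.

    Only genes with |log2 fold change| >= ``min_lfc`` and detected in at least
    ``min_frac`` of either group are tested; BH correction runs over tested
    genes.  Small groups use exact enumeration of the rank-sum null, larger
    groups the normal approximation with tie correction.
    """
    X = sp.csr_matrix(norm)
    group_a = np.asarray(group_a)
    group_b = np.asarray(group_b)
    ia = np.flatnonzero(group_a) if group_a.dtype == bool else group_a
    ib = np.flatnonzero(group_b) if group_b.dtype == bool else group_b
    if np.intersect1d(ia, ib).size:
        raise ValueError("groups must be disjoint")
    if len(ia) < 3 or len(ib) < 3:
        raise ValueError("each group needs at least 3 cells")

    A = np.asarray(X[ia].todense(), dtype=float)
    B = np.asarray(X[ib].todense(), dtype=float)
    mean_a = A.mean(axis=0) / LN2
    mean_b = B.mean(axis=0) / LN2
    l2fc = mean_a - mean_b
    frac_a = (A > 0).mean(axis=0)
    frac_b = (B > 0).mean(axis=0)
    testable = (np.abs(l2fc) >= min_lfc) & ((frac_a >= min_frac) | (frac_b >= min_frac))

    names = list(gene_names) if gene_names is not None else list(range(X.shape[1]))
    idx = np.flatnonzero(testable)
    pvals = np.array([_ranksum_pvalue(A[:, j], B[:, j], method=method) for j in idx])
    adj = bh_adjust(pvals) if idx.size else np.array([])
    return pd.DataFrame({
        "gene": [names[j] for j in idx],
        "l2fc": l2fc[idx],
        "frac_a": frac_a[idx],
        "frac_b": frac_b[idx],
        "pvalue": pvals,
        "adj_pvalue": adj,
    })


def significant_genes(
    de: pd.DataFrame,
    max_adj_p: float = 0.05,
    min_abs_l2fc: float = 0.8,
    min_frac: float = 0.25,
) -> list:
    """Genes with adj p < cutoff, |log2FC| > cutoff and detection > cutoff
    in the group where the gene is higher."""
    if de.empty:
        return []
    higher_frac = np.where(de["l2fc"] > 0, de["frac_a"], de["frac_b"])
    keep = (
        (de["adj_pvalue"] < max_adj_p)
        & (de["l2fc"].abs() > min_abs_l2fc)
        & (higher_frac > min_frac)
    )
    return de.loc[keep, "gene"].tolist()


# ---------------------------------------------------------------------------
# preranked GSEA
# ---------------------------------------------------------------------------

def gsea_running_sum(scores: np.ndarray, hit_mask: np.ndarray, weight: float = 1.0) -> np.ndarray:
    """Weighted Kolmogorov-Smirnov running sum over a ranked list.

    Hits increment proportionally to |score|**weight (normalized to sum 1);
    misses decrement uniformly by 1/(N - n_hits).
    """
    scores = np.asarray(scores, dtype=float)
    hit_mask = np.asarray(hit_mask, dtype=bool)
    n = scores.size
    nh = int(hit_mask.sum())
    if nh == 0 or nh == n:
        raise ValueError("gene set must be a proper subset of the ranked list")
    w = np.abs(scores) ** weight
    hit_total = w[hit_mask].sum()
    steps = np.where(hit_mask, w / hit_total if hit_total > 0 else 1.0 / nh,
                     -1.0 / (n - nh))
    return np.cumsum(steps)


def _enrichment_score(scores, hit_mask, weight):
    rs = gsea_running_sum(scores, hit_mask, weight)
    i = int(np.abs(rs).argmax())
    return float(rs[i])


def preranked_gsea(
    ranked: pd.Series,
    gene_sets: dict,
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
    min_size: int = 5,
) -> pd.DataFrame:
    """Preranked GSEA over a gene -> log2FC Series.

    ES is the signed extremum of the weighted KS running sum; the null is
    gene-label permutation within the ranked list; NES divides ES by the mean
    |null ES| of matching sign; p = (1 + #{null at least as extreme in
    magnitude}) / (n_perm + 1); BH across sets.  Sets smaller than
    ``min_size`` after intersecting with the ranked universe are skipped with
    a note.
    """
    if ranked.index.duplicated().any():
        raise ValueError("ranked list contains duplicate genes")
    ranked = ranked.sort_values(ascending=False)
    scores = ranked.to_numpy(dtype=float)
    universe = list(ranked.index)
    pos = {g: i for i, g in enumerate(universe)}
    n = len(universe)
    rng = np.random.default_rng(seed)

    rows = []
    for name, genes in gene_sets.items():
        members = sorted({g for g in genes if g in pos})
        if len(members) < min_size:
            warnings.warn(f"gene set {name!r} smaller than {min_size} after intersection; skipped")
            continue
        hit = np.zeros(n, dtype=bool)
        hit[[pos[g] for g in members]] = True
        es = _enrichment_score(scores, hit, weight)

        null = np.empty(n_perm)
        nh = len(members)
        for b in range(n_perm):
            perm_hit = np.zeros(n, dtype=bool)
            perm_hit[rng.choice(n, size=nh, replace=False)] = True
            null[b] = _enrichment_score(scores, perm_hit, weight)
        more_extreme = int((np.abs(null) >= abs(es)).sum())
        p = (1 + more_extreme) / (n_perm + 1)
        same = null[np.sign(null) == np.sign(es)] if es != 0 else null
        denom = np.abs(same).mean() if same.size else np.nan
        nes = es / denom if denom and not np.isnan(denom) else np.nan
        rows.append((name, len(members), es, nes, p))

    out = pd.DataFrame(rows, columns=["set", "size", "es", "nes", "pvalue"])
    if not out.empty:
        out["adj_pvalue"] = bh_adjust(out["pvalue"].to_numpy())
    else:
        out["adj_pvalue"] = []
    return out


# ---------------------------------------------------------------------------
# module scores and cell-cycle phases
# ---------------------------------------------------------------------------

def module_score(
    norm,
    gene_set,
    gene_names,
    n_bins: int = 24,
    n_control: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Per-cell score: mean set expression minus bin-matched control expression.

    Genes are binned into ``n_bins`` equal-size bins by average expression;
    for every set gene, ``n_control`` control genes are drawn (without
    replacement) from the non-set genes of its bin, and the control mean runs
    over the concatenated draws.  Deterministic for a fixed seed.
    """
    gene_names = list(gene_names)
    if len(gene_names) < n_bins:
        raise ValueError("need at least n_bins genes")
    pos = {g: i for i, g in enumerate(gene_names)}
    set_idx = [pos[g] for g in gene_set if g in pos]
    if not set_idx:
        raise ValueError("gene set empty after intersection with the matrix")

    X = np.asarray(sp.csr_matrix(norm).todense(), dtype=float)
    avg = X.mean(axis=0)
    order = np.argsort(avg, kind="stable")
    bin_of = np.empty(len(gene_names), dtype=int)
    bin_of[order] = (np.arange(len(gene_names)) * n_bins) // len(gene_names)
    bins = {b: np.flatnonzero(bin_of == b) for b in range(n_bins)}

    rng = np.random.default_rng(seed)
    in_set = np.zeros(len(gene_names), dtype=bool)
    in_set[set_idx] = True
    control_idx = []
    for gi in set_idx:
        members = bins[bin_of[gi]]
        candidates = members[~in_set[members]]
        if candidates.size == 0:  # bin holds only set genes; fall back
            candidates = members
        take = min(n_control, candidates.size)
        control_idx.extend(rng.choice(candidates, size=take, replace=False))
    return X[:, set_idx].mean(axis=1) - X[:, control_idx].mean(axis=1)


def assign_phase(s_scores, g2m_scores) -> np.ndarray:
    """G1 when both scores <= 0; otherwise the larger score's phase (ties -> S)."""
    s = np.asarray(s_scores, dtype=float)
    g = np.asarray(g2m_scores, dtype=float)
    if s.shape != g.shape:
        raise ValueError("score vectors not aligned")
    phases = np.where((s <= 0) & (g <= 0), "G1", np.where(s >= g, "S", "G2M"))
    ties = (s == g) & (s > 0)
    if ties.any():
        warnings.warn(f"{int(ties.sum())} cells with exactly tied positive scores assigned S")
    return phases


def phase_shift_test(tables: dict) -> pd.DataFrame:
    """Per-patient chi-square test of phase distribution, diagnosis vs relapse.

    Each value of ``tables`` is a 2 x n_phases contingency array (rows:
    timepoints, columns: phases).  Phases absent from both timepoints are
    collapsed with a warning (reducing the degrees of freedom); BH correction
    runs across patients.
    """
    rows = []
    for patient, tab in tables.items():
        tab = np.asarray(tab, dtype=float)
        if tab.shape[0] != 2:
            raise ValueError("contingency table must have 2 rows (timepoints)")
        present = tab.sum(axis=0) > 0
        if not present.all():
            warnings.warn(f"{patient}: phases absent in both samples collapsed")
            tab = tab[:, present]
        stat, p, dof, _ = sps.chi2_contingency(tab, correction=False)
        rows.append((patient, float(stat), int(dof), float(p)))
    out = pd.DataFrame(rows, columns=["patient", "statistic", "dof", "pvalue"])
    out["adj_pvalue"] = bh_adjust(out["pvalue"].to_numpy())
    return out
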