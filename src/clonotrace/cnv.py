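"""Expression-based copy-number inference with a six-state HMM.

The procedure follows the standard expression-CNV recipe: genes below a mean
expression cutoff are dropped; each cell's log-normalized expression is turned
into a residual against the mean of diploid reference cells and clipped;
residuals are smoothed along genomic gene order with a triangular
moving-average window that never crosses a chromosome boundary; per-cell
medians are removed so the diploid baseline sits at zero; and a six-state
hidden Markov model over copy numbers {0,...,5+} with Gaussian emissions and a
strongly persistent uniform-switch transition matrix decodes each
cell-chromosome residual track into integer copy states by Viterbi.

Emission means use a dosage-attenuation calibration: on the log1p-normalized
scale the residual of a gene with reference linear expression e under copy
number c is ln((1 + (c/2) e) / (1 + e)) ~= kappa * ln(c/2) with
kappa = e / (1 + e), so state means are kappa_bar * ln(max(c, eps0)/2) with
kappa_bar averaged over kept genes.  The shared emission sd is estimated from
the smoothed residuals of the reference cells, floored to stay proper.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.base import BaseEstimator

__all__ = [
    "HMMParams",
    "filter_genes_by_mean",
    "reference_residuals",
    "smoothing_matrix",
    "smooth_chromosome",
    "center_cells",
    "estimate_hmm_params",
    "viterbi_states",
    "viterbi_states_matrix",
    "states_to_segments",
    "subclone_mean_profile",
    "CNVCaller",
]

N_STATES = 6


# ---------------------------------------------------------------------------
# HMM parameters
# ---------------------------------------------------------------------------

@dataclass
class HMMParams:
    """Six-state copy-number HMM: Gaussian emissions, uniform-switch transitions."""

    means: np.ndarray                 # per-state emission mean, monotone increasing
    sigma: float                      # shared emission sd
    transition: float = 1e-6          # probability of switching to each other state
    initial: np.ndarray = field(default_factory=lambda: np.full(N_STATES, 1.0 / N_STATES))

    def __post_init__(self):
        self.means = np.asarray(self.means, dtype=float)
        self.initial = np.asarray(self.initial, dtype=float)
        if self.means.shape != (N_STATES,):
            raise ValueError("means must have 6 entries")
        if not np.all(np.diff(self.means) > 0):
            raise ValueError("emission means must be strictly increasing in state")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if not (0 < self.transition < 1.0 / (N_STATES - 1)):
            raise ValueError("transition must lie in (0, 1/5)")
        if abs(self.initial.sum() - 1) > 1e-9 or (self.initial < 0).any():
            raise ValueError("initial distribution must be a probability vector")

    @property
    def log_transition_matrix(self) -> np.ndarray:
        stay = 1.0 - (N_STATES - 1) * self.transition
        T = np.full((N_STATES, N_STATES), self.transition)
        np.fill_diagonal(T, stay)
        return np.log(T)


def estimate_hmm_params(
    smoothed_ref: np.ndarray,
    kappa: float,
    eps0: float = 0.05,
    transition: float = 1e-6,
    sigma_floor: float = 0.05,
) -> HMMParams:
    """Calibrated emission means and reference-derived sd.

    ``kappa`` is the mean dosage-attenuation factor e/(1+e) over kept genes;
    ``smoothed_ref`` are the centered smoothed residuals of reference cells.
    """
    states = np.arange(N_STATES, dtype=float)
    means = kappa * np.log(np.maximum(states, eps0) / 2.0)
    sigma = max(float(np.std(smoothed_ref)), sigma_floor)
    return HMMParams(means=means, sigma=sigma, transition=transition)


# ---------------------------------------------------------------------------
# residual pipeline
# ---------------------------------------------------------------------------

def filter_genes_by_mean(norm, reference_cells, min_mean: float = 0.1) -> np.ndarray:
    """Indices of genes whose mean expression over all analyzed cells is >= cutoff."""
    reference_cells = np.asarray(reference_cells)
    if reference_cells.dtype == bool:
        if not reference_cells.any():
            raise ValueError("reference cell set is empty")
    elif reference_cells.size == 0:
        raise ValueError("reference cell set is empty")
    mean = np.asarray(sp.csr_matrix(norm).mean(axis=0)).ravel()
    keep = np.flatnonzero(mean >= min_mean)
    if keep.size == 0:
        raise ValueError("no genes pass the mean-expression cutoff")
    return keep


def reference_residuals(norm, reference_mask, clip: float = 3.0) -> np.ndarray:
    """Expression minus per-gene reference mean, clipped to [-clip, clip]."""
    X = np.asarray(sp.csr_matrix(norm).todense(), dtype=float)
    reference_mask = np.asarray(reference_mask, dtype=bool)
    if not reference_mask.any():
        raise ValueError("reference cell set is empty")
    ref_mean = X[reference_mask].mean(axis=0)
    return np.clip(X - ref_mean, -clip, clip)


def smoothing_matrix(n: int, window: int) -> np.ndarray:
    """Row-stochastic triangular moving-average operator for one chromosome.

    Row i holds weights (h+1-|j-i|) for |j-i| <= h, truncated at the
    chromosome edges and renormalized to sum 1.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    h = (window - 1) // 2
    W = np.zeros((n, n))
    for i in range(n):
        lo, hi = max(0, i - h), min(n - 1, i + h)
        j = np.arange(lo, hi + 1)
        w = (h + 1 - np.abs(j - i)).astype(float)
        w /= w.sum()
        w[i - lo] += 1.0 - w.sum()  # pin the row sum to exactly 1.0
        W[i, j] = w
    return W


def smooth_chromosome(residuals: np.ndarray, chromosomes, window: int = 101) -> np.ndarray:
    """Triangular within-chromosome smoothing of cells x genes residuals.

    ``chromosomes`` gives the per-gene chromosome label in genome order;
    smoothing never mixes chromosomes.
    """
    residuals = np.asarray(residuals, dtype=float)
    chromosomes = np.asarray(chromosomes)
    out = np.empty_like(residuals)
    for chrom in pd.unique(chromosomes):
        cols = np.flatnonzero(chromosomes == chrom)
        W = smoothing_matrix(cols.size, window)
        out[:, cols] = residuals[:, cols] @ W.T
    return out


def center_cells(smoothed: np.ndarray) -> np.ndarray:
    """Subtract each cell's median so the per-cell median of the output is 0."""
    smoothed = np.asarray(smoothed, dtype=float)
    return smoothed - np.median(smoothed, axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# Viterbi decoding
# ---------------------------------------------------------------------------

# tie-break preference: state 2 first, then lower states
_TIE_ORDER = np.array([2, 0, 1, 3, 4, 5])
_TIE_RANK = np.argsort(_TIE_ORDER)  # rank of each state in preference order


def _tie_argmax(scores: np.ndarray) -> np.ndarray:
    """Argmax over the last axis, ties resolved toward state 2 then lower."""
    pref = scores[..., _TIE_ORDER]
    best = pref.argmax(axis=-1)  # argmax takes the first (most preferred) on ties
    return _TIE_ORDER[best]


def viterbi_states_matrix(obs: np.ndarray, params: HMMParams) -> np.ndarray:
    """Viterbi paths for many cells at once over one chromosome.

    ``obs`` is (n_cells, L); returns (n_cells, L) integer states.  Log-space
    throughout; ties broken toward state 2 then the lower state.
    """
    obs = np.atleast_2d(np.asarray(obs, dtype=float))
    n, L = obs.shape
    if L == 0:
        raise ValueError("empty observation segment")
    logT = params.log_transition_matrix
    mu = params.means
    s2 = 2.0 * params.sigma**2
    const = -0.5 * np.log(np.pi * s2)

    def loglik(col):
        return const - (col[:, None] - mu[None, :]) ** 2 / s2

    delta = np.log(params.initial)[None, :] + loglik(obs[:, 0])
    back = np.empty((L, n, N_STATES), dtype=np.int8)
    for t in range(1, L):
        cand = delta[:, :, None] + logT[None, :, :]  # (n, from, to)
        cand_pref = cand[:, _TIE_ORDER, :]
        arg_pref = cand_pref.argmax(axis=1)
        back[t] = _TIE_ORDER[arg_pref]
        delta = np.take_along_axis(cand, back[t][:, None, :].astype(np.int64), axis=1)[:, 0, :]
        delta = delta + loglik(obs[:, t])

    path = np.empty((n, L), dtype=np.int8)
    path[:, L - 1] = _tie_argmax(delta)
    for t in range(L - 1, 0, -1):
        path[:, t - 1] = back[t][np.arange(n), path[:, t]]
    return path


def viterbi_states(obs, params: HMMParams) -> np.ndarray:
    """Maximum a posteriori state path for one cell-chromosome residual track."""
    obs = np.asarray(obs, dtype=float)
    if obs.ndim != 1:
        raise ValueError("viterbi_states expects a single 1-D segment")
    return viterbi_states_matrix(obs[None, :], params)[0].astype(int)


# ---------------------------------------------------------------------------
# segments and profiles
# ---------------------------------------------------------------------------

def states_to_segments(
    states: np.ndarray,
    gene_coords: pd.DataFrame,
    group_labels,
    events_only: bool = False,
) -> pd.DataFrame:
    """Majority-state segment table per cell group.

    Per group and gene the majority copy state across cells is taken (ties
    resolved toward state 2 then lower); consecutive same-state genes on a
    chromosome merge into one segment spanning [first gene start, last gene
    end].  With ``events_only`` the diploid (state 2) runs are omitted.
    """
    states = np.asarray(states)
    group_labels = np.asarray(group_labels)
    if states.shape[0] != group_labels.shape[0]:
        raise ValueError("group labels must cover all cells")
    chrom = gene_coords["chromosome"].to_numpy()
    gstart = gene_coords["start"].to_numpy()
    gend = gene_coords["end"].to_numpy()

    rows = []
    for grp in pd.unique(group_labels):
        mask = group_labels == grp
        if not mask.any():
            raise ValueError(f"empty group {grp!r}")
        sub = states[mask]
        counts = np.stack([(sub == s).sum(axis=0) for s in range(N_STATES)], axis=1)
        maj = _tie_argmax(counts)
        start_i = 0
        for i in range(1, len(maj) + 1):
            if i == len(maj) or maj[i] != maj[start_i] or chrom[i] != chrom[start_i]:
                state = int(maj[start_i])
                if not (events_only and state == 2):
                    rows.append((grp, chrom[start_i], int(gstart[start_i]),
                                 int(gend[i - 1]), state))
                start_i = i
    return pd.DataFrame(rows, columns=["group", "chromosome", "start", "end", "copy_number"])


def subclone_mean_profile(values: np.ndarray, labels) -> pd.DataFrame:
    """Arithmetic mean per subclone per gene (rows: subclones)."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    out = {}
    for grp in pd.unique(labels):
        mask = labels == grp
        if not mask.any():
            raise ValueError(f"empty subclone {grp!r}")
        out[grp] = values[mask].mean(axis=0)
    return pd.DataFrame.from_dict(out, orient="index")


# ---------------------------------------------------------------------------
# estimator facade
# ---------------------------------------------------------------------------

class CNVCaller(BaseEstimator):
    """Reference-normalized smoothed residuals and Viterbi copy states.

    fit(norm, reference_mask) learns the gene filter, reference means, the
    dosage-attenuation factor and HMM parameters; transform(norm) returns
    centered smoothed residuals over kept genes; predict(norm) returns the
    integer copy-state matrix.
    """

    def __init__(
        self,
        gene_chromosomes=None,
        min_mean: float = 0.1,
        clip: float = 3.0,
        window: int = 101,
        transition: float = 1e-6,
        eps0: float = 0.05,
        sigma_floor: float = 0.05,
    ):
        self.gene_chromosomes = gene_chromosomes
        self.min_mean = min_mean
        self.clip = clip
        self.window = window
        self.transition = transition
        self.eps0 = eps0
        self.sigma_floor = sigma_floor

    def fit(self, norm, reference_mask):
        norm = sp.csr_matrix(norm)
        reference_mask = np.asarray(reference_mask, dtype=bool)
        self.kept_genes_ = filter_genes_by_mean(norm, reference_mask, self.min_mean)
        kept = norm[:, self.kept_genes_]
        ref = kept[reference_mask]
        self.reference_mean_ = np.asarray(ref.mean(axis=0)).ravel()
        # dosage attenuation: mean of e/(1+e) with e the reference linear mean
        lin = np.expm1(np.asarray(ref.todense(), dtype=float)).mean(axis=0)
        self.kappa_ = float(np.mean(lin / (1.0 + lin)))
        self.chromosomes_ = np.asarray(self.gene_chromosomes)[self.kept_genes_]
        smoothed_ref = self._residual_pipeline(ref)
        self.hmm_params_ = estimate_hmm_params(
            smoothed_ref, self.kappa_, eps0=self.eps0,
            transition=self.transition, sigma_floor=self.sigma_floor,
        )
        return self

    def _residual_pipeline(self, kept_norm) -> np.ndarray:
        X = np.asarray(sp.csr_matrix(kept_norm).todense(), dtype=float)
        resid = np.clip(X - self.reference_mean_, -self.clip, self.clip)
        smoothed = smooth_chromosome(resid, self.chromosomes_, self.window)
        return center_cells(smoothed)

    def transform(self, norm) -> np.ndarray:
        return self._residual_pipeline(sp.csr_matrix(norm)[:, self.kept_genes_])

    def predict(self, norm) -> np.ndarray:
        smoothed = self.transform(norm)
        return self.predict_from_smoothed(smoothed)

    def predict_from_smoothed(self, smoothed: np.ndarray) -> np.ndarray:
        states = np.empty(smoothed.shape, dtype=np.int8)
        for chrom in pd.unique(self.chromosomes_):
            cols = np.flatnonzero(self.chromosomes_ == chrom)
            states[:, cols] = viterbi_states_matrix(smoothed[:, cols], self.hmm_params_)
        return states
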