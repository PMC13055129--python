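"""Copy-number profile concordance: fixed-width binning and Spearman rank correlation.

Segment tables (1-based closed genomic intervals with real copy numbers) are
tiled onto fixed-width autosomal bins; a bin overlapped by several segments
takes the unweighted mean of their copy numbers (a bp-weighted mean is
available behind a flag).  Profiles are normalized by subtracting the diploid
baseline (copy number 2) and compared by Spearman's rank correlation over
bins covered in both profiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "bin_segments",
    "normalize_baseline",
    "ConcordanceResult",
    "spearman_concordance",
]

log = logging.getLogger(__name__)

_SEX_CHROMS = {"chrX", "chrY", "X", "Y"}


def bin_segments(
    segments: pd.DataFrame,
    chrom_lengths: dict,
    bin_size: int = 100_000,
    weighted: bool = False,
) -> pd.Series:
    """Bin a segment table onto a fixed autosomal grid.

    Returns a Series indexed by (chromosome, bin_start) holding the mean copy
    number of all segments overlapping each bin — unweighted across distinct
    segments by default, bp-weighted with ``weighted=True``.  Bins with no
    overlapping segment are NaN.  Sex chromosomes are dropped with a log note.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    dropped = set(segments["chromosome"]) & _SEX_CHROMS
    if dropped:
        log.info("dropping sex chromosomes from binning: %s", sorted(dropped))

    index = []
    for chrom, length in chrom_lengths.items():
        if chrom in _SEX_CHROMS:
            continue
        n_bins = (int(length) + bin_size - 1) // bin_size
        index.extend((chrom, b * bin_size + 1) for b in range(n_bins))
    sums = pd.Series(0.0, index=pd.MultiIndex.from_tuples(index, names=["chromosome", "bin_start"]))
    wsum = sums.copy()

    for _, row in segments.iterrows():
        chrom = row["chromosome"]
        if chrom in _SEX_CHROMS or chrom not in chrom_lengths:
            continue
        s, e, c = int(row["start"]), int(row["end"]), float(row["copy_number"])
        b0, b1 = (s - 1) // bin_size, (e - 1) // bin_size
        for b in range(b0, b1 + 1):
            bs = b * bin_size + 1
            be = bs + bin_size - 1
            if weighted:
                w = min(e, be) - max(s, bs) + 1
            else:
                w = 1.0
            sums.loc[(chrom, bs)] += w * c
            wsum.loc[(chrom, bs)] += w

    out = sums / wsum.where(wsum > 0)
    out.name = "copy_number"
    out.attrs["bin_size"] = bin_size
    return out


def normalize_baseline(profile: pd.Series) -> pd.Series:
    """Subtract the diploid baseline (copy number 2); missing bins stay missing."""
    out = profile - 2.0
    out.attrs.update(profile.attrs)
    return out


@dataclass
class ConcordanceResult:
    rho: float
    pvalue: float
    n_bins: int
    defined: bool
    profile_a: pd.Series = None
    profile_b: pd.Series = None


def spearman_concordance(a: pd.Series, b: pd.Series) -> ConcordanceResult:
    """Spearman rho over bins present in both profiles (average-rank ties).

    Undefined (``defined=False``, rho NaN) when fewer than 3 shared bins or
    either profile is constant on the shared support.
    """
    common = a.index.intersection(b.index)
    av = a.loc[common].to_numpy(dtype=float)
    bv = b.loc[common].to_numpy(dtype=float)
    ok = ~(np.isnan(av) | np.isnan(bv))
    av, bv = av[ok], bv[ok]
    n = int(ok.sum())
    if n < 3 or np.ptp(av) == 0 or np.ptp(bv) == 0:
        return ConcordanceResult(np.nan, np.nan, n, False, a, b)
    rho, p = stats.spearmanr(av, bv)
    return ConcordanceResult(float(rho), float(p), n, True, a, b)
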