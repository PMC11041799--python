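"""Islands of divergence and interval-overlap enrichment.

A genomic island of divergence is called where two lines of evidence
coincide: window differentiation F_ST >= 0.2 and a reciprocal-monophyly
(species-tree) topology signal.  Enrichment of one interval set inside
another is tested with Fisher's exact test on a base-pair (optionally
binned) 2x2 contingency table against the genome size, with tail sums
evaluated in log space so counts of order 1e8 are exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import IntervalSet, merge_intervals

__all__ = ["call_islands", "merge_intervals", "fisher_overlap",
           "FisherOverlapResult"]


def call_islands(fst_table: pd.DataFrame, species_tree_intervals: IntervalSet,
                 fst_min: float = 0.2, merge_gap: int = 0,
                 min_length: int = 0) -> IntervalSet:
    """Intersect high-F_ST windows with species-tree (reciprocal monophyly)
    intervals; overlapping or book-ended results merge into maximal islands
    (``merge_gap`` bridges residual sub-window gaps; islands shorter than
    ``min_length`` bp are discarded).
    """
    if fst_table.empty or len(species_tree_intervals) == 0:
        return IntervalSet()
    hi = fst_table[fst_table["fst"] >= fst_min]
    if hi.empty:
        return IntervalSet()
    fst_set = IntervalSet.from_records(
        zip(hi["chrom"], hi["start"], hi["end"])
    ).merge()
    out = fst_set.intersect(species_tree_intervals).merge(gap=merge_gap)
    if min_length > 0:
        out = IntervalSet(out.df[(out.df["end"] - out.df["start"]) >= min_length])
    return out


@dataclass
class FisherOverlapResult:
    """2x2 base-level contingency of two interval sets over a genome.

    Counts are in ``unit``-sized bins: (in A and B, A only, B only,
    neither); they sum to the binned genome size.
    """

    n_both: int
    n_a_only: int
    n_b_only: int
    n_neither: int
    odds_ratio: float
    p_left: float
    p_right: float
    p_two_tail: float
    genome_bins: int
    unit: int


def _bin_mask(iset: IntervalSet, genome_sizes: dict, unit: int):
    masks = {}
    for chrom, length in genome_sizes.items():
        n_bins = int(np.ceil(length / unit))
        masks[chrom] = np.zeros(n_bins, dtype=bool)
    for chrom, start, end in iset.merge():
        if chrom not in genome_sizes:
            raise ValueError(f"interval on chromosome {chrom} absent from genome")
        if end > genome_sizes[chrom]:
            raise ValueError(f"interval beyond end of {chrom}: {start}-{end}")
        masks[chrom][start // unit : (end - 1) // unit + 1] = True
    return masks


def fisher_overlap(set_a: IntervalSet, set_b: IntervalSet, genome_sizes: dict,
                   unit: int = 1000) -> FisherOverlapResult:
    """Fisher's exact test for base-level overlap of two interval sets.

    The genome is cut into ``unit``-bp bins (a bin counts as covered when
    any of its bases is); the hypergeometric left/right tails and the
    two-tail sum of tables no more probable than the observed one are
    computed from log-pmfs.
    """
    ma = _bin_mask(set_a, genome_sizes, unit)
    mb = _bin_mask(set_b, genome_sizes, unit)
    n_both = n_a = n_b = total = 0
    for chrom in genome_sizes:
        a, b = ma[chrom], mb[chrom]
        n_both += int((a & b).sum())
        n_a += int(a.sum())
        n_b += int(b.sum())
        total += len(a)
    n_a_only = n_a - n_both
    n_b_only = n_b - n_both
    n_neither = total - n_a - n_b_only

    # hypergeometric: draw |A| bins out of `total`, `n_b` of which are in B
    hg = stats.hypergeom(total, n_b, n_a)
    k = n_both
    p_right = float(np.exp(hg.logsf(k - 1))) if k > 0 else 1.0
    p_left = float(np.exp(hg.logcdf(k)))
    lo, hi = int(hg.support()[0]), int(hg.support()[1])
    support = np.arange(lo, hi + 1)
    logpmf = hg.logpmf(support)
    obs = hg.logpmf(k)
    p_two = float(np.exp(logpmf[logpmf <= obs + 1e-7]).sum())
    p_two = min(p_two, 1.0)

    if n_a_only == 0 or n_b_only == 0:
        odds = np.inf if n_both > 0 else np.nan
    else:
        odds = n_both * n_neither / (n_a_only * n_b_only)
    return FisherOverlapResult(n_both, n_a_only, n_b_only, n_neither, float(odds),
                               min(p_left, 1.0), min(p_right, 1.0), p_two,
                               total, unit)
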