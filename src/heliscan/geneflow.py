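"""f4 statistics with weighted block jackknife, Mantel test, Nm conversion.

The f4 statistic for populations (A, B; C, D) is the genome-wide mean of the
per-site product ``(p_A - p_B) * (p_C - p_D)`` of allele-frequency
differences.  It is zero under a tree ((A,B),(C,D)) without gene flow; a
systematic departure indicates allele sharing violating the tree.  Standard
errors come from a weighted delete-one block jackknife over contiguous
genomic blocks (default 500 kb), with block weights equal to their usable
site counts (Busing-style delete-m_j formulae).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform

from .windows import GenotypeMatrix


@dataclass
class F4Result:
    f4: float
    se: float
    z: float
    n_blocks: int
    block_bp: int
    n_sites: int


def weighted_block_jackknife_se(values: np.ndarray, block_ids: np.ndarray):
    """Weighted delete-one-block jackknife SE of the mean of ``values``.

    Blocks are weighted by their element counts; returns (SE, n_blocks).
    """
    values = np.asarray(values, dtype=float)
    blocks = np.unique(block_ids)
    g = len(blocks)
    if g < 2:
        return np.nan, g
    n = len(values)
    total = values.sum()
    theta = total / n
    m = np.array([(block_ids == b).sum() for b in blocks], dtype=float)
    block_sums = np.array([values[block_ids == b].sum() for b in blocks])
    theta_del = (total - block_sums) / (n - m)  # delete-block estimates
    h = n / m
    tau = h * theta - (h - 1.0) * theta_del
    theta_j = g * theta - ((1.0 - m / n) * theta_del).sum()
    var = ((tau - theta_j) ** 2 / (h - 1.0)).sum() / g
    return float(np.sqrt(var)), g


def f4(gm: GenotypeMatrix, a: str, b: str, c: str, d: str,
       block_bp: int = 500_000) -> F4Result:
    """f4(A, B; C, D) with weighted block-jackknife standard error.

    Uses biallelic sites where every population has at least one genotyped
    individual.  Antisymmetric in (A, B) and in (C, D).
    """
    freqs, ns = {}, {}
    for pop in (a, b, c, d):
        freqs[pop], ns[pop] = gm.allele_freq(pop)
        if (ns[pop] == 0).all():
            raise ValueError(f"population {pop} has no data at any site")
    use = np.ones(gm.n_sites, dtype=bool)
    for pop in (a, b, c, d):
        use &= ns[pop] >= 2
    if not use.any():
        raise ValueError("no sites usable in all four populations")
    contrib = ((freqs[a] - freqs[b]) * (freqs[c] - freqs[d]))[use]
    chrom = gm.chrom[use]
    pos0 = gm.pos[use] - 1
    block_ids = np.array([f"{c_}:{p // block_bp}" for c_, p in zip(chrom, pos0)])
    est = float(contrib.mean())
    se, n_blocks = weighted_block_jackknife_se(contrib, block_ids)
    z = est / se if se and np.isfinite(se) and se > 0 else np.nan
    return F4Result(est, se, z, n_blocks, block_bp, int(use.sum()))


def mantel(x, y, n_perm: int = 9999, seed: int = 0):
    """Mantel test between two distance structures.

    ``x`` and ``y`` are square symmetric distance matrices or condensed
    (upper-triangle) vectors over the same subjects.  Returns
    ``(r, P)`` where r is the Pearson correlation of the off-diagonal
    entries and P the two-sided permutation p-value
    ``(1 + #{|r*| >= |r|}) / (n_perm + 1)``, permuting subject labels of one
    matrix (not raw entries).
    """
    from skbio.stats.distance import DistanceMatrix, mantel as _sk_mantel

    def as_square(v):
        v = np.asarray(v, dtype=float)
        return squareform(v) if v.ndim == 1 else v

    xs, ys = as_square(x), as_square(y)
    if xs.shape != ys.shape or xs.shape[0] < 3:
        raise ValueError("need matching distance structures over >= 3 subjects")
    for m, name in ((xs, "x"), (ys, "y")):
        if np.std(squareform(m, checks=False)) == 0:
            raise ValueError(f"zero variance in {name}; r undefined")
    r, p, _ = _sk_mantel(DistanceMatrix(xs), DistanceMatrix(ys),
                         method="pearson", permutations=n_perm,
                         alternative="two-sided", seed=seed)
    return float(r), float(p)


def nm_convert(m_ab: float, theta_b: float) -> float:
    """Effective migrants per generation: Nm_AB = M_AB * theta_B / 4."""
    if m_ab < 0 or theta_b < 0:
        raise ValueError("inputs must be non-negative")
    return m_ab * theta_b / 4.0
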