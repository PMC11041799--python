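"""Genotype I/O, site filtering, window iteration and window diversity stats.

The central container is :class:`GenotypeMatrix`: biallelic diploid genotypes
coded 0/1/2 (copies of the alternate allele, -1 for missing) with 1-based
positions and a sample-to-population map.  Window outputs use BED-style
0-based half-open coordinates; the 1-based convention exists only at the VCF
boundary.

Differentiation is Hudson-style: per window,
``F_ST = 1 - mean(pi_A, pi_B) / pi_pooled``, with each pi formed as a ratio
of per-site sums over the window's usable sites and an ``n/(n-1)``
small-sample heterozygosity correction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1


@dataclass
class GenotypeMatrix:
    """Biallelic diploid genotypes at SNPs, with population labels.

    Attributes
    ----------
    chrom : array of str, per site
    pos : array of int, 1-based positions, strictly increasing per chromosome
    geno : (n_sites, n_samples) int8 array of alt-allele counts; -1 missing
    samples : list of sample names
    popmap : dict sample -> population
    """

    chrom: np.ndarray
    pos: np.ndarray
    geno: np.ndarray
    samples: list
    popmap: dict

    def __post_init__(self):
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.geno = np.asarray(self.geno, dtype=np.int8)
        missing = [s for s in self.samples if s not in self.popmap]
        if missing:
            raise ValueError(f"samples missing from popmap: {missing}")
        for c in pd.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def populations(self) -> list:
        seen = {}
        for s in self.samples:
            seen.setdefault(self.popmap[s], None)
        return list(seen)

    def pop_indices(self, pop: str) -> np.ndarray:
        idx = np.array(
            [i for i, s in enumerate(self.samples) if self.popmap[s] == pop], dtype=int
        )
        if idx.size == 0:
            raise KeyError(f"unknown or empty population: {pop}")
        return idx

    def take_sites(self, mask) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        return GenotypeMatrix(
            self.chrom[mask], self.pos[mask], self.geno[mask], list(self.samples),
            dict(self.popmap),
        )

    def take_samples(self, names) -> "GenotypeMatrix":
        idx = [self.samples.index(n) for n in names]
        return GenotypeMatrix(
            self.chrom, self.pos, self.geno[:, idx], list(names),
            {n: self.popmap[n] for n in names},
        )

    def allele_freq(self, pop: str):
        """Alt-allele frequency and allele-copy count per site for one pop."""
        sub = self.geno[:, self.pop_indices(pop)]
        called = sub != MISSING
        n = 2 * called.sum(axis=1)
        alt = np.where(called, sub, 0).sum(axis=1)
        with np.errstate(invalid="ignore"):
            p = np.where(n > 0, alt / np.maximum(n, 1), np.nan)
        return p, n


def read_popmap(path) -> dict:
    popmap = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            sample, pop = line.split("\t")[:2]
            popmap[sample] = pop
    return popmap


def read_genotypes(vcf_path, popmap_path) -> GenotypeMatrix:
    """Load a VCF + popmap TSV into a :class:`GenotypeMatrix`.

    Multiallelic records are dropped (a count is logged).  ``./.`` genotypes
    become missing.  Every VCF sample must appear in the popmap.
    """
    from cyvcf2 import VCF

    popmap = read_popmap(popmap_path)
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    absent = [s for s in samples if s not in popmap]
    if absent:
        raise ValueError(f"VCF sample(s) absent from popmap: {absent}")

    chroms, poss, rows = [], [], []
    n_dropped = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_dropped += 1
            continue
        # gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        gt = rec.gt_types
        codes = np.full(len(samples), MISSING, dtype=np.int8)
        codes[gt == 0] = 0
        codes[gt == 1] = 1
        codes[gt == 3] = 2
        chroms.append(rec.CHROM)
        poss.append(rec.POS)
        rows.append(codes)
    if n_dropped:
        logger.info("dropped %d non-biallelic records", n_dropped)
    geno = (
        np.array(rows, dtype=np.int8)
        if rows
        else np.zeros((0, len(samples)), dtype=np.int8)
    )
    return GenotypeMatrix(np.array(chroms, dtype=object), np.array(poss), geno,
                          samples, popmap)


def filter_sites(gm: GenotypeMatrix, min_per_pop: int = 3,
                 drop_missing_samples: bool = False) -> GenotypeMatrix:
    """Keep sites genotyped in enough individuals of every population.

    A site is retained when every population has at least
    ``min(min_per_pop, population size)`` genotyped individuals.  With
    ``drop_missing_samples`` individuals with > 50% missing data are removed
    first.
    """
    if gm.n_sites == 0:
        return gm
    if drop_missing_samples:
        frac_missing = (gm.geno == MISSING).mean(axis=0)
        keep = [s for s, f in zip(gm.samples, frac_missing) if f <= 0.5]
        gm = gm.take_samples(keep)
    mask = np.ones(gm.n_sites, dtype=bool)
    for pop in gm.populations:
        idx = gm.pop_indices(pop)
        need = min(min_per_pop, idx.size)
        called = (gm.geno[:, idx] != MISSING).sum(axis=1)
        mask &= called >= need
    return gm.take_sites(mask)


def iter_windows(gm: GenotypeMatrix, mode: str, size: int, step: int):
    """Yield ``(chrom, start, end, site_index_array)`` windows (0-based, half-open).

    ``coordinate`` mode tiles each chromosome with ``[k*step, k*step + size)``
    windows out to the last genotyped site (trailing partial windows are
    emitted).  ``snp_count`` mode emits windows of exactly ``size`` retained
    SNPs advancing ``step`` SNPs; a trailing partial SNP window is dropped.
    """
    if size <= 0 or step <= 0:
        raise ValueError("size and step must be positive")
    if mode not in ("coordinate", "snp_count"):
        raise ValueError(f"unknown window mode: {mode}")
    if mode == "snp_count" and step > size:
        warnings.warn("step > size in snp_count mode leaves gaps between windows")

    for chrom in pd.unique(gm.chrom):
        idx = np.flatnonzero(gm.chrom == chrom)
        pos0 = gm.pos[idx] - 1  # 0-based
        if mode == "coordinate":
            last = pos0[-1] if len(pos0) else 0
            start = 0
            while start <= last:
                end = start + size
                in_win = idx[(pos0 >= start) & (pos0 < end)]
                yield chrom, start, end, in_win
                start += step
        else:
            k = 0
            while k + size <= len(idx):
                in_win = idx[k : k + size]
                s = int(gm.pos[in_win[0]] - 1)
                e = int(gm.pos[in_win[-1]])
                yield chrom, s, e, in_win
                k += step


def _per_site_pi(p: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Unbiased per-site heterozygosity 2*p*q*n/(n-1) on n allele copies."""
    with np.errstate(divide="ignore", invalid="ignore"):
        return 2.0 * p * (1.0 - p) * n / (n - 1.0)


def window_diversity(gm: GenotypeMatrix, site_idx, popA: str, popB: str):
    """Within/pooled diversity and d_xy for one window.

    Sites with fewer than 2 allele copies in either population are excluded.
    Returns ``(pi_A, pi_B, pi_pooled, d_xy, n_sites_used)``; NaNs when no
    site is usable.
    """
    site_idx = np.asarray(site_idx, dtype=int)
    if site_idx.size == 0:
        return np.nan, np.nan, np.nan, np.nan, 0
    sub = gm.take_sites(site_idx)
    pA, nA = sub.allele_freq(popA)
    pB, nB = sub.allele_freq(popB)
    idx_pool = np.concatenate([sub.pop_indices(popA), sub.pop_indices(popB)])
    pooled = sub.geno[:, idx_pool]
    called = pooled != MISSING
    nP = 2 * called.sum(axis=1)
    altP = np.where(called, pooled, 0).sum(axis=1)
    with np.errstate(invalid="ignore"):
        pP = np.where(nP > 0, altP / np.maximum(nP, 1), np.nan)

    use = (nA >= 2) & (nB >= 2)
    if not use.any():
        return np.nan, np.nan, np.nan, np.nan, 0
    piA = _per_site_pi(pA[use], nA[use])
    piB = _per_site_pi(pB[use], nB[use])
    piP = _per_site_pi(pP[use], nP[use])
    dxy = pA[use] * (1 - pB[use]) + pB[use] * (1 - pA[use])
    k = int(use.sum())
    return float(piA.mean()), float(piB.mean()), float(piP.mean()), float(dxy.mean()), k


def window_fst(pi_A: float, pi_B: float, pi_pooled: float) -> float:
    """Hudson-style window F_ST = 1 - mean(pi_A, pi_B)/pi_pooled.

    Returns NaN (undefined) when the pooled diversity is zero or any input
    is missing.
    """
    if any(np.isnan(x) for x in (pi_A, pi_B, pi_pooled)) or pi_pooled == 0:
        return np.nan
    return 1.0 - ((pi_A + pi_B) / 2.0) / pi_pooled


def fst_scan(gm: GenotypeMatrix, popA: str, popB: str, size: int = 25_000,
             step: int = 5_000, min_fraction: float = 0.10,
             min_sites: int = 1, min_per_pop: int = 3,
             prefiltered: bool = False) -> pd.DataFrame:
    """Sliding-window F_ST scan between two populations.

    Windows with fewer than ``min_fraction * size`` usable sites (or fewer
    than ``min_sites``) are omitted.  ``min_fraction`` follows the all-sites
    convention (genotyped sites per window bp); for SNP-only matrices set it
    to 0 and use ``min_sites``.  Output columns: chrom, start, end, n_sites,
    pi_A, pi_B, pi_pooled, dxy, fst; sorted by chromosome then start.
    """
    for pop in (popA, popB):
        gm.pop_indices(pop)  # raises for unknown populations
    if not prefiltered:
        gm = filter_sites(gm, min_per_pop=min_per_pop)
    rows = []
    for chrom, start, end, idx in iter_windows(gm, "coordinate", size, step):
        piA, piB, piP, dxy, k = window_diversity(gm, idx, popA, popB)
        if k < max(min_sites, min_fraction * size):
            continue
        rows.append((chrom, start, end, k, piA, piB, piP, dxy,
                     window_fst(piA, piB, piP)))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_sites", "pi_A",
                                     "pi_B", "pi_pooled", "dxy", "fst"])
    return df.sort_values(["chrom", "start"]).reset_index(drop=True)
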