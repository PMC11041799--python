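"""Species-diagnostic SNPs, per-individual ancestry scores and het tracts.

Diagnostic (ancestry-informative) SNPs are biallelic sites with a large
allele-frequency difference between two reference panels (default >= 0.8),
thinned so consecutive retained SNPs are at least 10 kb apart.  Each
individual's genotype at a diagnostic SNP maps to an ancestry score of 0
(homozygous species-E), 1 (homozygous species-P) or 0.5 (heterozygous);
long runs of heterozygous scores are the footprint of recent hybridization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import IntervalSet
from .windows import MISSING, GenotypeMatrix


@dataclass
class DiagnosticSNPSet:
    """Retained ancestry-informative SNPs.

    ``df`` columns: chrom, pos (1-based), freq_E, freq_P (alt-allele
    frequencies in the two panels), p_is_alt (True when the alternate allele
    is the species-P allele).
    """

    df: pd.DataFrame
    pop_e: str
    pop_p: str
    afd_min: float
    spacing_bp: int

    def __len__(self):
        return len(self.df)

    def to_tsv(self, path):
        self.df.to_csv(path, sep="\t", index=False)


def diagnostic_snps(gm: GenotypeMatrix, pop_e: str, pop_p: str,
                    afd_min: float = 0.8, spacing_bp: int = 10_000,
                    min_panel: int = 2) -> DiagnosticSNPSet:
    """Find diagnostic SNPs between two reference panels.

    Sites need >= ``min_panel`` genotyped individuals per panel and
    |freq_P - freq_E| >= ``afd_min``; retained SNPs are thinned greedily
    left-to-right to be >= ``spacing_bp`` apart.
    """
    for pop in (pop_e, pop_p):
        if gm.pop_indices(pop).size == 0:
            raise ValueError(f"empty panel {pop}")
    pE, nE = gm.allele_freq(pop_e)
    pP, nP = gm.allele_freq(pop_p)
    ok = (nE >= 2 * min_panel) & (nP >= 2 * min_panel)
    with np.errstate(invalid="ignore"):
        afd = np.abs(pP - pE)
    ok &= afd >= afd_min

    rows = []
    for chrom in pd.unique(gm.chrom):
        idx = np.flatnonzero((gm.chrom == chrom) & ok)
        last = -np.inf
        for i in idx:
            if gm.pos[i] - last >= spacing_bp:
                rows.append((chrom, int(gm.pos[i]), float(pE[i]), float(pP[i]),
                             bool(pP[i] > pE[i])))
                last = gm.pos[i]
    df = pd.DataFrame(rows, columns=["chrom", "pos", "freq_E", "freq_P", "p_is_alt"])
    return DiagnosticSNPSet(df, pop_e, pop_p, afd_min, spacing_bp)


def ancestry_scores(gm: GenotypeMatrix, dset: DiagnosticSNPSet, individual: str):
    """Per-SNP ancestry scores for one individual.

    Returns a DataFrame (chrom, pos, score) with score 1 for homozygous
    species-P, 0 for homozygous species-E, 0.5 heterozygous, NaN missing.
    """
    if individual not in gm.samples:
        raise KeyError(f"unknown individual {individual}")
    col = gm.samples.index(individual)
    key = pd.MultiIndex.from_arrays([gm.chrom, gm.pos])
    lookup = pd.Series(np.arange(gm.n_sites), index=key)
    site_idx = lookup.loc[list(zip(dset.df["chrom"], dset.df["pos"]))].to_numpy()
    g = gm.geno[site_idx, col].astype(float)
    g[g == MISSING] = np.nan
    score = np.where(dset.df["p_is_alt"].to_numpy(), g / 2.0, 1.0 - g / 2.0)
    return pd.DataFrame({"chrom": dset.df["chrom"], "pos": dset.df["pos"],
                         "score": score})


def profile_summary(scores: pd.DataFrame) -> dict:
    """Mean ancestry and heterozygosity over non-missing scores.

    Flagged undefined (NaNs) when the individual has no scored SNP.
    """
    s = scores["score"].dropna()
    if s.empty:
        return {"mean_ancestry": np.nan, "heterozygosity": np.nan, "n_snps": 0,
                "defined": False}
    return {"mean_ancestry": float(s.mean()),
            "heterozygosity": float((s == 0.5).mean()),
            "n_snps": int(len(s)), "defined": True}


def ancestry_profiles(gm: GenotypeMatrix, dset: DiagnosticSNPSet,
                      individuals=None) -> pd.DataFrame:
    """Profile table (mean ancestry, heterozygosity) for many individuals."""
    individuals = individuals if individuals is not None else gm.samples
    rows = []
    for ind in individuals:
        summ = profile_summary(ancestry_scores(gm, dset, ind))
        summ["individual"] = ind
        rows.append(summ)
    return pd.DataFrame(rows).set_index("individual")


def het_tracts(scores: pd.DataFrame, min_run: int = 20) -> IntervalSet:
    """Maximal runs of >= ``min_run`` consecutive heterozygous diagnostic
    SNPs, as intervals spanning the first to last SNP of the run.

    Missing scores are skipped without breaking a run; homozygous scores
    break runs.
    """
    records = []
    for chrom, sub in scores.groupby("chrom", sort=False):
        run = []
        for pos, score in zip(sub["pos"], sub["score"]):
            if np.isnan(score):
                continue
            if score == 0.5:
                run.append(pos)
            else:
                if len(run) >= min_run:
                    records.append((chrom, run[0] - 1, run[-1]))
                run = []
        if len(run) >= min_run:
            records.append((chrom, run[0] - 1, run[-1]))
    return IntervalSet.from_records(records, label="het_tract")
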