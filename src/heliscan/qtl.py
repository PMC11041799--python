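"""Genetic-map utilities, F2 QTL scanning and trait-coupling randomization tests.

The scan is simplified Haley-Knott interval mapping for an achiasmatic F2:
the maternal gamete carries a whole non-recombinant haplotype per chromosome
while the paternal gamete recombines with Haldane (no-interference) spacing.
Genotype probabilities on a 1-cM grid are computed from the two flanking
markers under this model with a fixed genotyping error rate, and
``LOD = (n/2) * log10(RSS0 / RSS1)`` from a linear model with additive and
dominance coefficients.  Genome-wide significance uses permutation of the
phenotypes; support intervals are 1.5-LOD drops.

Coupling between trait loci (and between loci and introgressed intervals)
is measured as the mean recombination fraction ``c`` to the nearest
neighbour, compared with a null in which QTL peaks are re-drawn uniformly
on the concatenated genetic map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import IntervalSet

MISSING = -1  # genotype codes: 0 = PP, 1 = EP, 2 = EE


# ---------------------------------------------------------------------------
# Map functions
# ---------------------------------------------------------------------------

def haldane_c(d_morgans):
    """Haldane map function: recombination fraction for distance d (Morgans)."""
    d = np.asarray(d_morgans, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be non-negative")
    c = (1.0 - np.exp(-2.0 * d)) / 2.0
    return float(c) if np.isscalar(d_morgans) else c


def haldane_d(c):
    """Inverse Haldane map function: distance (Morgans) for recombination
    fraction c in [0, 0.5)."""
    c_arr = np.asarray(c, dtype=float)
    if np.any(c_arr < 0) or np.any(c_arr >= 0.5):
        raise ValueError("recombination fraction must be in [0, 0.5)")
    d = -np.log(1.0 - 2.0 * c_arr) / 2.0
    return float(d) if np.isscalar(c) else d


@dataclass
class GeneticMarkerMap:
    """Marker map: columns ``marker``, ``chrom``, ``bp``, ``cm``.

    Within each chromosome cM must be non-decreasing with bp.
    """

    df: pd.DataFrame

    def __post_init__(self):
        df = self.df[["marker", "chrom", "bp", "cm"]].copy()
        df = df.sort_values(["chrom", "bp"], kind="stable").reset_index(drop=True)
        for chrom, sub in df.groupby("chrom"):
            if np.any(np.diff(sub["cm"].to_numpy()) < 0):
                raise ValueError(f"cM decreasing with bp on {chrom}")
        self.df = df

    @property
    def chromosomes(self) -> list:
        return list(pd.unique(self.df["chrom"]))

    def chrom_table(self, chrom) -> pd.DataFrame:
        sub = self.df[self.df["chrom"] == chrom]
        if sub.empty:
            raise KeyError(f"unknown chromosome {chrom}")
        return sub

    def cm_span(self, chrom):
        sub = self.chrom_table(chrom)
        return float(sub["cm"].min()), float(sub["cm"].max())

    def to_tsv(self, path):
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path):
        return cls(pd.read_csv(path, sep="\t"))


def interpolate_cM(gmap: GeneticMarkerMap, chrom, bp) -> float:
    """Linear bp -> cM interpolation; positions outside the marker span clamp
    to the terminal marker (with a warning)."""
    sub = gmap.chrom_table(chrom)
    bps = sub["bp"].to_numpy(dtype=float)
    cms = sub["cm"].to_numpy(dtype=float)
    if bp < bps[0] or bp > bps[-1]:
        warnings.warn(f"{chrom}:{bp} outside marker span; clamping to terminal marker")
    return float(np.interp(bp, bps, cms))


# ---------------------------------------------------------------------------
# Cross genotypes
# ---------------------------------------------------------------------------


@dataclass
class CrossGenotypes:
    """Ancestry genotypes of a mapping cross on a genetic map.

    ``geno`` is (n_individuals, n_markers) with codes 0 = PP, 1 = EP,
    2 = EE, -1 missing.  Backcrosses to E must carry no PP genotypes (and
    symmetrically for backcrosses to P).
    """

    ids: list
    family: list
    cross_type: str
    sex: list
    geno: np.ndarray
    marker_map: GeneticMarkerMap
    maternal_hap: np.ndarray | None = None
    paternal_hap: np.ndarray | None = None

    def __post_init__(self):
        self.geno = np.asarray(self.geno, dtype=np.int8)
        if self.geno.shape != (len(self.ids), len(self.marker_map.df)):
            raise ValueError("genotype matrix shape does not match ids x markers")
        if self.cross_type == "bc_e" and np.any(self.geno == 0):
            raise ValueError("backcross to E cannot carry PP genotypes")
        if self.cross_type == "bc_p" and np.any(self.geno == 2):
            raise ValueError("backcross to P cannot carry EE genotypes")

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    def to_tsv(self, path):
        codes = {0: "PP", 1: "EP", 2: "EE", -1: "NA"}
        df = pd.DataFrame(
            [[codes[int(g)] for g in row] for row in self.geno],
            index=self.ids, columns=list(self.marker_map.df["marker"]),
        )
        df.insert(0, "family", self.family)
        df.insert(1, "cross_type", self.cross_type)
        df.insert(2, "sex", self.sex)
        df.to_csv(path, sep="\t", index_label="id")

    @classmethod
    def read_tsv(cls, path, marker_map: GeneticMarkerMap):
        df = pd.read_csv(path, sep="\t", index_col="id")
        codes = {"PP": 0, "EP": 1, "EE": 2, "NA": -1}
        markers = list(marker_map.df["marker"])
        geno = np.array(
            [[codes[str(v)] for v in row] for row in df[markers].to_numpy()],
            dtype=np.int8,
        )
        return cls(list(df.index), list(df["family"]), str(df["cross_type"].iloc[0]),
                   list(df["sex"]), geno, marker_map)


def ancestry_fraction(cross: CrossGenotypes, individual=None):
    """Genome-wide E-ancestry fraction: mean of {EE: 1, EP: 0.5, PP: 0} over
    non-missing markers.  NaN for an all-missing individual (flagged)."""
    geno = cross.geno.astype(float)
    geno[geno == MISSING] = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        frac = np.nanmean(geno / 2.0, axis=1)
    if individual is not None:
        return float(frac[cross.ids.index(individual)])
    return pd.Series(frac, index=cross.ids)


def segregation_filter(cross: CrossGenotypes, p_limit: float = 0.01) -> CrossGenotypes:
    """Drop markers whose genotype counts depart from Mendelian expectation
    (1:2:1 in an F2, 1:1 in a backcross) at chi-square p < ``p_limit``."""
    if cross.cross_type == "f2":
        classes, expected = [0, 1, 2], np.array([0.25, 0.5, 0.25])
    elif cross.cross_type == "bc_e":
        classes, expected = [1, 2], np.array([0.5, 0.5])
    elif cross.cross_type == "bc_p":
        classes, expected = [0, 1], np.array([0.5, 0.5])
    else:
        raise ValueError(f"no segregation expectation for {cross.cross_type}")
    keep = []
    for j in range(cross.geno.shape[1]):
        col = cross.geno[:, j]
        col = col[col != MISSING]
        obs = np.array([(col == c).sum() for c in classes], dtype=float)
        n = obs.sum()
        if n == 0:
            keep.append(False)
            continue
        chi2 = ((obs - n * expected) ** 2 / (n * expected)).sum()
        p = stats.chi2.sf(chi2, df=len(classes) - 1)
        keep.append(p >= p_limit)
    keep = np.asarray(keep)
    new_map = GeneticMarkerMap(cross.marker_map.df[keep])
    return CrossGenotypes(
        cross.ids, cross.family, cross.cross_type, cross.sex,
        cross.geno[:, keep], new_map,
        None if cross.maternal_hap is None else cross.maternal_hap[:, keep],
        None if cross.paternal_hap is None else cross.paternal_hap[:, keep],
    )


# ---------------------------------------------------------------------------
# QTL scan
# ---------------------------------------------------------------------------


@dataclass
class QTLRecord:
    trait: str
    pheno_class: str
    chrom: str
    peak_cm: float
    lod: float
    ci_lo: float
    ci_hi: float

    def __post_init__(self):
        if not (self.ci_lo <= self.peak_cm <= self.ci_hi):
            raise ValueError("credible interval must bracket the peak")
        if self.lod < 0:
            raise ValueError("LOD must be non-negative")


def _obs_likelihood(obs: np.ndarray, error_rate: float) -> np.ndarray:
    """(n, 3) matrix of P(observed marker genotype | true genotype)."""
    lik = np.ones((len(obs), 3))
    called = obs != MISSING
    for true_g in range(3):
        match = obs == true_g
        lik[called, true_g] = np.where(match[called], 1.0 - error_rate,
                                       error_rate / 2.0)
    return lik


def genotype_probabilities(cross: CrossGenotypes, chrom, grid_cm: float = 1.0,
                           error_rate: float = 0.001):
    """F2 genotype probabilities on a cM grid from flanking markers.

    Models achiasmy: the maternal allele is constant per chromosome (prior
    1/2 E), the paternal allele follows a two-state Haldane chain.  Returns
    ``(grid positions, (n, n_grid, 3) probability array)`` with genotype
    order PP, EP, EE.
    """
    sub = cross.marker_map.chrom_table(chrom)
    marker_idx = sub.index.to_numpy()
    cms = sub["cm"].to_numpy(dtype=float)
    lo, hi = cms[0], cms[-1]
    grid = np.arange(lo, hi + 1e-9, grid_cm)
    n = cross.n_individuals
    probs = np.zeros((n, len(grid), 3))

    lik = {j: _obs_likelihood(cross.geno[:, marker_idx[j]], error_rate)
           for j in range(len(cms))}

    for gi, t in enumerate(grid):
        jr = int(np.searchsorted(cms, t, side="left"))
        jl = max(0, min(jr - 1, len(cms) - 1)) if t > cms[0] else 0
        jr = min(jr, len(cms) - 1)
        if jl == jr:  # at a terminal marker
            jr = min(jl + 1, len(cms) - 1)
            jl = max(jr - 1, 0)
        r1 = haldane_c(max(t - cms[jl], 0.0) / 100.0)
        r2 = haldane_c(max(cms[jr] - t, 0.0) / 100.0)
        r12 = haldane_c((cms[jr] - cms[jl]) / 100.0)
        post = np.zeros((n, 3))
        for mat in (0, 1):  # maternal allele: 0 = P, 1 = E
            for pl in (0, 1):
                for pr in (0, 1):
                    # paternal chain L -> R and conditional allele at t
                    p_lr = (1 - r12) if pl == pr else r12
                    w = 0.25 * p_lr  # P(mat) * P(pl) * P(pr | pl)
                    base = w * lik[jl][:, mat + pl] * lik[jr][:, mat + pr]
                    # P(pat_t = e | pl, pr) by Markov bridge
                    num_e = (r1 if pl == 0 else 1 - r1) * (r2 if pr == 0 else 1 - r2)
                    num_p = ((1 - r1) if pl == 0 else r1) * ((1 - r2) if pr == 0 else r2)
                    tot = num_e + num_p
                    pe = num_e / tot
                    post[:, mat + 1] += base * pe
                    post[:, mat + 0] += base * (1 - pe)
        probs[:, gi, :] = post / post.sum(axis=1, keepdims=True)
    return grid, probs


def _lod_matrix(probs: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """LOD scores, shape (n_grid, n_phenotype_columns), by Haley-Knott
    regression of each column of Y on additive + dominance predictors."""
    n, n_grid, _ = probs.shape
    rss0 = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)
    lods = np.zeros((n_grid, Y.shape[1]))
    ones = np.ones((n, 1))
    for gi in range(n_grid):
        a = (probs[:, gi, 2] - probs[:, gi, 0])[:, None]
        d = probs[:, gi, 1][:, None]
        X = np.hstack([ones, a, d])
        Q, _ = np.linalg.qr(X)
        proj = Q.T @ Y
        rss1 = (Y**2).sum(axis=0) - (proj**2).sum(axis=0)
        rss1 = np.maximum(rss1, 1e-300)
        lods[gi] = (n / 2.0) * np.log10(rss0 / rss1)
    return lods


def precompute_genotype_probabilities(cross: CrossGenotypes,
                                      grid_cm: float = 1.0,
                                      error_rate: float = 0.001):
    """Genotype probabilities for every chromosome (reusable across scans of
    different phenotypes on the same cross)."""
    return [(chrom, *genotype_probabilities(cross, chrom, grid_cm, error_rate))
            for chrom in cross.marker_map.chromosomes]


def qtl_scan(cross: CrossGenotypes, phenotype, trait: str = "trait",
             pheno_class: str = "", grid_cm: float = 1.0, n_perm: int = 1000,
             error_rate: float = 0.001, seed: int = 0,
             lod_drop: float = 1.5, genotype_probs=None):
    """Genome scan with permutation threshold.

    Returns ``(lod_curve DataFrame, [QTLRecord], threshold)``.  The
    genome-wide 5% threshold is the 95th percentile of the max LOD over
    ``n_perm`` phenotype permutations; support intervals are ``lod_drop``
    LOD drops from each significant per-chromosome peak.
    ``genotype_probs`` accepts the output of
    :func:`precompute_genotype_probabilities`.
    """
    y = np.asarray(phenotype, dtype=float)
    if y.std() == 0:
        raise ValueError("constant phenotype")
    rng = np.random.default_rng(seed)
    perms = np.column_stack([y] + [rng.permutation(y) for _ in range(n_perm)])

    if genotype_probs is None:
        genotype_probs = precompute_genotype_probabilities(cross, grid_cm,
                                                           error_rate)
    curves = []
    monomorphic = True
    for chrom, grid, probs in genotype_probs:
        if np.ptp(probs[:, :, 2] - probs[:, :, 0]) > 1e-9:
            monomorphic = False
        lods = _lod_matrix(probs, perms)
        curves.append((chrom, grid, lods))
    if monomorphic:
        raise ValueError("genotypes monomorphic at all grid positions")

    max_per_perm = np.max(np.vstack([l for _, _, l in curves]), axis=0)
    threshold = float(np.quantile(max_per_perm[1:], 0.95)) if n_perm else np.inf

    rows, records = [], []
    for chrom, grid, lods in curves:
        obs = lods[:, 0]
        for g, l in zip(grid, obs):
            rows.append((chrom, float(g), float(l)))
        peak = int(np.argmax(obs))
        if obs[peak] >= threshold:
            above = obs >= obs[peak] - lod_drop
            # contiguous run containing the peak
            lo = peak
            while lo > 0 and above[lo - 1]:
                lo -= 1
            hi = peak
            while hi < len(grid) - 1 and above[hi + 1]:
                hi += 1
            records.append(QTLRecord(trait, pheno_class, chrom, float(grid[peak]),
                                     float(obs[peak]), float(grid[lo]),
                                     float(grid[hi])))
    curve = pd.DataFrame(rows, columns=["chrom", "cm", "lod"])
    return curve, records, threshold


def prune_overlapping(qtls, classes=None):
    """Within each phenotypic class, collapse QTLs whose support intervals
    overlap (transitively) to the highest-LOD record.

    Ties break toward the smaller interval, then lower chromosome / cM.
    """
    qtls = list(qtls)
    by_class = {}
    for q in qtls:
        key = q.pheno_class if classes is None else classes[qtls.index(q)]
        by_class.setdefault(key, []).append(q)
    kept = []
    for group in by_class.values():
        group = sorted(group, key=lambda q: (str(q.chrom), q.ci_lo))
        components = []
        for q in group:
            placed = False
            for comp in components:
                if any(q.chrom == o.chrom and q.ci_lo <= o.ci_hi and o.ci_lo <= q.ci_hi
                       for o in comp):
                    comp.append(q)
                    placed = True
                    break
            if not placed:
                components.append([q])
        for comp in components:
            best = min(comp, key=lambda q: (-q.lod, q.ci_hi - q.ci_lo,
                                            str(q.chrom), q.peak_cm))
            kept.append(best)
    return sorted(kept, key=lambda q: (str(q.chrom), q.peak_cm))


# ---------------------------------------------------------------------------
# Coupling statistics
# ---------------------------------------------------------------------------


def _interval_cm_edges(iset: IntervalSet, gmap: GeneticMarkerMap):
    """Map physical intervals to (chrom, cm_lo, cm_hi) on the genetic map."""
    edges = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for chrom, start, end in iset:
            if chrom not in gmap.chromosomes:
                continue
            lo = interpolate_cM(gmap, chrom, start)
            hi = interpolate_cM(gmap, chrom, end)
            edges.append((chrom, min(lo, hi), max(lo, hi)))
    return edges


def nearest_neighbor_c(qtls, gmap: GeneticMarkerMap, targets: IntervalSet = None):
    """Mean recombination fraction to each QTL's nearest neighbour.

    Neighbours are the other QTLs, or (if ``targets`` is given) genomic
    intervals mapped onto the genetic map.  Same-chromosome distances use
    the Haldane function on |delta cM| / 100; different chromosomes count as
    unlinked (c = 0.5); a peak inside a target interval gives c = 0.
    Returns ``(mean c, per-QTL c array)``.
    """
    qtls = list(qtls)
    if targets is None and len(qtls) < 2:
        raise ValueError("need >= 2 QTLs (or targets) for nearest-neighbour c")
    target_edges = None if targets is None else _interval_cm_edges(targets, gmap)
    if targets is not None and not target_edges:
        raise ValueError("no targets on the genetic map")
    per_qtl = []
    for i, q in enumerate(qtls):
        cands = []
        if targets is None:
            for j, o in enumerate(qtls):
                if j == i:
                    continue
                if o.chrom == q.chrom:
                    cands.append(haldane_c(abs(o.peak_cm - q.peak_cm) / 100.0))
                else:
                    cands.append(0.5)
        else:
            for chrom, lo, hi in target_edges:
                if chrom != q.chrom:
                    cands.append(0.5)
                elif lo <= q.peak_cm <= hi:
                    cands.append(0.0)
                else:
                    d = min(abs(q.peak_cm - lo), abs(q.peak_cm - hi))
                    cands.append(haldane_c(d / 100.0))
        per_qtl.append(min(cands))
    per_qtl = np.array(per_qtl)
    return float(per_qtl.mean()), per_qtl


@dataclass
class CouplingResult:
    observed: float
    null_mean: float
    null_quantiles: dict
    n_randomizations: int
    p_value: float
    p_is_upper_bound: bool = False


def randomization_test(observed_stat: float, randomizer, n: int = 10_000,
                       seed: int = 0) -> CouplingResult:
    """Two-tailed randomization test with the doubled-smaller-tail rule.

    ``randomizer(rng)`` must return one null draw of the statistic.  P is
    ``2 * min(#{null <= obs}, #{null >= obs}) / n``, reported as an upper
    bound ``2/n`` when the smaller tail is empty.
    """
    if n < 100:
        raise ValueError("need >= 100 randomizations")
    rng = np.random.default_rng(seed)
    null = np.array([randomizer(rng) for _ in range(n)], dtype=float)
    return _tail_result(observed_stat, null)


def randomize_qtl_positions(qtls, gmap: GeneticMarkerMap, rng):
    """Redraw QTL peaks uniformly on the concatenated genetic map: chromosome
    chosen proportional to map length, position uniform on its cM span."""
    chroms = gmap.chromosomes
    spans = np.array([gmap.cm_span(c)[1] - gmap.cm_span(c)[0] for c in chroms])
    prob = spans / spans.sum()
    out = []
    for q in qtls:
        c = rng.choice(len(chroms), p=prob)
        lo, hi = gmap.cm_span(chroms[c])
        cm = float(rng.uniform(lo, hi))
        out.append(QTLRecord(q.trait, q.pheno_class, chroms[c], cm, q.lod, cm, cm))
    return out


def _null_mean_c(qtls, gmap: GeneticMarkerMap, targets, n: int, rng):
    """Vectorized null draws of the nearest-neighbour mean c: QTL peaks
    redrawn uniformly on the concatenated genetic map."""
    chroms = gmap.chromosomes
    spans = np.array([gmap.cm_span(c) for c in chroms], dtype=float)
    lengths = spans[:, 1] - spans[:, 0]
    prob = lengths / lengths.sum()
    k = len(qtls)
    ci = rng.choice(len(chroms), size=(n, k), p=prob)
    cm = spans[ci, 0] + rng.random((n, k)) * lengths[ci]
    if targets is None:
        same = ci[:, :, None] == ci[:, None, :]
        d = np.abs(cm[:, :, None] - cm[:, None, :]) / 100.0
        c = np.where(same, (1.0 - np.exp(-2.0 * d)) / 2.0, 0.5)
        c[:, np.arange(k), np.arange(k)] = np.inf
        per = c.min(axis=2)
    else:
        edges = _interval_cm_edges(targets, gmap)
        if not edges:
            raise ValueError("no targets on the genetic map")
        t_ci = np.array([chroms.index(e[0]) for e in edges])
        t_lo = np.array([e[1] for e in edges])
        t_hi = np.array([e[2] for e in edges])
        same = ci[:, :, None] == t_ci[None, None, :]
        below = np.maximum(t_lo[None, None, :] - cm[:, :, None], 0.0)
        above = np.maximum(cm[:, :, None] - t_hi[None, None, :], 0.0)
        d = (below + above) / 100.0
        c = np.where(same, (1.0 - np.exp(-2.0 * d)) / 2.0, 0.5)
        per = c.min(axis=2)
    return per.mean(axis=1)


def _tail_result(observed: float, null: np.ndarray) -> CouplingResult:
    lo = int((null <= observed).sum())
    hi = int((null >= observed).sum())
    tail = min(lo, hi)
    bound = tail == 0
    p = min(2.0 * max(tail, 1) / len(null), 1.0)
    qs = {q: float(np.quantile(null, q)) for q in (0.025, 0.25, 0.5, 0.75, 0.975)}
    return CouplingResult(float(observed), float(null.mean()), qs, len(null),
                          p, bound)


def coupling_test(qtls, gmap: GeneticMarkerMap, targets: IntervalSet = None,
                  n: int = 10_000, seed: int = 0) -> CouplingResult:
    """Randomization test of QTL clustering (targets=None) or QTL coupling to
    genomic intervals, holding the targets fixed.

    Same null and tail rules as :func:`randomization_test`, with the null
    mean-c draws computed vectorized.
    """
    if n < 100:
        raise ValueError("need >= 100 randomizations")
    observed, _ = nearest_neighbor_c(qtls, gmap, targets)
    rng = np.random.default_rng(seed)
    null = _null_mean_c(qtls, gmap, targets, n, rng)
    return _tail_result(observed, null)


# ---------------------------------------------------------------------------
# Breakpoint rearrangement statistic
# ---------------------------------------------------------------------------


@dataclass
class BreakpointTest:
    chrom: str
    cm_lo: float
    cm_hi: float
    n_events: int
    p: float
    statistic: float
    candidate: bool


def parental_fraction(n_f2: int, n_parental_a: int, n_parental_b: int) -> float:
    """Fraction of parental (within-species) individuals in the crosses."""
    total = n_f2 + n_parental_a + n_parental_b
    return (n_parental_a + n_parental_b) / total


def pn_statistic(p: float, n: int) -> float:
    """Probability p^n of observing n within-species recombination events in
    a region where F2s never recombine."""
    if not 0.0 < p < 1.0:
        raise ValueError("p must be in (0, 1)")
    return p**n


def breakpoint_rearrangements(f2_events: pd.DataFrame, parental_events: pd.DataFrame,
                              p: float, gmap: GeneticMarkerMap = None,
                              threshold: float = 0.01):
    """Candidate rearrangements from recombination-event maps.

    ``f2_events`` and ``parental_events`` are DataFrames with ``chrom`` and
    ``cm`` columns locating crossover events.  Each maximal map segment free
    of F2 events (an F2 breakpoint) containing ``n >= 1`` parental events is
    scored ``p^n``; segments with ``p^n < threshold`` are candidates.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("p must be in (0, 1)")
    chroms = set(parental_events["chrom"]) | set(f2_events["chrom"])
    out = []
    for chrom in sorted(chroms):
        if gmap is not None and chrom in gmap.chromosomes:
            lo, hi = gmap.cm_span(chrom)
        else:
            allcm = np.concatenate([
                f2_events.loc[f2_events["chrom"] == chrom, "cm"].to_numpy(float),
                parental_events.loc[parental_events["chrom"] == chrom, "cm"].to_numpy(float),
            ])
            lo, hi = float(allcm.min()), float(allcm.max())
        cuts = np.sort(f2_events.loc[f2_events["chrom"] == chrom, "cm"].to_numpy(float))
        bounds = np.concatenate([[lo], cuts, [hi]])
        par = np.sort(parental_events.loc[parental_events["chrom"] == chrom,
                                          "cm"].to_numpy(float))
        for a, b in zip(bounds[:-1], bounds[1:]):
            if b <= a:
                continue
            n = int(((par > a) & (par < b)).sum())
            if n >= 1:
                s = pn_statistic(p, n)
                out.append(BreakpointTest(chrom, float(a), float(b), n, p, s,
                                          s < threshold))
    return out
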