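"""Synthetic genomes and crosses with planted truth.

Two generators back the whole test surface of the package:

* :func:`simulate_species_genomes` draws an independent coalescent genealogy
  per genomic window under a ladder demography (two sister species exchanging
  migrants, a distant relative, and optionally a true outgroup), drops
  infinite-sites binary mutations, and returns diploid genotypes together
  with the planted truth interval sets.  Planted *island* windows suppress
  sister migration (and locally reduce sister N_e, emulating linked
  selection at barrier loci); planted *introgressed* windows additionally
  reroute the recipient's lineages to the distant donor via an admixture
  pulse.

* :func:`simulate_cross` builds F2/backcross ancestry genotypes on a genetic
  map with achiasmatic females (zero crossovers in female meioses, Haldane
  crossover process in males) and quantitative/binary phenotypes from
  planted QTL effects.

All randomness flows from the config seeds; fixed seeds give byte-identical
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import msprime
import numpy as np
import pandas as pd

from .intervals import IntervalSet
from .qtl import CrossGenotypes, GeneticMarkerMap, haldane_c
from .windows import GenotypeMatrix

#: Scaled sister-migration presets (migrants per generation).
NM_PRESETS = (0.01, 0.1, 1.0, 2.0, 10.0)

#: Default per-site per-generation mutation rate.
MU_DEFAULT = 2.9e-9

#: Default generation time in years.
GENERATION_TIME_DEFAULT = 0.25


@dataclass
class IntrogressionPulse:
    """Admixture pulse: at ``time`` generations ago, ``fraction`` of the
    target population's ancestry derives from the source population."""

    source: str
    target: str
    time: float
    fraction: float = 1.0

    def __post_init__(self):
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("pulse fraction must be in [0, 1]")
        if self.time <= 0:
            raise ValueError("pulse time must be positive")


@dataclass
class DemographyConfig:
    """Ladder demography for 3 or 4 populations.

    ``populations`` is an ordered list of ``(name, diploid N_e)``: the first
    two are the sister species joining at ``split_times[0]`` (T_D1), the
    third joins at ``split_times[1]`` (T_D2), an optional fourth outgroup at
    ``split_times[2]``.  ``nm`` is the scaled migration rate (migrants per
    generation, Nm = N_e * m) between the sisters; the per-direction rate
    into each sister is ``nm / N_e(sister)``.
    """

    populations: list
    split_times: list
    samples: dict
    nm: float = 0.0
    pulse: IntrogressionPulse | None = None
    island_ne_scale: float = 0.25
    sweep_ne_scale: float = 0.1
    mu: float = MU_DEFAULT
    generation_time: float = GENERATION_TIME_DEFAULT
    ancestral_ne: float | None = None
    seed: int = 1

    def __post_init__(self):
        if len(self.populations) not in (3, 4):
            raise ValueError("expected 3 or 4 populations")
        if len(self.split_times) != len(self.populations) - 1:
            raise ValueError("need one split time per non-sister population")
        t = list(self.split_times)
        if any(x <= 0 for x in t) or any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("split times must be positive and increasing")
        if any(ne <= 0 for _, ne in self.populations):
            raise ValueError("effective sizes must be positive")
        if self.nm < 0:
            raise ValueError("Nm must be non-negative")
        names = [n for n, _ in self.populations]
        for name, n in self.samples.items():
            if name not in names:
                raise ValueError(f"samples given for unknown population {name}")
            if n <= 0:
                raise ValueError(f"zero samples in population {name}")
        for name in names:
            if self.samples.get(name, 0) <= 0:
                raise ValueError(f"zero samples in population {name}")

    @property
    def t_d1(self) -> float:
        return self.split_times[0]

    @property
    def t_d2(self) -> float:
        return self.split_times[1]


@dataclass
class GenomeLayout:
    """Chromosome lengths, simulation window grid, and planted intervals."""

    chromosomes: dict
    window_size: int
    islands: IntervalSet = field(default_factory=IntervalSet)
    introgressed: IntervalSet = field(default_factory=IntervalSet)

    def __post_init__(self):
        if self.window_size < 1:
            raise ValueError("window shorter than 1 bp")
        for iset in (self.islands, self.introgressed):
            for chrom, start, end in iset:
                if chrom not in self.chromosomes:
                    raise ValueError(f"planted interval on unknown chromosome {chrom}")
                if start < 0 or end > self.chromosomes[chrom]:
                    raise ValueError(
                        f"planted interval outside {chrom}: [{start}, {end})"
                    )

    def windows(self):
        """Tiling simulation windows ``(chrom, start, end)``."""
        for chrom, length in self.chromosomes.items():
            start = 0
            while start < length:
                yield chrom, start, min(start + self.window_size, length)
                start += self.window_size


def _overlaps(iset: IntervalSet, chrom: str, start: int, end: int) -> bool:
    sub = iset.df[iset.df["chrom"] == chrom]
    return bool(((sub["start"] < end) & (sub["end"] > start)).any())


def _window_demography(cfg: DemographyConfig, island: bool, introgressed: bool):
    names = [n for n, _ in cfg.populations]
    sizes = dict(cfg.populations)
    anc_ne = cfg.ancestral_ne if cfg.ancestral_ne is not None else sizes[names[0]]
    d = msprime.Demography()
    scale = cfg.island_ne_scale if island else 1.0
    for i, name in enumerate(names):
        ne = sizes[name] * (scale if i < 2 else 1.0)
        if introgressed and cfg.pulse is not None and name == cfg.pulse.target:
            # fixation of the introgressed haplotype sweeps local diversity
            ne *= cfg.sweep_ne_scale
        d.add_population(name=name, initial_size=ne)
    anc_names = [f"anc{i}" for i in range(1, len(names))]
    for a in anc_names:
        # linked selection at a barrier locus also depresses ancestral N_e
        d.add_population(name=a, initial_size=anc_ne * scale)
    if cfg.nm > 0 and not island:
        a, b = names[0], names[1]
        d.set_migration_rate(source=a, dest=b, rate=cfg.nm / sizes[a])
        d.set_migration_rate(source=b, dest=a, rate=cfg.nm / sizes[b])
    if introgressed:
        if cfg.pulse is None:
            raise ValueError("introgressed window requested without a pulse config")
        d.add_mass_migration(
            time=cfg.pulse.time, source=cfg.pulse.target, dest=cfg.pulse.source,
            proportion=cfg.pulse.fraction,
        )
    derived = [names[0], names[1]]
    for t, anc, nxt in zip(cfg.split_times, anc_names, names[2:] + [None]):
        d.add_population_split(time=t, derived=derived, ancestral=anc)
        derived = [anc, nxt] if nxt is not None else [anc]
    d.sort_events()
    return d


def simulate_window(cfg: DemographyConfig, length: int, island: bool,
                    introgressed: bool, seed_pair):
    """Simulate one window; returns (positions 0-based, diploid geno matrix)."""
    demog = _window_demography(cfg, island, introgressed)
    ts = msprime.sim_ancestry(
        samples={n: cfg.samples[n] for n, _ in cfg.populations},
        demography=demog, sequence_length=length, recombination_rate=0,
        random_seed=int(seed_pair[0]),
    )
    mts = msprime.sim_mutations(
        ts, rate=cfg.mu, random_seed=int(seed_pair[1]),
        model=msprime.BinaryMutationModel(), discrete_genome=True,
    )
    n_dip = sum(cfg.samples.values())
    if mts.num_sites == 0:
        return np.array([], dtype=np.int64), np.zeros((0, n_dip), dtype=np.int8)
    hap = mts.genotype_matrix().astype(np.int8)  # binary model: 0/1 alleles
    pos = mts.tables.sites.position.astype(np.int64)
    dip = hap[:, 0::2] + hap[:, 1::2]
    poly = hap.min(axis=1) != hap.max(axis=1)  # drop back-mutated monomorphic
    return pos[poly], dip[poly]


def simulate_species_genomes(cfg: DemographyConfig, layout: GenomeLayout):
    """Per-window coalescent simulation of the whole genome.

    Returns ``(GenotypeMatrix, truth_islands, truth_introgressed)``.  The
    truth sets are the planted layout intervals, merged.
    """
    names = [n for n, _ in cfg.populations]
    samples = []
    popmap = {}
    for name in names:
        for i in range(cfg.samples[name]):
            s = f"{name}_{i}"
            samples.append(s)
            popmap[s] = name
    rng = np.random.default_rng(cfg.seed)
    chroms, poss, genos = [], [], []
    for chrom, start, end in layout.windows():
        seeds = rng.integers(1, 2**31 - 1, size=2)
        island = _overlaps(layout.islands, chrom, start, end)
        intro = _overlaps(layout.introgressed, chrom, start, end)
        pos, geno = simulate_window(cfg, end - start, island, intro, seeds)
        chroms.extend([chrom] * len(pos))
        poss.append(pos + start + 1)  # to 1-based
        genos.append(geno)
    gm = GenotypeMatrix(
        np.array(chroms, dtype=object),
        np.concatenate(poss) if poss else np.array([], dtype=np.int64),
        np.vstack(genos) if genos else np.zeros((0, len(samples)), dtype=np.int8),
        samples, popmap,
    )
    return gm, layout.islands.merge(), layout.introgressed.merge()


# ---------------------------------------------------------------------------
# VCF / TSV / BED output
# ---------------------------------------------------------------------------

_GT = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


def write_vcf(gm: GenotypeMatrix, path, contig_lengths: dict | None = None) -> None:
    """Write a minimal biallelic VCF (REF=A, ALT=T placeholder alleles)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=heliscan\n")
        if contig_lengths:
            for chrom, length in contig_lengths.items():
                fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.samples) + "\n")
        for i in range(gm.n_sites):
            gts = "\t".join(_GT[int(g)] for g in gm.geno[i])
            fh.write(f"{gm.chrom[i]}\t{gm.pos[i]}\t.\tA\tT\t.\tPASS\t.\tGT\t{gts}\n")


def write_popmap(popmap: dict, path) -> None:
    with open(path, "w") as fh:
        for sample, pop in popmap.items():
            fh.write(f"{sample}\t{pop}\n")


def write_outputs(gm: GenotypeMatrix, out_dir, layout: GenomeLayout | None = None,
                  truth_islands: IntervalSet | None = None,
                  truth_introgressed: IntervalSet | None = None) -> dict:
    """Write sim.vcf, popmap.tsv and the truth BED files; returns the paths."""
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {"vcf": out_dir / "sim.vcf", "popmap": out_dir / "popmap.tsv"}
    write_vcf(gm, paths["vcf"], layout.chromosomes if layout else None)
    write_popmap(gm.popmap, paths["popmap"])
    if truth_islands is not None:
        paths["islands"] = out_dir / "truth_islands.bed"
        truth_islands.to_bed(paths["islands"])
    if truth_introgressed is not None:
        paths["introgression"] = out_dir / "truth_introgression.bed"
        truth_introgressed.to_bed(paths["introgression"])
    return paths


# ---------------------------------------------------------------------------
# Crosses
# ---------------------------------------------------------------------------


@dataclass
class PlantedQTL:
    trait: str
    chrom: str
    cm: float
    additive: float
    dominance: float = 0.0


@dataclass
class CrossDesign:
    """Design of a mapping cross on a genetic map.

    ``design`` is one of ``f2``, ``bc_e``, ``bc_p``, ``pure_e``, ``pure_p``.
    Backcrosses mate an F1 male (recombining) to a pure female
    (achiasmatic), so all informative crossovers are paternal, as in the F2.
    """

    design: str
    family_sizes: list
    marker_map: GeneticMarkerMap
    qtls: list = field(default_factory=list)
    residual_sd: float = 1.0
    seed: int = 1

    def __post_init__(self):
        if self.design not in ("f2", "bc_e", "bc_p", "pure_e", "pure_p"):
            raise ValueError(f"unknown cross design {self.design}")
        for chrom in self.marker_map.chromosomes:
            if len(self.marker_map.chrom_table(chrom)) < 2:
                raise ValueError(f"need >= 2 markers on {chrom}")


def _male_gamete(rng, cm: np.ndarray) -> np.ndarray:
    """One recombinant haplotype (0 = P allele, 1 = E allele) along loci at
    map positions ``cm`` (one chromosome), Haldane (no-interference) spacing."""
    alleles = np.empty(len(cm), dtype=np.int8)
    alleles[0] = rng.integers(0, 2)
    d = np.diff(cm) / 100.0  # Morgans
    r = haldane_c(d)
    flips = rng.random(len(r)) < r
    for i, f in enumerate(flips):
        alleles[i + 1] = alleles[i] ^ int(f)
    return alleles


def _female_gamete(rng, n_loci: int) -> np.ndarray:
    """Achiasmatic gamete: a whole parental haplotype, no crossovers."""
    return np.full(n_loci, rng.integers(0, 2), dtype=np.int8)


def simulate_cross(design: CrossDesign):
    """Simulate cross genotypes and phenotypes.

    Returns ``(CrossGenotypes, phenotypes)``.  Phenotypes carry one
    quantitative column per trait (QTL additive + dominance effects plus
    Gaussian noise) and one ``<trait>_choice`` binary column drawn from a
    logistic of the same linear predictor.  The achiasmy truth (maternal and
    paternal haplotypes) is stored on the returned genotypes for testing.
    """
    rng = np.random.default_rng(design.seed)
    gmap = design.marker_map
    n_ind = int(sum(design.family_sizes))
    chrom_loci = {}  # chrom -> (cm incl. QTL pseudo-loci, marker mask, qtl index)
    qtl_of = {}
    for chrom in gmap.chromosomes:
        tab = gmap.chrom_table(chrom)
        cms = list(tab["cm"])
        is_marker = [True] * len(cms)
        for qi, q in enumerate(design.qtls):
            if q.chrom == chrom:
                cms.append(q.cm)
                is_marker.append(False)
                qtl_of[(chrom, len(cms) - 1)] = qi
        order = np.argsort(cms, kind="stable")
        chrom_loci[chrom] = (np.array(cms)[order], np.array(is_marker)[order], order)

    marker_names = list(gmap.df["marker"])
    n_markers = len(marker_names)
    geno = np.zeros((n_ind, n_markers), dtype=np.int8)
    mat_hap = np.zeros((n_ind, n_markers), dtype=np.int8)
    pat_hap = np.zeros((n_ind, n_markers), dtype=np.int8)
    qtl_geno = np.zeros((n_ind, len(design.qtls)), dtype=np.int8)

    families = np.concatenate([
        np.full(n, f"fam{k}") for k, n in enumerate(design.family_sizes)
    ]) if n_ind else np.array([], dtype=object)
    sexes = np.where(rng.random(n_ind) < 0.5, "F", "M")

    for ind in range(n_ind):
        mcol = 0
        for chrom in gmap.chromosomes:
            cms, is_marker, _ = chrom_loci[chrom]
            n_loci = len(cms)
            if design.design == "f2":
                mat = _female_gamete(rng, n_loci)       # F1 mother, achiasmatic
                pat = _male_gamete(rng, cms)            # F1 father, recombining
            elif design.design == "bc_e":
                mat = np.ones(n_loci, dtype=np.int8)    # pure E mother
                pat = _male_gamete(rng, cms)
            elif design.design == "bc_p":
                mat = np.zeros(n_loci, dtype=np.int8)   # pure P mother
                pat = _male_gamete(rng, cms)
            elif design.design == "pure_e":
                mat = np.ones(n_loci, dtype=np.int8)
                pat = np.ones(n_loci, dtype=np.int8)
            else:  # pure_p
                mat = np.zeros(n_loci, dtype=np.int8)
                pat = np.zeros(n_loci, dtype=np.int8)
            g = mat + pat
            for j in range(n_loci):
                if is_marker[j]:
                    geno[ind, mcol] = g[j]
                    mat_hap[ind, mcol] = mat[j]
                    pat_hap[ind, mcol] = pat[j]
                    mcol += 1
                else:
                    qtl_geno[ind, qtl_of[(chrom, _orig_index(chrom_loci, chrom, j))]] = g[j]

    cross = CrossGenotypes(
        ids=[f"ind{i}" for i in range(n_ind)], family=list(families),
        cross_type=design.design, sex=list(sexes), geno=geno, marker_map=gmap,
        maternal_hap=mat_hap, paternal_hap=pat_hap,
    )

    traits = sorted({q.trait for q in design.qtls})
    pheno = pd.DataFrame(index=cross.ids)
    for trait in traits:
        lin = np.zeros(n_ind)
        for qi, q in enumerate(design.qtls):
            if q.trait != trait:
                continue
            g = qtl_geno[:, qi]
            lin += q.additive * (g - 1) + q.dominance * (g == 1)
        pheno[trait] = lin + rng.normal(0.0, design.residual_sd, size=n_ind)
        prob = 1.0 / (1.0 + np.exp(-lin))
        pheno[f"{trait}_choice"] = (rng.random(n_ind) < prob).astype(int)
    if not traits:
        pheno["noise"] = rng.normal(0.0, design.residual_sd, size=n_ind)
    return cross, pheno


def _orig_index(chrom_loci, chrom, sorted_j):
    """Map a sorted locus index back to its pre-sort index on this chromosome."""
    _, _, order = chrom_loci[chrom]
    return int(order[sorted_j])
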