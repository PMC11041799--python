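"""Shared fixtures: hand-built genotype matrices, simulated genomes and
crosses used across the suite."""

import numpy as np
import pandas as pd
import pytest

import heliscan as hs
from heliscan.study import run_island_scan
from heliscan.windows import GenotypeMatrix


def make_gm(chrom, pos, geno, pops):
    """Build a GenotypeMatrix from per-site rows and a population layout.

    ``pops`` maps population name -> number of samples; samples are named
    ``<pop><i>`` in order.
    """
    samples, popmap = [], {}
    for pop, n in pops.items():
        for i in range(n):
            s = f"{pop}{i}"
            samples.append(s)
            popmap[s] = pop
    return GenotypeMatrix(np.array(chrom, dtype=object), np.array(pos),
                          np.array(geno, dtype=np.int8), samples, popmap)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240417)


@pytest.fixture(scope="session")
def random_gm(rng):
    """A moderately sized random genotype matrix with two populations."""
    n_sites, n_a, n_b = 400, 5, 4
    geno = rng.integers(0, 3, size=(n_sites, n_a + n_b)).astype(np.int8)
    miss = rng.random(geno.shape) < 0.05
    geno[miss] = -1
    pos = np.sort(rng.choice(np.arange(1, 100_001), size=n_sites, replace=False))
    return make_gm(["chr1"] * n_sites, pos, geno, {"A": n_a, "B": n_b})


@pytest.fixture(scope="session")
def island_scans():
    """Ten replicate island-scan pipelines on the reference synthetic study."""
    return [run_island_scan(seed) for seed in range(1, 11)]


@pytest.fixture(scope="session")
def pure_species_genome():
    """Deep-split genome with no gene flow: pure species panels."""
    cfg = hs.DemographyConfig(
        populations=[("ele", 50_000), ("par", 50_000), ("mel", 50_000),
                     ("out", 20_000)],
        split_times=[400_000, 800_000, 1_200_000],
        samples={"ele": 4, "par": 4, "mel": 2, "out": 2},
        nm=0.0, seed=99,
    )
    layout = hs.GenomeLayout(chromosomes={"chr1": 200_000, "chr2": 200_000},
                             window_size=5_000)
    gm, _, _ = hs.simulate_species_genomes(cfg, layout)
    return gm


@pytest.fixture(scope="session")
def qtl_map():
    """Five 100-cM chromosomes with markers every 10 cM."""
    rows = []
    for c in range(1, 6):
        for i, cm in enumerate(range(0, 101, 10)):
            rows.append((f"m{c}_{i}", f"lg{c}", cm * 100_000, float(cm)))
    return hs.GeneticMarkerMap(pd.DataFrame(
        rows, columns=["marker", "chrom", "bp", "cm"]))


@pytest.fixture(scope="session")
def f2_cross(qtl_map):
    """An F2 of 500 individuals with one planted additive QTL."""
    design = hs.CrossDesign(
        "f2", [250, 250], qtl_map,
        qtls=[hs.PlantedQTL("colour", "lg2", 30.0, additive=np.sqrt(4 / 3))],
        residual_sd=1.0, seed=7)
    return hs.simulate_cross(design)
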