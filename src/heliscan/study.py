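"""Reference synthetic study: the end-to-end island/introgression scan.

This module fixes one set of study conditions — demography, genome layout,
sampling and scan settings — used throughout the package's own validation:
two sister species (``ele``, ``par``) exchanging Nm = 2 migrants per
generation, a distant donor (``mel``) and an outgroup, with planted islands
of divergence (migration shut off, locally reduced N_e) a subset of which
carry fixed introgression from the donor.  Split times and rates follow the
three-species coalescent template used for the scans (T_D1 = 4e6 and
T_D2 = 8e6 generations, ingroup N_e = 1e6, outgroup N_e = 4e5,
mu = 2.9e-9); the genome is two 300-kb chromosomes of 5-kb simulation
windows, a desk-scale stand-in for a butterfly genome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import IntervalSet
from .islands import call_islands
from .simulate import DemographyConfig, GenomeLayout, IntrogressionPulse, \
    simulate_species_genomes
from .topology import flag_windows, grouping_predicate, \
    reciprocal_monophyly_predicate, twisst_scan
from .windows import fst_scan

SPECIES_OF = {"eleA": "ele", "eleB": "ele", "parA": "par", "parB": "par",
              "mel": "mel", "out": "outgroup"}

GROUPS = {"eleA": ["ele_0"], "eleB": ["ele_1"],
          "parA": ["par_0"], "parB": ["par_1"],
          "mel": ["mel_0"], "out": ["out_0"]}

ISLANDS = [("chr1", 60_000, 100_000), ("chr1", 180_000, 220_000),
           ("chr2", 120_000, 160_000)]
INTROGRESSED = [("chr1", 70_000, 90_000), ("chr2", 130_000, 150_000)]


def default_demography(seed: int, nm: float = 2.0,
                       ingroup_ne: float = 1_000_000) -> DemographyConfig:
    """The three-species-plus-outgroup ladder used by the reference study."""
    return DemographyConfig(
        populations=[("ele", ingroup_ne), ("par", ingroup_ne),
                     ("mel", ingroup_ne), ("out", 400_000)],
        split_times=[4_000_000, 8_000_000, 12_000_000],
        samples={"ele": 4, "par": 4, "mel": 2, "out": 2},
        nm=nm,
        pulse=IntrogressionPulse("mel", "ele", time=400_000, fraction=1.0),
        seed=seed,
    )


def default_layout(islands=ISLANDS, introgressed=INTROGRESSED) -> GenomeLayout:
    return GenomeLayout(
        chromosomes={"chr1": 300_000, "chr2": 300_000}, window_size=5_000,
        islands=IntervalSet.from_records(islands),
        introgressed=IntervalSet.from_records(introgressed),
    )


@dataclass
class IslandScanResult:
    genotypes: object
    truth_islands: IntervalSet
    truth_introgressed: IntervalSet
    weights: pd.DataFrame
    fst: pd.DataFrame
    species_tree_intervals: IntervalSet
    introgression_intervals: IntervalSet
    called_islands: IntervalSet

    def sensitivity(self) -> float:
        tp = self.called_islands.overlap_bases(self.truth_islands)
        return tp / self.truth_islands.total_bases()

    def false_positive_fraction(self) -> float:
        called = self.called_islands.total_bases()
        if called == 0:
            return 0.0
        tp = self.called_islands.overlap_bases(self.truth_islands)
        return (called - tp) / called

    def introgression_sensitivity(self) -> float:
        tp = self.introgression_intervals.overlap_bases(self.truth_introgressed)
        return tp / self.truth_introgressed.total_bases()

    def introgression_false_positive_fraction(self) -> float:
        called = self.introgression_intervals.total_bases()
        if called == 0:
            return 0.0
        tp = self.introgression_intervals.overlap_bases(self.truth_introgressed)
        return (called - tp) / called


def run_island_scan(seed: int, nm: float = 2.0, layout: GenomeLayout = None,
                    window_snps: int = 100, step: int = 100,
                    merge_gap: int = 5_000, min_length: int = 10_000,
                    weight_threshold: float = 0.8) -> IslandScanResult:
    """Simulate a genome and run the full island-calling pipeline.

    F_ST is scanned in 25-kb windows (5-kb step); topology weighting uses
    non-overlapping 100-SNP windows; islands are F_ST >= 0.2 intersected
    with reciprocal-monophyly intervals (weight >= 0.8), merged across
    sub-window gaps and filtered to >= ``min_length`` bp.
    """
    cfg = default_demography(seed, nm=nm)
    layout = layout if layout is not None else default_layout()
    gm, truth_islands, truth_intro = simulate_species_genomes(cfg, layout)
    sp_pred = reciprocal_monophyly_predicate(SPECIES_OF, "ele", "par")
    in_pred = grouping_predicate(SPECIES_OF, "ele", "mel")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        weights = twisst_scan(gm, GROUPS, "out",
                              {"w_species": sp_pred, "w_intro": in_pred},
                              window_snps=window_snps, step=step, seed=seed)
        fst = fst_scan(gm, "ele", "par", size=25_000, step=5_000,
                       min_fraction=0.0, min_sites=20)
    sp_iv = flag_windows(weights, "w_species", weight_threshold, merge_gap)
    in_iv = flag_windows(weights, "w_intro", weight_threshold, merge_gap)
    called = call_islands(fst, sp_iv, fst_min=0.2, merge_gap=merge_gap,
                          min_length=min_length)
    return IslandScanResult(gm, truth_islands, truth_intro, weights, fst,
                            sp_iv, in_iv, called)
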