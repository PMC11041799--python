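# Methods

`heliscan` implements the statistical machinery of a hybrid-speciation
genome scan: window differentiation statistics, topology weighting of window
genealogies, f4 gene-flow tests, ancestry-tract detection, island-of-
divergence calling with interval-overlap enrichment, and QTL mapping with
recombination-fraction coupling tests — together with a coalescent and cross
simulator that plants exactly the structures these scans are designed to
find. This note records the models, the defaults and why they were chosen,
and what the synthetic validation does and does not establish.

## Window diversity and differentiation

Genotypes are biallelic diploid codes (0/1/2 copies of the alternate
allele) with 1-based VCF positions converted to 0-based half-open window
coordinates at the I/O boundary. Sites are retained when every population
has at least `min(3, population size)` genotyped individuals; individuals
with more than 50% missing data can be dropped first.

Per usable site, within-population diversity is the unbiased heterozygosity
`pi = 2 p q n / (n - 1)` on the `n` non-missing allele copies; the pooled
diversity uses the pooled copies, and
`d_xy = p_A (1 - p_B) + p_B (1 - p_A)`. Window values are means over the
window's usable sites (a ratio of per-site sums, not a mean of per-site
ratios — the standard convention for Hudson-type window estimators), and

    F_ST = 1 - ((pi_A + pi_B) / 2) / pi_pooled,

reported as missing when the pooled diversity is zero. Sites with fewer
than two allele copies in either population are excluded from that window.
The default scan uses 25-kb windows with a 5-kb step. The 10%-usable-sites
window rule presumes all-sites genotype input; for SNP-only matrices (as
produced by the bundled simulator) the scan instead takes a minimum SNP
count per window (`min_sites`), with `min_fraction=0`.

## Topology weighting

For each SNP-count window (default 100 SNPs, sliding 25) the package keeps
sites that are fixed and homozygous in the designated outgroup group,
variable in the focal samples, and at ingroup minor-allele frequency of at
least 0.05. Diploids are split into pseudo-haplotypes by seeded random
phase assignment: group-level topology weights are insensitive to
within-individual phase, which removes the need for statistical phasing. A
neighbour-joining tree is built on pairwise-complete p-distances, with tips
sorted by name before clustering so ties resolve deterministically.

The weight of a group-level topology is the fraction of all
one-tip-per-group combinations of the tree whose induced (pruned) topology
matches it. Exact weights enumerate every combination — the implementation
restricts each tree edge's tip set to the combination with vectorized
bit-mask operations, so enumeration is cheap up to the 10^7-combination cap,
beyond which a uniform sampler takes over (with a logged notice). A
topology is encoded canonically as the sorted tuple of its non-trivial
split sides that exclude a reference group; the unrooted topology counts
(1, 3, 15, 105 for 3–6 groups) and an independent shear-and-read-splits
oracle pin the algebra in the tests.

Window classification uses clade predicates on the group-level topology:
*reciprocal monophyly* of two species (each species' groups form exclusive
clades — the species-tree/island signal, which also holds in introgressed
islands where one sister attaches to the donor), and *grouping* (the union
of two species' groups forms a clade — the introgression signal). Windows
whose summed predicate weight reaches a threshold (0.8 for interval
flagging; 0.5 for the four-way window classes) are flagged and merged.
Because SNP-count windows leave small between-SNP gaps on the physical
axis, merging bridges gaps up to `merge_gap` (default 5 kb in the reference
pipeline, i.e. the F_ST window step).

## Islands of divergence and overlap enrichment

An island is called where the two evidence tracks coincide: windows with
F_ST ≥ 0.2 intersected with reciprocal-monophyly intervals, merged across
sub-window gaps and filtered to a 10-kb minimum length (single stray
windows are not islands). Enrichment of one interval set inside another is
a Fisher's exact test on the base-level 2×2 table against the genome size,
with bases binned into units (default 1 kb) and all tail sums computed from
hypergeometric log-pmfs so counts of order 10^8 are exact. The two-tail
p-value sums tables no more probable than the one observed. This base-pair
contingency is a deliberate dialect: it is exactly specified and
reproducible, and conservative for merged interval sets.

## f4, Mantel and Nm

`f4(A,B;C,D)` is the mean over usable sites of
`(p_A - p_B)(p_C - p_D)`; the standard error is a weighted delete-one
block jackknife over contiguous 500-kb blocks with block weights equal to
their site counts (Busing-style delete-m_j formulae), and `Z = f4 / SE`.
The Mantel test correlates two distance structures and permutes subject
labels of one matrix (never raw entries); the two-sided permutation
p-value is `(1 + #{|r*| >= |r|}) / (n_perm + 1)`. Migration-rate reporting
uses `Nm_AB = M_AB * theta_B / 4`.

## Crosses and QTL mapping

The cross simulator models Lepidopteran achiasmy: female meioses contribute
zero crossovers (a whole parental haplotype per chromosome), male meioses
follow a Haldane (no-interference) crossover process on the cM map.
Phenotypes sum planted additive and dominance effects plus Gaussian noise;
binary-choice phenotypes are Bernoulli draws from a logistic of the same
linear predictor (choice data are bounded proportions).

The scan is Haley–Knott interval mapping adapted to achiasmy: at each 1-cM
grid position, genotype probabilities are computed from the two flanking
markers by summing over the (constant) maternal allele and a paternal
two-state Markov bridge, with a genotyping error rate of 0.001
(`P(obs|true) = 1 - e` on the diagonal, `e/2` off it). LOD is
`(n/2) log10(RSS_0 / RSS_1)` from the regression on additive
(`P(EE) - P(PP)`) and dominance (`P(EP)`) predictors; with error rate 0
the LOD at a fully informative marker equals the direct regression formula
exactly. The genome-wide 5% threshold is the 95th percentile of the max
LOD over phenotype permutations (default 1,000); support intervals are
1.5-LOD drops, standing in for Bayesian credible intervals because they are
deterministic. Sex chromosomes and sex/cross covariates are out of scope of
this simplified scan. Markers failing a Mendelian segregation chi-square
test (p < 0.01 against 1:2:1 or 1:1) can be removed first.

## Coupling and breakpoint statistics

For a set of QTL peaks, each peak's recombination fraction to its nearest
neighbour (another QTL, or the nearest edge of a target interval mapped to
cM by linear interpolation) uses the Haldane function on |Δ cM|/100; pairs
on different chromosomes count as unlinked (c = 0.5) and a peak inside a
target gives c = 0. The test statistic is the mean over peaks. The null
redraws peak positions uniformly on the concatenated genetic map —
chromosome chosen proportional to cM length, because the statistic lives in
recombination units — holding targets fixed; the two-tailed P doubles the
smaller tail proportion over 10,000 randomizations, floored at 2/n and
reported as an upper bound when the tail is empty.

Candidate rearrangements score each F2-breakpoint interval (a maximal map
segment free of F2 crossover events) containing `n ≥ 1` within-species
crossover events as `p^n`, where `p` is the fraction of parental
individuals among all cross progeny; `p^n < 0.01` flags a candidate. With
the reported cross sizes (441 F2, 179 + 296 parental) `p = 475/916` and the
smallest candidate event count is `n = 8` (`p^8 ≈ 0.0052`). The threshold
is applied to the statistic `p^n`, making explicit a reading on which the
verbal description is ambiguous.

## The synthetic study

The species simulator draws one independent genealogy per genomic window
(no within-window recombination) under a ladder demography: two sister
species joining at T_D1 = 4×10^6 generations, a distant donor at
T_D2 = 8×10^6, and an optional outgroup at 12×10^6; ingroup diploid
N_e = 10^6 (outgroup 4×10^5), mutation rate 2.9×10^-9 per site per
generation under infinite-sites binary mutations, generation time 0.25
years. Scaled sister migration Nm ∈ {0.01, 0.1, 1, 2, 10} is supported as
presets; the reference study uses Nm = 2, enough to homogenize neutral
variation. Windows are independent by design, which keeps the coalescent
oracle exact for every per-window expectation.

Planted **islands** suppress sister migration and scale the sisters' — and
their ancestors' — N_e by 0.25, so the barrier divergence is
T_D1/2N = 8 coalescent units and reciprocal monophyly is near-certain.
Extending the reduction through the ancestral population reflects
persistent linked selection at a barrier locus; without it, about e^-2 of
island windows retain deep ancestral lineages and a third of those attach a
sister to the donor, a pure incomplete-lineage-sorting artefact. Planted
**introgressed** windows additionally reroute the recipient's lineages to
the donor at 4×10^5 generations with fraction 1.0, and scale the recipient's
local N_e by 0.1: a fixed introgressed haplotype implies a local sweep that
collapses diversity, which is also what keeps the recipient monophyletic in
those windows.

The reference genome is two 300-kb chromosomes of 5-kb simulation windows
with three 40-kb islands, two of which contain 20-kb introgressed cores —
a desk-scale stand-in; all reported recovery rates and calibrations in the
tests and the acceptance script are computed at this scale. What passing
shows: the estimators are exact (against per-site and enumeration oracles),
the permutation machinery is calibrated, and the pipeline recovers planted
structure with high base-level sensitivity and low false-positive fraction
under the stated demography. What it does not show: performance under
within-window recombination, selection, realistic chromosome-scale linkage,
genotyping error in real VCFs, or the sample sizes and heterogeneity of
wild data.

## Numerical and degenerate-input conventions

Positions are validated strictly increasing per chromosome; F_ST is missing
(never clamped) when pooled diversity is zero; an all-zero distance matrix
yields a deterministic, flagged star resolution; greedy left-to-right
thinning of diagnostic SNPs (keep the first, drop any within 10 kb) is
deterministic and frequency-independent; pruning of overlapping QTLs breaks
LOD ties toward the smaller support interval, then chromosome and position.
Heterozygosity tracts skip missing scores without breaking a run and break
on homozygous scores; the default minimum run is 20 consecutive
heterozygous diagnostic SNPs (tract calling in the field is described
qualitatively, so the cutoff is exposed as a flag).

## Known limitations

The f4 surface accepts any population quadruple but does not compute
geographic distances (Euclidean distances are supplied by the caller for
the Mantel test). The QTL scan uses only flanking markers rather than a
full hidden Markov model — exact at markers, slightly conservative between
widely spaced markers. The Fisher overlap test conditions on the merged
interval sets and total genome size; spatial autocorrelation of real
interval data makes it conservative rather than exact. Reproducing
coupling statistics for real wild data requires a published QTL table,
genetic map and introgression track as external inputs (`data/external/`),
which are not bundled.
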