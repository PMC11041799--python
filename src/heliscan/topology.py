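"""Window trees and topology weighting (TWISST-style).

For each SNP window a neighbour-joining tree is built over pseudo-haplotypes
and the window genealogy is summarized by *topology weights*: the fraction
of all one-tip-per-group subsamples of the tree whose induced group-level
unrooted topology matches each possible topology.  Exact weights enumerate
every combination (the product of group sizes); a uniform sampler is used
above a combination cap.  Weights feed the window classifiers (species-tree
vs introgression genealogies) used to call islands of divergence and
introgressed regions.

Group-level topologies are encoded canonically as sorted tuples of split
bitmasks: each non-trivial split is the side that excludes group 0.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import IntervalSet
from .windows import MISSING, GenotypeMatrix, iter_windows

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Haplotype windows
# ---------------------------------------------------------------------------


@dataclass
class HaplotypeWindow:
    """Pseudo-haplotype alleles at one window's SNPs.

    ``haps`` is (n_snps, n_haplotypes) with alleles 0/1 and -1 missing;
    ``hap_groups`` maps haplotype names to their group.
    """

    chrom: str
    start: int
    end: int
    haps: np.ndarray
    hap_names: list
    hap_groups: dict


def _site_filter(gm: GenotypeMatrix, ingroup_idx, outgroup_idx, maf_min):
    og = gm.geno[:, outgroup_idx]
    og_called = og != MISSING
    any_called = og_called.any(axis=1)
    hom0 = ((og == 0) | ~og_called).all(axis=1)
    hom2 = ((og == 2) | ~og_called).all(axis=1)
    out_fixed = any_called & (hom0 | hom2)

    ig = gm.geno[:, ingroup_idx]
    called = ig != MISSING
    n = 2 * called.sum(axis=1)
    alt = np.where(called, ig, 0).sum(axis=1)
    with np.errstate(invalid="ignore"):
        p = np.where(n > 0, alt / np.maximum(n, 1), np.nan)
    variable = (alt > 0) & (alt < n)
    maf = np.minimum(p, 1 - p)
    return out_fixed & variable & (maf >= maf_min)


def make_haplotypes(gm: GenotypeMatrix, groups: dict, outgroup: str,
                    window_snps: int = 100, step: int = 25,
                    maf_min: float = 0.05, seed: int = 0):
    """Yield :class:`HaplotypeWindow` objects over SNP-count windows.

    ``groups`` maps group name -> list of sample names; ``outgroup`` names
    the designated outgroup group.  Sites must be fixed (homozygous, one
    allele) in the outgroup, variable in the focal samples, and pass the
    ingroup minimum-allele-frequency filter.  Diploids are split into two
    pseudo-haplotypes by random phase assignment under ``seed``.
    """
    if outgroup not in groups:
        raise ValueError(f"outgroup group {outgroup!r} not in groups")
    sample_order = [s for g in groups.values() for s in g]
    col = {s: gm.samples.index(s) for s in sample_order}
    out_idx = np.array([col[s] for s in groups[outgroup]])
    in_idx = np.array([col[s] for g, ss in groups.items() if g != outgroup
                       for s in ss])
    keep = _site_filter(gm, in_idx, out_idx, maf_min)
    sub = gm.take_sites(keep)

    rng = np.random.default_rng(seed)
    hap_names, hap_groups = [], {}
    for gname, ss in groups.items():
        for s in ss:
            for phase in ("a", "b"):
                hap_names.append(f"{s}_{phase}")
                hap_groups[f"{s}_{phase}"] = gname

    # random phase assignment: genotype 1 -> (0,1) or (1,0) uniformly
    n_sites = sub.n_sites
    geno = sub.geno[:, [sub.samples.index(s) for g, ss in groups.items() for s in ss]]
    n_dip = geno.shape[1]
    hapmat = np.full((n_sites, 2 * n_dip), -1, dtype=np.int8)
    swap = rng.random((n_sites, n_dip)) < 0.5
    for j in range(n_dip):
        g = geno[:, j]
        a = np.where(g == MISSING, -1, (g >= 1).astype(np.int8))   # 1 for het/hom-alt
        b = np.where(g == MISSING, -1, (g == 2).astype(np.int8))   # 1 for hom-alt
        sw = swap[:, j] & (g == 1)
        hapmat[:, 2 * j] = np.where(sw, b, a)
        hapmat[:, 2 * j + 1] = np.where(sw, a, b)

    emitted = {c: False for c in pd.unique(sub.chrom)}
    for chrom, start, end, idx in iter_windows(sub, "snp_count", window_snps, step):
        emitted[chrom] = True
        yield HaplotypeWindow(chrom, int(start), int(end), hapmat[idx],
                              list(hap_names), dict(hap_groups))
    for chrom, ok in emitted.items():
        if not ok:
            warnings.warn(f"fewer than {window_snps} usable SNPs on {chrom}; "
                          "no window emitted")


# ---------------------------------------------------------------------------
# Neighbour-joining trees
# ---------------------------------------------------------------------------


def p_distance_matrix(haps: np.ndarray, names):
    """Pairwise-complete proportion of differing alleles between haplotypes."""
    H = haps.T
    n = H.shape[0]
    D = np.zeros((n, n))
    valid = H != -1
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            if both.any():
                D[i, j] = D[j, i] = float((H[i, both] != H[j, both]).mean())
    return D


def nj_tree(window: HaplotypeWindow):
    """Saitou-Nei neighbour joining on p-distances.

    Tips are sorted by name before clustering so the result is independent
    of input order (ties break toward the lowest tip index).  An all-zero
    distance matrix is resolved arbitrarily but deterministically, with a
    warning.
    """
    from skbio import DistanceMatrix
    from skbio.tree import nj

    if len(window.hap_names) < 3:
        raise ValueError("need >= 3 haplotypes for a tree")
    order = np.argsort(window.hap_names, kind="stable")
    names = [window.hap_names[i] for i in order]
    D = p_distance_matrix(window.haps[:, order], names)
    if np.all(D == 0):
        warnings.warn(f"all-zero distance matrix in window "
                      f"{window.chrom}:{window.start}-{window.end}; "
                      "star topology resolved arbitrarily")
    return nj(DistanceMatrix(D, ids=names))


# ---------------------------------------------------------------------------
# Topology algebra
# ---------------------------------------------------------------------------


def _canonical_mask(mask: int, k: int) -> int:
    """Canonical form of a split side: the side excluding group 0."""
    full = (1 << k) - 1
    return mask ^ full if mask & 1 else mask


def all_topologies(k: int):
    """All unrooted binary topologies over k labelled groups, as canonical
    sorted split-mask tuples.  Counts: 1 (k=3), 3, 15, 105, ..."""
    if k < 3:
        raise ValueError("need >= 3 groups")
    # grow trees by attaching each new taxon to every edge
    trees = [[("i0", 0), ("i0", 1), ("i0", 2)]]
    for taxon in range(3, k):
        new_trees = []
        for edges in trees:
            for ei, (u, v) in enumerate(edges):
                node = f"i{taxon}"
                new = edges[:ei] + edges[ei + 1:] + [(u, node), (node, v),
                                                     (node, taxon)]
                new_trees.append(new)
        trees = new_trees
    return sorted({_splits_of_edgelist(edges, k) for edges in trees})


def _splits_of_edgelist(edges, k):
    adj = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    masks = set()

    def below(node, parent):
        m = 0
        if isinstance(node, int):
            m |= 1 << node
        for nb in adj[node]:
            if nb != parent:
                m |= below(nb, node)
        c = _canonical_mask(m, k)
        if 2 <= bin(c).count("1") <= k - 2:
            masks.add(c)
        return m

    root = next(n for n in adj if isinstance(n, str))
    for nb in adj[root]:
        below(nb, root)
    return tuple(sorted(masks))


@dataclass
class WeightRecord:
    """Topology weights for one window (weights sum to 1)."""

    group_names: list
    weights: dict  # topology key (sorted split-mask tuple) -> weight
    n_combinations: int
    method: str

    def weight_where(self, predicate) -> float:
        """Summed weight of topologies satisfying ``predicate(key)``."""
        return float(sum(w for key, w in self.weights.items() if predicate(key)))

    def check_normalized(self, tol: float = 1e-9):
        total = sum(self.weights.values())
        if abs(total - 1.0) > tol:
            raise ValueError(f"weights sum to {total}, expected 1")


def _edge_below_matrix(tree, tip_index: dict):
    """Boolean (n_edges, n_tips): tips below each edge of the (arbitrarily
    rooted) tree."""
    rows = []
    cache = {}
    for node in tree.postorder(include_self=False):
        if node.is_tip():
            vec = np.zeros(len(tip_index), dtype=bool)
            vec[tip_index[node.name]] = True
        else:
            vec = np.zeros(len(tip_index), dtype=bool)
            for child in node.children:
                vec |= cache[id(child)]
        cache[id(node)] = vec
        rows.append(vec)
    return np.array(rows)


def topology_weights(tree, hap_groups: dict, method: str = "exact",
                     n_samples: int = 10_000, seed: int = 0,
                     max_exact: int = 10_000_000) -> WeightRecord:
    """Topology weights of a haplotype tree over its groups.

    ``hap_groups`` maps tip name -> group.  The exact method enumerates all
    one-tip-per-group combinations, restricts the tree to each and tallies
    the induced group-level topology; weights are tallies / total.  The
    sample method draws ``n_samples`` combinations uniformly with
    replacement.  Exact enumeration above ``max_exact`` combinations falls
    back to sampling with a logged notice.
    """
    tips = [t.name for t in tree.tips()]
    tip_index = {name: i for i, name in enumerate(tips)}
    group_names = sorted({hap_groups[t] for t in tips if t in hap_groups})
    k = len(group_names)
    group_tips = {g: [] for g in group_names}
    for t in tips:
        if t in hap_groups:
            group_tips[hap_groups[t]].append(tip_index[t])
    for g in hap_groups.values():
        if g not in group_tips or not group_tips[g]:
            raise ValueError(f"group {g} absent from tree")

    below = _edge_below_matrix(tree, tip_index)
    sizes = [len(group_tips[g]) for g in group_names]
    total = int(np.prod(sizes))

    rng = np.random.default_rng(seed)
    if method == "exact" and total > max_exact:
        logger.info("exact enumeration of %d combinations exceeds cap %d; "
                    "sampling %d instead", total, max_exact, n_samples)
        method = "sample"
    if method == "exact":
        combos = np.array(list(itertools.product(*(group_tips[g]
                                                   for g in group_names))))
        n_comb = total
    elif method == "sample":
        combos = np.column_stack([
            np.array(group_tips[g])[rng.integers(0, len(group_tips[g]),
                                                 size=n_samples)]
            for g in group_names
        ])
        n_comb = n_samples
    else:
        raise ValueError(f"unknown method {method}")

    counts = {}
    full = (1 << k) - 1
    nbits = 1 << k
    pop = np.array([bin(m).count("1") for m in range(nbits)])
    for lo in range(0, len(combos), 20_000):
        chunk = combos[lo:lo + 20_000]
        C = len(chunk)
        B = below[:, chunk]                       # (E, C, k)
        masks = (B * (1 << np.arange(k))).sum(axis=2)  # (E, C)
        flip = (masks & 1).astype(bool)
        masks = np.where(flip, masks ^ full, masks)
        valid = (pop[masks] >= 2) & (pop[masks] <= k - 2)
        occ = np.zeros((C, nbits), dtype=bool)
        cc = np.broadcast_to(np.arange(C)[None, :], masks.shape)
        occ[cc[valid], masks[valid]] = True
        packed = np.packbits(occ, axis=1)
        uniq, cnt = np.unique(packed, axis=0, return_counts=True)
        for row, c in zip(uniq, cnt):
            bits = np.unpackbits(row)[:nbits]
            key = tuple(sorted(int(m) for m in np.flatnonzero(bits)))
            counts[key] = counts.get(key, 0) + int(c)

    weights = {key: c / n_comb for key, c in counts.items()}
    return WeightRecord(group_names, weights, n_comb, method)


# ---------------------------------------------------------------------------
# Window classification
# ---------------------------------------------------------------------------


def _group_mask(group_names, subset) -> int:
    m = 0
    for g in subset:
        m |= 1 << group_names.index(g)
    return m


def is_clade(key, group_names, subset) -> bool:
    """Whether ``subset`` of groups forms a clade (relative to the rest) in
    the topology encoded by ``key``."""
    k = len(group_names)
    m = _group_mask(group_names, subset)
    size = len(subset)
    if size <= 1 or size >= k - 1:
        return True
    return _canonical_mask(m, k) in key


def make_classifier(group_names, species_of: dict, sister_a: str, sister_b: str,
                    other: str):
    """Build a topology -> category function for the species/introgression
    classes.

    Categories: ``sister_pair`` (sisters group, not reciprocally
    monophyletic), ``sister_pair_mono``, ``other_pair`` (sister_a groups
    with ``other``), ``other_pair_mono``, or None.
    """
    grp = {sp: [g for g in group_names if species_of.get(g) == sp]
           for sp in (sister_a, sister_b, other)}

    def classify(key):
        ab = is_clade(key, group_names, grp[sister_a] + grp[sister_b])
        if ab:
            mono = (is_clade(key, group_names, grp[sister_a])
                    and is_clade(key, group_names, grp[sister_b]))
            return "sister_pair_mono" if mono else "sister_pair"
        ao = is_clade(key, group_names, grp[sister_a] + grp[other])
        if ao:
            mono = (is_clade(key, group_names, grp[sister_a])
                    and is_clade(key, group_names, grp[other]))
            return "other_pair_mono" if mono else "other_pair"
        return None

    return classify


def reciprocal_monophyly_predicate(species_of: dict, sp_a: str, sp_b: str):
    """Predicate: both species' groups form exclusive clades (the island /
    species-tree signal), regardless of what either clade attaches to."""

    def pred(key, group_names):
        ga = [g for g in group_names if species_of.get(g) == sp_a]
        gb = [g for g in group_names if species_of.get(g) == sp_b]
        return is_clade(key, group_names, ga) and is_clade(key, group_names, gb)

    return pred


def grouping_predicate(species_of: dict, sp_a: str, sp_b: str):
    """Predicate: the union of two species' groups forms a clade (the
    introgression signal when sp_b is the distant donor)."""

    def pred(key, group_names):
        gab = [g for g in group_names
               if species_of.get(g) in (sp_a, sp_b)]
        return is_clade(key, group_names, gab)

    return pred


def classify_window(record: WeightRecord, classifier, threshold: float = 0.5):
    """Class whose summed weight reaches ``threshold``, else 'unclassified'."""
    record.check_normalized(tol=1e-6)
    sums = {}
    for key, w in record.weights.items():
        cat = classifier(key)
        if cat is not None:
            sums[cat] = sums.get(cat, 0.0) + w
    best = max(sums, key=sums.get, default=None)
    if best is not None and sums[best] >= threshold:
        return best
    return "unclassified"


def twisst_scan(gm: GenotypeMatrix, groups: dict, outgroup: str,
                predicates: dict, window_snps: int = 100, step: int = 25,
                maf_min: float = 0.05, seed: int = 0, method: str = "exact",
                n_samples: int = 10_000) -> pd.DataFrame:
    """Window scan: NJ tree + topology weights + summed predicate weights.

    ``predicates`` maps column name -> callable(key, group_names) -> bool.
    Returns a DataFrame with chrom/start/end and one weight column per
    predicate.
    """
    rows = []
    for win in make_haplotypes(gm, groups, outgroup, window_snps, step,
                               maf_min, seed):
        tree = nj_tree(win)
        rec = topology_weights(tree, win.hap_groups, method=method,
                               n_samples=n_samples, seed=seed)
        row = {"chrom": win.chrom, "start": win.start, "end": win.end}
        for name, pred in predicates.items():
            row[name] = rec.weight_where(lambda key: pred(key, rec.group_names))
        rows.append(row)
    return pd.DataFrame(rows)


def flag_windows(table: pd.DataFrame, column: str, threshold: float = 0.8,
                 merge_gap: int = 0) -> IntervalSet:
    """Windows whose predicate weight reaches the threshold, merged into
    maximal intervals.

    Overlapping or book-ended windows always join; ``merge_gap`` additionally
    bridges gaps up to that many bp (SNP-count windows leave small
    between-SNP gaps on the physical axis).
    """
    hits = table[table[column] >= threshold]
    if hits.empty:
        return IntervalSet()
    return IntervalSet.from_records(
        zip(hits["chrom"], hits["start"], hits["end"])
    ).merge(gap=merge_gap)
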