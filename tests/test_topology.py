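"""Window trees, exact/sampled topology weighting and window classification."""

import itertools
import warnings

import numpy as np
import pytest
from skbio import TreeNode

import heliscan as hs
from heliscan.topology import (HaplotypeWindow, WeightRecord, all_topologies,
                               classify_window, flag_windows, is_clade,
                               make_classifier, make_haplotypes, nj_tree,
                               topology_weights)

from conftest import make_gm


# ---------------------------------------------------------------------------
# Independent oracle: prune each combination with skbio and read the
# group-level topology straight off the sheared tree.
# ---------------------------------------------------------------------------


def sheared_topology(tree, combo, groups):
    """Group-level topology of a tip subset as frozenset of split frozensets."""
    sub = tree.copy().shear(list(combo))
    name_of = {tip: groups[tip] for tip in combo}
    k = len(combo)
    splits = set()
    for node in sub.non_tips(include_self=False):
        side = frozenset(name_of[t.name] for t in node.tips())
        if 2 <= len(side) <= k - 2:
            other = frozenset(name_of[t] for t in combo) - side
            splits.add(frozenset({side, other}))
    return frozenset(splits)


def key_to_split_sets(key, group_names):
    """Convert a package topology key (mask tuple) to the oracle encoding."""
    k = len(group_names)
    allg = frozenset(group_names)
    splits = set()
    for mask in key:
        side = frozenset(g for i, g in enumerate(group_names) if mask & (1 << i))
        splits.add(frozenset({side, allg - side}))
    return frozenset(splits)


def brute_force_weights(tree, groups):
    tips_by_group = {}
    for tip, g in groups.items():
        tips_by_group.setdefault(g, []).append(tip)
    names = sorted(tips_by_group)
    counts = {}
    total = 0
    for combo in itertools.product(*(tips_by_group[g] for g in names)):
        topo = sheared_topology(tree, combo, groups)
        counts[topo] = counts.get(topo, 0) + 1
        total += 1
    return {t: c / total for t, c in counts.items()}


def random_group_tree(rng, n_groups, max_tips_per_group):
    """Random coalescent-shaped tree over grouped tips."""
    groups = {}
    tips = []
    for gi in range(n_groups):
        for ti in range(rng.integers(1, max_tips_per_group + 1)):
            name = f"g{gi}_t{ti}"
            groups[name] = f"g{gi}"
            tips.append(name)
    nodes = [TreeNode(name=t, length=float(rng.random())) for t in tips]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = TreeNode(length=float(rng.random()),
                          children=[nodes.pop(j), nodes.pop(i)])
        nodes.append(parent)
    return TreeNode(children=nodes), groups


def test_topology_counts():
    assert [len(all_topologies(k)) for k in (3, 4, 5, 6)] == [1, 3, 15, 105]


def test_exact_weights_match_shearing_oracle(rng):
    for rep in range(12):
        n_groups = int(rng.integers(4, 6))
        tree, groups = random_group_tree(rng, n_groups, 3)
        rec = topology_weights(tree, groups, method="exact")
        got = {key_to_split_sets(k, rec.group_names): w
               for k, w in rec.weights.items()}
        want = brute_force_weights(tree, groups)
        assert set(got) == set(want)
        for topo, w in want.items():
            assert got[topo] == pytest.approx(w, abs=1e-12)


def test_sampled_weights_converge_to_exact(rng):
    tree, groups = random_group_tree(rng, 4, 2)
    exact = topology_weights(tree, groups, method="exact")
    n = 10_000
    sampled = topology_weights(tree, groups, method="sample", n_samples=n,
                               seed=3)
    for key, w in exact.weights.items():
        se = np.sqrt(max(w * (1 - w), 1e-12) / n)
        assert abs(sampled.weights.get(key, 0.0) - w) <= 3 * se + 1e-9


def test_single_tip_groups_give_unit_weight():
    tree = TreeNode.read(["((a,b),(c,d));"])
    rec = topology_weights(tree, {"a": "A", "b": "B", "c": "C", "d": "D"})
    assert len(rec.weights) == 1
    assert list(rec.weights.values()) == [1.0]


def test_five_group_weights_normalized(rng):
    tree, groups = random_group_tree(rng, 5, 3)
    rec = topology_weights(tree, groups)
    assert sum(rec.weights.values()) == pytest.approx(1.0, abs=1e-9)
    assert all(k in all_topologies(5) for k in rec.weights)


def test_weights_invariant_to_relabeling_within_group(rng):
    tree, groups = random_group_tree(rng, 4, 3)
    rec1 = topology_weights(tree, groups)
    # swap names of two tips in the same group (relabels tree tips)
    same = [t for t, g in groups.items() if g == "g0"]
    if len(same) >= 2:
        a, b = same[0], same[1]
        tree2 = tree.copy()
        for tip in tree2.tips():
            if tip.name == a:
                tip.name = b
            elif tip.name == b:
                tip.name = a
        rec2 = topology_weights(tree2, groups)
        for k in set(rec1.weights) | set(rec2.weights):
            assert rec1.weights.get(k, 0) == pytest.approx(
                rec2.weights.get(k, 0), abs=1e-12)


def test_group_absent_from_tree_raises():
    tree = TreeNode.read(["((a,b),(c,d));"])
    with pytest.raises(ValueError, match="absent"):
        topology_weights(tree, {"a": "A", "b": "B", "c": "C", "d": "D",
                                "zz": "E"})


# ---------------------------------------------------------------------------
# Neighbour joining
# ---------------------------------------------------------------------------


def window_from_matrix(D_haps, names):
    return HaplotypeWindow("c", 0, 100, np.asarray(D_haps, dtype=np.int8),
                           names, {n: n for n in names})


def test_nj_recovers_additive_tree():
    # additive distances: d(AB) = d(CD) = 2/6, all cross distances 4/6;
    # four-point condition gives split AB|CD with tip branches 1/6 and an
    # internal branch of 2/6
    haps = np.zeros((6, 4), dtype=np.int8)
    haps[0, 0] = 1           # A private site
    haps[1, 1] = 1           # B private site
    haps[2, 2] = 1           # C private site
    haps[3, 3] = 1           # D private site
    haps[4:6, 2:4] = 1       # two CD-clade characters
    win = window_from_matrix(haps, ["A", "B", "C", "D"])
    tree = nj_tree(win)
    rec = topology_weights(tree, {"A": "A", "B": "B", "C": "C", "D": "D"})
    ((key, w),) = rec.weights.items()
    assert w == 1.0
    assert key_to_split_sets(key, rec.group_names) == frozenset(
        {frozenset({frozenset({"A", "B"}), frozenset({"C", "D"})})})
    lengths = {t.name: t.length for t in tree.tips()}
    for tip in "ABCD":
        assert lengths[tip] == pytest.approx(1 / 6)
    internal = [n.length for n in tree.non_tips(include_self=False)]
    assert pytest.approx(2 / 6) in internal


def test_nj_three_tips_and_input_order_invariance(rng):
    haps = rng.integers(0, 2, size=(30, 5)).astype(np.int8)
    names = ["t4", "t2", "t0", "t3", "t1"]
    win1 = window_from_matrix(haps, names)
    order = [names.index(f"t{i}") for i in range(5)]
    win2 = window_from_matrix(haps[:, order], [f"t{i}" for i in range(5)])
    t1, t2 = nj_tree(win1), nj_tree(win2)
    r1 = topology_weights(t1, {n: n for n in names})
    r2 = topology_weights(t2, {n: n for n in names})
    assert r1.weights == r2.weights
    # three tips: the unique unrooted topology
    win3 = window_from_matrix(haps[:, :3], names[:3])
    rec3 = topology_weights(nj_tree(win3), {n: n for n in names[:3]})
    assert list(rec3.weights.values()) == [1.0]


def test_nj_zero_matrix_warns():
    win = window_from_matrix(np.zeros((5, 4), dtype=np.int8),
                             ["a", "b", "c", "d"])
    with pytest.warns(UserWarning, match="all-zero"):
        nj_tree(win)


# ---------------------------------------------------------------------------
# Haplotype windows
# ---------------------------------------------------------------------------


def test_haplotype_site_filters():
    # site 1: polymorphic outgroup -> excluded; site 2: MAF 0.04 -> excluded;
    # site 3: passes
    n_in = 25
    geno = np.array([
        [1] * n_in + [0, 1],          # outgroup heterozygous
        [1] + [0] * (n_in - 1) + [0, 0],  # ingroup MAF 1/50 = 0.02
        [1] * 10 + [0] * (n_in - 10) + [0, 0],
    ], dtype=np.int8)
    gm = make_gm(["chr1"] * 3, [10, 20, 30], geno, {"in": n_in, "og": 2})
    groups = {"A": [f"in{i}" for i in range(12)],
              "B": [f"in{i}" for i in range(12, 25)],
              "out": ["og0", "og1"]}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        wins = list(make_haplotypes(gm, groups, "out", window_snps=1, step=1,
                                    maf_min=0.05, seed=0))
    assert [w.start for w in wins] == [29]  # only site 3 retained


def test_haplotypes_deterministic_under_seed(random_gm):
    groups = {"A": [s for s in random_gm.samples if s.startswith("A")],
              "B": [s for s in random_gm.samples if s.startswith("B")][:2],
              "out": [s for s in random_gm.samples if s.startswith("B")][2:]}
    w1 = list(make_haplotypes(random_gm, groups, "out", 10, 10, 0.05, seed=5))
    w2 = list(make_haplotypes(random_gm, groups, "out", 10, 10, 0.05, seed=5))
    assert len(w1) == len(w2)
    for a, b in zip(w1, w2):
        assert np.array_equal(a.haps, b.haps)


# ---------------------------------------------------------------------------
# Classification and flagging
# ---------------------------------------------------------------------------


# five groups in the style of the three-species scan: one group per sister
# species, two donor populations, one outgroup
GROUPS5 = ["ele", "melAgl", "melAms", "out", "par"]
SPECIES5 = {"ele": "ele", "par": "par", "melAgl": "mel", "melAms": "mel",
            "out": "outgroup"}
# six groups in the style of the five-group geography scan plus donor
GROUPS6 = ["eleA", "eleB", "mel", "out", "parA", "parB"]
SPECIES6 = {"eleA": "ele", "eleB": "ele", "parA": "par", "parB": "par",
            "mel": "mel", "out": "outgroup"}


def record_from_newick(newick, groups):
    tree = TreeNode.read([newick])
    return topology_weights(tree, {g: g for g in groups})


def test_classify_reciprocal_monophyly_class():
    rec = record_from_newick("((((eleA,eleB),(parA,parB)),mel),out);", GROUPS6)
    cls = make_classifier(rec.group_names, SPECIES6, "ele", "par", "mel")
    assert classify_window(rec, cls) == "sister_pair_mono"


def test_classify_uniform_weights_unclassified():
    keys = all_topologies(5)
    rec = WeightRecord(GROUPS5, {k: 1 / 15 for k in keys}, 15, "exact")
    cls = make_classifier(GROUPS5, SPECIES5, "ele", "par", "mel")
    assert classify_window(rec, cls) == "unclassified"


def test_classify_introgression_class_at_point_six():
    intro = record_from_newick("(((melAgl,melAms),ele),(par,out));", GROUPS5)
    other = record_from_newick("((ele,(par,melAgl)),(melAms,out));", GROUPS5)
    (k1, _), = intro.weights.items()
    (k2, _), = other.weights.items()
    rec = WeightRecord(intro.group_names, {k1: 0.6, k2: 0.4}, 10, "exact")
    cls = make_classifier(rec.group_names, SPECIES5, "ele", "par", "mel")
    assert classify_window(rec, cls) == "other_pair_mono"


def test_classify_rejects_unnormalized():
    keys = all_topologies(5)
    rec = WeightRecord(GROUPS5, {keys[0]: 0.7}, 10, "exact")
    cls = make_classifier(GROUPS5, SPECIES5, "ele", "par", "mel")
    with pytest.raises(ValueError, match="sum"):
        classify_window(rec, cls)


def test_is_clade_trivial_sets():
    key = all_topologies(4)[0]
    assert is_clade(key, ["a", "b", "c", "d"], ["a"])
    assert is_clade(key, ["a", "b", "c", "d"], ["a", "b", "c"])


def test_flag_windows_threshold_and_merge():
    import pandas as pd
    tab = pd.DataFrame({
        "chrom": ["c"] * 3, "start": [0, 75, 300], "end": [100, 175, 400],
        "w": [0.79, 0.85, 0.9]})
    flagged = flag_windows(tab, "w", threshold=0.8)
    assert list(flagged) == [("c", 75, 175), ("c", 300, 400)]
    tab.loc[0, "w"] = 0.80   # boundary: >= threshold is flagged
    flagged = flag_windows(tab, "w", threshold=0.8)
    assert list(flagged) == [("c", 0, 175), ("c", 300, 400)]


def test_flagged_introgression_recovers_planted_truth(island_scans):
    """Pooled over replicate synthetic genomes, flagged introgression
    intervals recover >= 80% of planted introgressed bases with <= 10%
    false-positive bases."""
    scans = island_scans[:3]
    tp = sum(s.introgression_intervals.overlap_bases(s.truth_introgressed)
             for s in scans)
    truth = sum(s.truth_introgressed.total_bases() for s in scans)
    called = sum(s.introgression_intervals.total_bases() for s in scans)
    assert tp / truth >= 0.8
    assert (called - tp) / called <= 0.10


def test_species_tree_class_fraction_rises_with_isolation(island_scans):
    """Windows in planted islands carry the reciprocal-monophyly signal;
    background windows homogenized by gene flow do not."""
    s = island_scans[0]
    w = s.weights
    in_island = np.zeros(len(w), dtype=bool)
    for chrom, start, end in s.truth_islands:
        in_island |= ((w["chrom"] == chrom) & (w["start"] < end)
                      & (w["end"] > start)).to_numpy()
    assert w.loc[in_island, "w_species"].mean() > 0.9
    assert w.loc[~in_island, "w_species"].mean() < 0.3
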