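"""Tree analytics: NJ consistency, bootstrap, clade frequencies,
consensus, STAR and Robinson-Foulds, each against an independent oracle
(dendropy or brute-force enumeration)."""

import itertools

import dendropy
import numpy as np
import pytest

import coalscan as cs
from coalscan.gtree import GeneTree, TreeSet, root_at
from coalscan.trees import (
    bootstrap_trees, clade_frequencies, consensus_tree, jc_distance_matrix,
    nj_tree, rf_distance, star_species_tree, assemble_supermatrices,
)


def random_topology(labels, rng):
    """Random binary tree by sequential leaf attachment (newick string)."""
    nodes = [l for l in labels]
    rng.shuffle(nodes)
    tree = nodes[0]
    for lab in nodes[1:]:
        # attach at a random split point by wrapping a random subtree
        tree = f"({tree},{lab})" if rng.random() < 0.5 else f"({lab},{tree})"
        if rng.random() < 0.5 and tree.count("(") > 1:
            pass
    return tree + ";"


def random_tree(labels, rng):
    """Uniform-ish random binary topology via random pair joins."""
    items = [f"{l}:1" for l in labels]
    rng.shuffle(items)
    while len(items) > 1:
        i, j = sorted(rng.choice(len(items), size=2, replace=False))
        b = items.pop(j)
        a = items.pop(i)
        items.append(f"({a},{b}):1")
        rng.shuffle(items)
    return GeneTree.from_newick(items[0] + ";")


class TestNeighborJoining:
    def test_additive_matrix_recovered_exactly(self):
        """NJ is consistent on additive input: topology and branch
        lengths of the generating tree come back exactly."""
        # tree ((A:2,B:3):6,C:4,D:5) as unrooted distances
        labels = ["A", "B", "C", "D"]
        D = np.array([[0, 5, 12, 13],
                      [5, 0, 13, 14],
                      [12, 13, 0, 9],
                      [13, 14, 9, 0]], dtype=float)
        t = nj_tree(D, labels)
        uni = sorted(labels)
        cd = (1 << uni.index("C")) | (1 << uni.index("D"))
        assert t.bipartitions(uni) == {cd}  # the AB|CD split, A-side normalized
        # leaf branch lengths
        bl = {t.labels[i]: t.blen[i] for i in range(4)}
        assert bl["A"] == pytest.approx(2.0)
        assert bl["B"] == pytest.approx(3.0)

    def test_three_taxa_three_point_formulas(self):
        D = np.array([[0, 7, 9], [7, 0, 10], [9, 10, 0]], dtype=float)
        t = nj_tree(D, ["A", "B", "C"])
        bl = {t.labels[i]: t.blen[i] for i in range(3)}
        assert bl["A"] == pytest.approx((7 + 9 - 10) / 2)
        assert bl["B"] == pytest.approx((7 + 10 - 9) / 2)

    def test_deterministic_newick(self):
        rng = np.random.default_rng(0)
        D = rng.random((6, 6))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0)
        labels = list("ABCDEF")
        assert nj_tree(D, labels).to_newick() == nj_tree(D, labels).to_newick()

    def test_jc_undefined_names_pair(self):
        var = np.zeros((80, 3), dtype=np.int8)
        var[:, 1] = 1  # 80% mismatch A-B
        with pytest.raises(ValueError, match=r"\(A, B\)"):
            jc_distance_matrix(var, 100, ["A", "B", "C"])

    def test_long_internal_branch_recovers_species_topology(self, panel):
        """Clean-signal windows give the species quartet in nearly every
        simulated replicate."""
        nwk = "(((P1:10000,P2:10000):200000,P3:210000):100000,O:310000);"
        m = cs.SpeciesTreeModel.from_newick(nwk, ne=5000, mu=5e-8, outgroup="O")
        hits = 0
        n = 40
        for seed in range(n):
            cfg = cs.SimulationConfig(m, n_windows=1, window_length=20000,
                                      seed=900 + seed)
            sim = cs.simulate_genome(cfg, return_trees=False)
            var = sim.matrix.geno[:, :, 0]
            D = jc_distance_matrix(var, 20000, m.labels)
            t = nj_tree(D, m.labels)
            uni = sorted(m.labels)
            if ((1 << uni.index("P1")) | (1 << uni.index("P2"))) in t.bipartitions(uni):
                hits += 1
        assert hits >= n - 1


class TestBootstrap:
    def test_invariant_alignment_identical_star_trees(self):
        var = np.zeros((0, 4), dtype=np.int8)
        ts = bootstrap_trees(var, 500, list("ABCD"), b=5, seed=3)
        newicks = {t.to_newick() for t in ts}
        assert len(newicks) == 1

    def test_b_zero_empty(self):
        ts = bootstrap_trees(np.zeros((0, 4), dtype=np.int8), 100,
                             list("ABCD"), b=0)
        assert len(ts) == 0

    def test_clean_signal_high_support(self):
        """A strongly structured alignment puts the focal split in >=95%
        of replicates."""
        rng = np.random.default_rng(8)
        # 60 sites supporting AB|CD, 2 conflicting
        rows = [(0, 0, 1, 1)] * 60 + [(0, 1, 0, 1)] * 2
        var = np.array(rows, dtype=np.int8)
        ts = bootstrap_trees(var, 1000, list("ABCD"), b=100, seed=9)
        freqs = clade_frequencies(ts)
        assert freqs.get(frozenset("CD"), 0.0) >= 0.95

    def test_reproducible_under_seed(self):
        var = np.array([(0, 0, 1, 1)] * 10 + [(0, 1, 0, 1)] * 6, dtype=np.int8)
        a = bootstrap_trees(var, 200, list("ABCD"), b=10, seed=5)
        b = bootstrap_trees(var, 200, list("ABCD"), b=10, seed=5)
        assert [t.to_newick() for t in a] == [t.to_newick() for t in b]


class TestCladeFrequencies:
    def test_identical_trees_all_one(self):
        t = GeneTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        ts = TreeSet([t, t, t])
        for f in clade_frequencies(ts, rooted=True).values():
            assert f == 1.0

    def test_sixty_forty_mix(self):
        t1 = GeneTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        t2 = GeneTree.from_newick("((A:1,C:1):1,(B:1,D:1):1);")
        ts = TreeSet([t1] * 6 + [t2] * 4, taxa=list("ABCD"))
        freqs = clade_frequencies(ts)
        assert freqs[frozenset("CD")] == pytest.approx(0.6)
        assert freqs[frozenset("BD")] == pytest.approx(0.4)

    def test_against_bruteforce_enumeration(self):
        """Frequency table equals per-tree clade counting over random
        trees."""
        rng = np.random.default_rng(4)
        labels = list("ABCDEF")
        trees = [random_tree(labels, rng) for _ in range(40)]
        ts = TreeSet(trees, taxa=labels)
        freqs = clade_frequencies(ts, rooted=True)
        brute: dict[frozenset, int] = {}
        for t in trees:
            ch = t.children()
            seen = set()

            def leafset(i):
                if i < t.n_leaves:
                    return frozenset([t.labels[i]])
                out = frozenset()
                for c in ch[i]:
                    out |= leafset(c)
                return out

            for i in range(t.n_nodes):
                seen.add(leafset(i))
            for s in seen:
                brute[s] = brute.get(s, 0) + 1
        assert freqs == {s: c / 40 for s, c in brute.items()}


class TestConsensus:
    def test_identical_trees_returned_with_full_support(self):
        t = GeneTree.from_newick("((A:1,B:1):1,((C:1,D:1):1,E:1):1);")
        cons = consensus_tree(TreeSet([t] * 7))
        assert rf_distance(cons, t) == 0
        internal = cons.support[cons.n_leaves:]
        assert np.all(internal[np.isfinite(internal)] == 1.0)

    def test_majority_split_present_with_frequency_support(self):
        t1 = GeneTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        t2 = GeneTree.from_newick("((A:1,C:1):1,(B:1,D:1):1);")
        cons = consensus_tree(TreeSet([t1] * 7 + [t2] * 3, taxa=list("ABCD")))
        freqs = clade_frequencies(TreeSet([cons], taxa=list("ABCD")))
        assert frozenset("CD") in freqs
        sup = cons.support[np.isfinite(cons.support)]
        assert 0.7 in sup

    def test_greedy_compatible_prefix_oracle(self):
        """The consensus bipartition set equals the greedily compatible
        prefix of the frequency-sorted bipartition list."""
        rng = np.random.default_rng(12)
        labels = list("ABCDEFG")
        trees = [random_tree(labels, rng) for _ in range(25)]
        ts = TreeSet(trees, taxa=labels)
        cons = consensus_tree(ts)
        got = cons.bipartitions(labels)
        # oracle re-implementation
        counts: dict[int, int] = {}
        for t in trees:
            for m in t.bipartitions(labels):
                counts[m] = counts.get(m, 0) + 1

        def compat(a, b):
            return (a & b) in (0, a, b)

        kept: list[int] = []
        for m in sorted(counts, key=lambda m: (-counts[m], m)):
            if all(compat(m, k) for k in kept):
                kept.append(m)
        assert got == set(kept)

    def test_supports_equal_clade_frequencies(self):
        rng = np.random.default_rng(3)
        labels = list("ABCDE")
        ts = TreeSet([random_tree(labels, rng) for _ in range(20)], taxa=labels)
        freqs = clade_frequencies(ts)
        cons = consensus_tree(ts)
        masks = cons.leaf_masks(labels)
        for i in range(cons.n_leaves, cons.n_nodes):
            m = int(masks[i])
            members = frozenset(labels[k] for k in range(len(labels)) if m >> k & 1)
            if 2 <= len(members) <= len(labels) - 2 and np.isfinite(cons.support[i]):
                assert cons.support[i] == pytest.approx(freqs[members])


class TestStar:
    def test_concordant_input_returns_species_tree(self, panel):
        spt = panel.as_gene_tree()
        ts = TreeSet([spt] * 20, taxa=panel.labels)
        star = star_species_tree(ts, "WAR")
        assert rf_distance(star, spt) == 0

    def test_two_taxa_plus_outgroup(self):
        t = GeneTree.from_newick("((A:1,B:1):1,O:2);")
        star = star_species_tree(TreeSet([t] * 3), "O")
        assert set(star.labels) == {"A", "B", "O"}

    def test_input_order_invariance(self, panel):
        cfg = cs.SimulationConfig(panel, n_windows=150, window_length=5000, seed=77)
        sim = cs.simulate_genome(cfg)
        fwd = star_species_tree(sim.trees, "WAR")
        rev = star_species_tree(
            TreeSet(list(reversed(sim.trees.trees)), taxa=sim.trees.taxa), "WAR")
        assert fwd.to_newick() == rev.to_newick()

    def test_trees_missing_outgroup_skipped(self):
        good = GeneTree.from_newick("((A:1,B:1):1,O:2);")
        bad = GeneTree.from_newick("(A:1,B:1);")
        star = star_species_tree(TreeSet([good, good, bad], taxa=["A", "B", "O"]),
                                 "O")
        assert star.n_skipped == 1

    def test_msc_consistency_small(self, panel):
        """With 400 gene trees from the panel, STAR recovers the species
        topology (full-scale version in the acceptance suite)."""
        cfg = cs.SimulationConfig(panel, n_windows=400, window_length=5000, seed=55)
        sim = cs.simulate_genome(cfg)
        star = star_species_tree(sim.trees, "WAR")
        assert rf_distance(star, panel.as_gene_tree()) == 0


class TestRobinsonFoulds:
    def test_identity_and_bound(self):
        rng = np.random.default_rng(6)
        labels = list("ABCDEF")
        for _ in range(30):
            t1, t2 = random_tree(labels, rng), random_tree(labels, rng)
            assert rf_distance(t1, t1) == 0
            assert 0 <= rf_distance(t1, t2) <= 2 * (len(labels) - 3)

    def test_differing_leaf_sets_rejected(self):
        t1 = GeneTree.from_newick("((A:1,B:1):1,C:1);")
        t2 = GeneTree.from_newick("((A:1,B:1):1,D:1);")
        with pytest.raises(ValueError, match="leaf sets"):
            rf_distance(t1, t2)

    def test_against_dendropy_oracle(self):
        """Exact agreement with dendropy's symmetric difference on random
        6-taxon tree pairs."""
        rng = np.random.default_rng(13)
        labels = list("ABCDEF")
        tns = dendropy.TaxonNamespace()
        for _ in range(100):
            t1, t2 = random_tree(labels, rng), random_tree(labels, rng)
            d1 = dendropy.Tree.get(data=t1.to_newick(), schema="newick",
                                   taxon_namespace=tns)
            d2 = dendropy.Tree.get(data=t2.to_newick(), schema="newick",
                                   taxon_namespace=tns)
            expected = dendropy.calculate.treecompare.symmetric_difference(d1, d2)
            assert rf_distance(t1, t2) == expected

    def test_metric_properties(self):
        """Symmetry and triangle inequality on random triples."""
        rng = np.random.default_rng(21)
        labels = list("ABCDEFG")
        for _ in range(40):
            a, b, c = (random_tree(labels, rng) for _ in range(3))
            assert rf_distance(a, b) == rf_distance(b, a)
            assert rf_distance(a, c) <= rf_distance(a, b) + rf_distance(b, c)


class TestNewickIO:
    def test_roundtrip_preserves_topology_lengths_support(self, tmp_path):
        t = GeneTree.from_newick("((A:1.5,B:2.5)0.9:3,(C:1,D:1)0.8:2);",
                                 window=("1", 0, 5000))
        ts = TreeSet([t])
        ts.to_newick_file(tmp_path / "t.nwk")
        back = TreeSet.from_newick_file(tmp_path / "t.nwk")
        assert back[0].window == ("1", 0, 5000)
        assert rf_distance(back[0], t) == 0
        assert sorted(back[0].blen[:4]) == sorted(t.blen[:4])

    def test_root_at_outgroup(self):
        t = GeneTree.from_newick("(((A:1,B:1):1,C:2):1,(O:1,D:1):2);")
        rt = root_at(t, "O")
        assert rt.parent[rt.labels.index("O")] == rt.root
        assert rf_distance(rt, t) == 0  # unrooted topology unchanged


def test_assemble_supermatrices_without_replacement():
    lengths = [1000] * 300
    groups = assemble_supermatrices(lengths, 10_000, 20, seed=2)
    flat = [b for g in groups for b in g]
    assert len(flat) == len(set(flat))  # unique bins across groups
    for g in groups:
        assert sum(lengths[b] for b in g) >= 10_000
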