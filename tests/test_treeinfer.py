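import math

import dendropy
import numpy as np
import pytest

from perchronos import treeinfer as ti
from tests.conftest import make_alignment
from tests.oracles import (brute_force_gtr_lnl, naive_mcc_scores,
                           simulate_jc_alignment)


def tree_of(newick, rooted=None):
    t = dendropy.Tree.get(data=newick, schema="newick")
    if rooted is not None:
        t.is_rooted = rooted
    return t


JC = ti.GTRModel(ncat=1)


class TestLikelihood:
    def test_two_taxon_closed_form(self):
        """Per-site probabilities under equal rates follow
        3/4 (1 - exp(-4t/3)) for a mismatch."""
        a = make_alignment(["ACGTACGT", "ACGTACGA"])
        t = tree_of("(t0:0.05,t1:0.05);")
        d = 0.1
        p_same = 0.25 + 0.75 * math.exp(-4 * d / 3)
        p_diff_specific = (1 - p_same) / 3
        expected = 7 * math.log(0.25 * p_same) + math.log(
            0.25 * p_diff_specific)
        assert ti.tree_log_likelihood(t, a, JC) == pytest.approx(expected)

    def test_huge_alpha_collapses_to_single_rate(self):
        a = make_alignment(["ACGTACGTAC", "ACGTTCGTAC", "ACCTACGAAC"])
        t = tree_of("(t0:0.1,t1:0.2,t2:0.15);")
        near_clock = ti.GTRModel(alpha=1e6, ncat=4)
        single = ti.GTRModel(ncat=1)
        assert ti.tree_log_likelihood(t, a, near_clock) == pytest.approx(
            ti.tree_log_likelihood(t, a, single), abs=1e-6)

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(2)
        t = tree_of("((t0:0.1,t1:0.2):0.15,(t2:0.3,t3:0.05):0.12);",
                    rooted=True)
        rows = ["".join(rng.choice(list("ACGTRN-"), size=6))
                for _ in range(4)]
        a = make_alignment(rows)
        m = ti.GTRModel(exchangeabilities=tuple(rng.uniform(0.5, 2.0, 6)),
                        freqs=(0.3, 0.2, 0.25, 0.25), alpha=0.7, ncat=3)
        assert ti.tree_log_likelihood(t, a, m) == pytest.approx(
            brute_force_gtr_lnl(t, a, m), abs=1e-9)

    def test_invariant_to_rerooting(self):
        rng = np.random.default_rng(4)
        rows = ["".join(rng.choice(list("ACGT"), size=20)) for _ in range(5)]
        a = make_alignment(rows)
        t = tree_of("((t0:0.1,t1:0.2):0.05,t2:0.3,(t3:0.1,t4:0.25):0.12);")
        lnl = ti.tree_log_likelihood(t, a, ti.GTRModel(alpha=0.8))
        for leaf_label in ("t3", "t0"):
            rerooted = ti.root_with_outgroup(t, leaf_label)
            assert ti.tree_log_likelihood(
                rerooted, a, ti.GTRModel(alpha=0.8)) == pytest.approx(lnl)

    def test_tip_mismatch_raises(self):
        a = make_alignment(["ACGT", "ACGA"])
        t = tree_of("(x:0.1,y:0.1);")
        with pytest.raises(ti.TipMismatchError):
            ti.tree_log_likelihood(t, a, JC)

    def test_invalid_model_rejected(self):
        with pytest.raises(ti.TreeInferError):
            ti.GTRModel(freqs=(0.5, 0.5, 0.2, -0.2))
        with pytest.raises(ti.TreeInferError):
            ti.GTRModel(alpha=0.0)


class TestOptimization:
    def test_two_taxon_jc_inversion(self):
        """Recovered branch length matches -3/4 ln(1 - 4p/3) of the observed
        mismatch fraction."""
        true_t, a = simulate_jc_alignment("(a:0.04,b:0.04);", 20000, seed=9)
        tree = tree_of("(a:0.01,b:0.01);")
        engine = ti.LikelihoodEngine(a, JC)
        engine.optimize_branch_lengths(tree, max_sweeps=5)
        total = sum(n.edge.length for n in tree.preorder_node_iter()
                    if n.parent_node is not None)
        codes = a.matrix
        p_hat = float((codes[0] != codes[1]).mean())
        expected = -0.75 * math.log(1 - 4 * p_hat / 3)
        assert total == pytest.approx(expected, rel=1e-3)

    def test_optimum_is_fixed_point(self):
        _, a = simulate_jc_alignment(
            "((a:0.05,b:0.05):0.2,(c:0.05,d:0.05):0.2);", 3000, seed=1)
        tree = ti.neighbor_joining_tree(a)
        engine = ti.LikelihoodEngine(a, JC)
        engine.optimize_branch_lengths(tree, max_sweeps=6)
        before = [n.edge.length for n in tree.preorder_node_iter()
                  if n.parent_node is not None]
        engine.optimize_branch_lengths(tree, max_sweeps=1)
        after = [n.edge.length for n in tree.preorder_node_iter()
                 if n.parent_node is not None]
        assert np.allclose(before, after, rtol=0.02, atol=1e-6)

    def test_ascent_contract(self):
        _, a = simulate_jc_alignment(
            "((a:0.05,b:0.08):0.2,(c:0.02,d:0.05):0.2);", 2000, seed=5)
        tree = ti.neighbor_joining_tree(a)
        engine = ti.LikelihoodEngine(a, JC)
        lnls = [engine.log_likelihood(tree)]
        for _ in range(4):
            lnls.append(engine.optimize_branch_lengths(tree, max_sweeps=1))
        assert all(b >= a_ - 1e-6 for a_, b in zip(lnls, lnls[1:]))

    def test_optimize_parameters_improves_and_returns_alpha(self):
        _, a = simulate_jc_alignment(
            "((a:0.1,b:0.1):0.2,(c:0.1,d:0.1):0.2);", 1500, seed=3)
        tree = ti.neighbor_joining_tree(a)
        start_lnl = ti.tree_log_likelihood(tree, a, ti.GTRModel(alpha=0.2))
        _, model, lnl = ti.optimize_parameters(tree, a,
                                               ti.GTRModel(alpha=0.2),
                                               max_rounds=2)
        assert lnl >= start_lnl
        assert model.alpha > 0.2  # JC data has no rate variation


class TestSearch:
    def test_three_taxa_unique_topology(self):
        _, a = simulate_jc_alignment("(a:0.1,b:0.1,c:0.1);", 500, seed=2)
        t = ti.search_topology(a, JC)
        assert {lf.taxon.label for lf in t.leaf_node_iter()} == {"a", "b", "c"}

    def test_recovers_long_internal_branch(self):
        true, a = simulate_jc_alignment(
            "((a:0.05,b:0.05):0.5,(c:0.05,d:0.05):0.5);", 2000, seed=7)
        best = ti.search_topology(a, JC)
        assert ti.topologies_identical(best, true)

    def test_search_beats_start_tree(self):
        _, a = simulate_jc_alignment(
            "((a:0.05,b:0.05):0.3,(c:0.05,d:0.05):0.3);", 1000, seed=8)
        engine = ti.LikelihoodEngine(a, JC)
        nj = ti.neighbor_joining_tree(a)
        start_lnl = engine.log_likelihood(nj)
        best = ti.search_topology(a, JC, engine=engine)
        assert engine.log_likelihood(best) >= start_lnl

    def test_six_taxon_recovery_rate(self):
        """Searches on data simulated from known 6-taxon trees recover the
        generating topology in >= 90% of seeded runs."""
        newick = ("(((a:0.05,b:0.05):0.1,c:0.15):0.1,"
                  "((d:0.05,e:0.05):0.1,f:0.15):0.1);")
        hits = 0
        for seed in range(20):
            true, a = simulate_jc_alignment(newick, 2000, seed=seed)
            best = ti.search_topology(a, JC)
            hits += ti.topologies_identical(best, true)
        assert hits >= 18

    def test_too_few_taxa_rejected(self):
        a = make_alignment(["ACGT", "ACGA"])
        with pytest.raises(ti.TreeInferError):
            ti.search_topology(a, JC)


class TestBootstrap:
    def test_strong_signal_support(self):
        true, a = simulate_jc_alignment(
            "((a:0.05,b:0.05):0.5,(c:0.05,d:0.05):0.5);", 2000, seed=7)
        tree, supports = ti.bootstrap_support(a, JC, 100, seed=1)
        assert all(0 <= v <= 100 for v in supports.values())
        assert min(supports.values()) >= 95

    def test_supports_invariant_to_tip_order(self):
        _, a = simulate_jc_alignment(
            "((a:0.1,b:0.1):0.3,(c:0.1,d:0.1):0.3);", 800, seed=4)
        perm = a.subset(["d", "b", "c", "a"])
        _, s1 = ti.bootstrap_support(a, JC, 25, seed=6)
        _, s2 = ti.bootstrap_support(perm, JC, 25, seed=6)
        assert sorted(s1.values()) == sorted(s2.values())


class TestTreeSetSummaries:
    def trees(self, newicks):
        tn = dendropy.TaxonNamespace()
        out = []
        for nwk in newicks:
            t = dendropy.Tree.get(data=nwk, schema="newick",
                                  taxon_namespace=tn)
            t.is_rooted = True
            out.append(t)
        return out

    def test_clade_frequency_enumeration(self):
        ts = self.trees(["((A,B),C);", "((A,B),C);", "((A,C),B);"])
        freq = ti.clade_frequencies(ts)
        assert freq[frozenset({"A", "B"})] == pytest.approx(2 / 3)
        assert freq[frozenset({"A", "C"})] == pytest.approx(1 / 3)
        assert freq[frozenset({"A"})] == 1.0
        assert freq[frozenset({"A", "B", "C"})] == 1.0

    def test_mixed_tip_sets_rejected(self):
        ts = self.trees(["((A,B),C);"]) + self.trees(["((A,B),D);"])
        with pytest.raises(ti.TreeInferError):
            ti.clade_frequencies(ts)

    def test_mcc_selects_majority_tree(self):
        ts = self.trees(["((A,B),C);", "((A,B),C);", "((A,C),B);"])
        best = ti.mcc_tree(ts)
        assert best is ts[0]  # ties broken by lowest index
        freq = ti.clade_frequencies(ts)
        scores = [ti.mcc_score(t, freq) for t in ts]
        assert scores == pytest.approx(naive_mcc_scores(ts))

    def test_mcc_is_member_and_maximal(self):
        rng = np.random.default_rng(12)
        labels = list("ABCDEF")
        newicks = []
        for _ in range(20):
            order = list(rng.permutation(labels))
            nwk = f"(({order[0]},{order[1]}),(({order[2]},{order[3]}),({order[4]},{order[5]})));"
            newicks.append(nwk)
        ts = self.trees(newicks)
        best = ti.mcc_tree(ts)
        assert best in ts
        scores = naive_mcc_scores(ts)
        assert scores[ts.index(best)] == pytest.approx(max(scores))

    def test_consensus_of_identical_trees(self):
        ts = self.trees(["((A,B),(C,D));"] * 3)
        cons = ti.majority_consensus(ts, 0.5)
        assert ti.topologies_identical(cons, ts[0])

    def test_conflicting_resolutions_give_star(self):
        ts = self.trees(["((A,B),(C,D));", "((A,C),(B,D));",
                         "((A,D),(B,C));"])
        cons = ti.majority_consensus(ts, 0.5)
        internal = [n for n in cons.preorder_node_iter()
                    if not n.is_leaf() and n.parent_node is not None]
        assert internal == []

    def test_consensus_clades_are_observed_clades(self):
        ts = self.trees(["((A,B),(C,D));", "((A,B),(C,D));",
                         "(((A,B),C),D);"])
        cons = ti.majority_consensus(ts, 0.5)
        observed = set()
        for t in ts:
            observed |= set(ti.clade_frequencies([t]))
        for node in cons.preorder_node_iter():
            clade = frozenset(lf.taxon.label for lf in node.leaf_iter())
            assert clade in observed

    def test_low_threshold_rejected(self):
        ts = self.trees(["((A,B),C);"])
        with pytest.raises(ti.TreeInferError):
            ti.majority_consensus(ts, 0.3)


class TestTreeUtilities:
    def test_prune_preserves_path_lengths(self):
        t = tree_of("((A:1,B:1):1,C:2);", rooted=True)
        pruned = ti.prune_tip(t, "C")
        pdm = pruned.phylogenetic_distance_matrix()
        taxa = {x.label: x for x in pruned.taxon_namespace}
        assert pdm.patristic_distance(
            taxa["A"], taxa["B"]) == pytest.approx(2.0)

    def test_prune_round_trips_through_newick(self):
        t = tree_of("(((A:1,B:2):1,C:3):1,(D:1,E:1):2);", rooted=True)
        pruned = ti.prune_tip(t, "B")
        back = ti.read_newick(pruned.as_string(schema="newick"))
        labels = {lf.taxon.label for lf in back.leaf_node_iter()}
        assert labels == {"A", "C", "D", "E"}
        pdm = back.phylogenetic_distance_matrix()
        taxa = {x.label: x for x in back.taxon_namespace}
        assert pdm.patristic_distance(
            taxa["A"], taxa["C"]) == pytest.approx(5.0)

    def test_prune_unknown_tip_rejected(self):
        t = tree_of("((A:1,B:1):1,C:2);")
        with pytest.raises(ti.TreeInferError):
            ti.prune_tip(t, "Z")

    def test_prune_to_fewer_than_two_tips_rejected(self):
        t = tree_of("(A:1,B:1);")
        with pytest.raises(ti.TreeInferError):
            ti.prune_tip(t, "A")

    def test_topology_identity_ignores_branch_lengths(self):
        t1 = tree_of("((A:1,B:1):1,(C:1,D:1):1);")
        t2 = tree_of("((A:9,B:2):5,(C:1,D:7):3);")
        assert ti.topologies_identical(t1, t2)
        assert ti.topologies_identical(t2, t1)
        assert ti.topologies_identical(t1, t1)

    def test_nni_neighbour_topologies_differ(self):
        t1 = tree_of("((A,B),(C,D));")
        t2 = tree_of("((A,C),(B,D));")
        assert not ti.topologies_identical(t1, t2)

    def test_tip_set_mismatch_rejected(self):
        with pytest.raises(ti.TreeInferError):
            ti.topologies_identical(tree_of("((A,B),C);"),
                                    tree_of("((A,B),D);"))
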