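"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately avoid the package's pruning code paths: likelihoods are
computed by exhaustive enumeration of ancestral state assignments (and
cladogenetic events, for the range models), P distances by per-site loops,
and MCC scores by naive membership counting.
"""

import itertools
import math

import numpy as np
from scipy.linalg import expm

BASES = "ACGT"
AMBIG = {"R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
         "N": "ACGT", "-": "ACGT", "?": "ACGT",
         **{b: b for b in BASES}}


def brute_force_gtr_lnl(tree, aln, model) -> float:
    """Sum over all internal-state assignments, per site, per gamma category."""
    q = model.q_matrix()
    pi = np.asarray(model.freqs)
    rates = model.category_rates()
    nodes = list(tree.postorder_node_iter())
    internals = [n for n in nodes if not n.is_leaf()]
    rows = {ind: aln.row(ind) for ind in aln.individuals}
    total = 0.0
    for site in range(aln.n_sites):
        site_lik = 0.0
        for r in rates:
            pmats = {n: expm(q * r * float(n.edge.length or 0.0))
                     for n in nodes if n.parent_node is not None}
            acc = 0.0
            for assign in itertools.product(range(4), repeat=len(internals)):
                amap = dict(zip(internals, assign))
                p = pi[amap[tree.seed_node]]
                for n in nodes:
                    if n.parent_node is None:
                        continue
                    sp = amap[n.parent_node]
                    if n.is_leaf():
                        ch = rows[n.taxon.label][site]
                        p *= sum(pmats[n][sp, BASES.index(b)]
                                 for b in AMBIG[ch])
                    else:
                        p *= pmats[n][sp, amap[n]]
                acc += p
            site_lik += acc / len(rates)
        total += math.log(site_lik)
    return total


def brute_force_range_lnl(tree, rd, model, params) -> float:
    """Enumerate ancestral range states and cladogenetic events."""
    from perchronos.rangeevol import (anagenetic_rate_matrix,
                                      cladogenesis_table,
                                      enumerate_range_states)

    states = enumerate_range_states(rd.areas, rd.max_range)
    index = {s: i for i, s in enumerate(states)}
    q = anagenetic_rate_matrix(params, states, rd.areas)
    nodes = list(tree.postorder_node_iter())
    internals = [n for n in nodes if not n.is_leaf()]
    tables = {i: cladogenesis_table(model, s, params, rd.areas, rd.max_range)
              for i, s in enumerate(states)}
    pmat = {n: expm(q * float(n.edge.length or 0.0))
            for n in nodes if n.parent_node is not None}
    total = 0.0
    for assign in itertools.product(range(len(states)),
                                    repeat=len(internals)):
        amap = dict(zip(internals, assign))
        for events in itertools.product(
                *[list(tables[amap[n]].items()) for n in internals]):
            emap = dict(zip(internals, events))
            p = 1.0 / len(states)
            for n in internals:
                (dl, dr), w = emap[n]
                p *= w
                for ch, dstate in zip(n.child_nodes(), (dl, dr)):
                    if ch.is_leaf():
                        target = index[rd.tip_ranges[ch.taxon.label]]
                    else:
                        target = amap[ch]
                    p *= pmat[ch][index[dstate], target]
            total += p
    return math.log(total)


def per_site_p_distance(seq_a: str, seq_b: str):
    """(distance, n_comparable); None distance when no comparable sites."""
    comparable = 0
    mismatches = 0
    for x, y in zip(seq_a, seq_b):
        if x in BASES and y in BASES:
            comparable += 1
            if x != y:
                mismatches += 1
    if comparable == 0:
        return None, 0
    return mismatches / comparable, comparable


def naive_clade_frequencies(trees):
    """Clade frequency table by naive membership counting."""
    def clades(t):
        out = []
        for node in t.preorder_node_iter():
            out.append(frozenset(lf.taxon.label for lf in node.leaf_iter()))
        return out

    freq = {}
    for t in trees:
        for c in set(clades(t)):
            freq[c] = freq.get(c, 0) + 1
    return {c: k / len(trees) for c, k in freq.items()}


def naive_mcc_scores(trees):
    freq = naive_clade_frequencies(trees)
    scores = []
    for t in trees:
        s = 0.0
        for node in t.preorder_node_iter():
            clade = frozenset(lf.taxon.label for lf in node.leaf_iter())
            s += math.log(freq[clade])
        scores.append(s)
    return scores


def simulate_jc_alignment(newick, nsites, seed):
    """Plain Jukes-Cantor simulation used as a search-recovery oracle."""
    import dendropy

    from perchronos.radmatrix import ConcatenatedAlignment

    tree = dendropy.Tree.get(data=newick, schema="newick")
    rng = np.random.default_rng(seed)
    state = {tree.seed_node: rng.integers(0, 4, nsites)}
    seqs = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        b = float(node.edge.length or 0.0)
        p_same = 0.25 + 0.75 * math.exp(-4.0 * b / 3.0)
        s = state[node.parent_node].copy()
        mut = rng.random(nsites) > p_same
        s[mut] = (s[mut] + rng.integers(1, 4, int(mut.sum()))) % 4
        state[node] = s
        if node.is_leaf():
            seqs[node.taxon.label] = s
    inds = sorted(seqs)
    mat = np.frombuffer(
        "".join("ACGT"[x] for ind in inds for x in seqs[ind]).encode(),
        dtype="S1").reshape(len(inds), nsites).copy()
    return tree, ConcatenatedAlignment(inds, mat, {"all": (0, nsites)})
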