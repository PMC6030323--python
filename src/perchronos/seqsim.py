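"""Synthetic ddRAD phylogenomic data with known truth.

Emulates the structure of a ddRAD phylogenomic study of a few dozen diploid
individuals: a Yule species tree rescaled to a known root age; per-branch
substitution rates, either strict-clock or autocorrelated lognormal;
thousands of short loci evolved under GTR+Gamma; diploid heterozygosity
applied phenomenologically (a per-site second allele produced by one extra
substitution event, encoded as a two-base IUPAC code); per-individual locus
dropout producing locus-level missing data; and binary East/West tip ranges
simulated under a DEC-family model (anagenesis by Gillespie draws along
branches, a cladogenetic event at every node).

Defaults mirror the study conditions this generator stands in for: 45 tips,
80 bp loci, a 20 Ma root, a mean rate of 9.67e-4 substitutions/site/Myr,
and a founder-event-dominated DIVALIKE+J range process (d = e = 1e-12,
j = 0.0972) from an eastern root.  Diploidy is deliberately phenomenological
(no coalescent gene trees): enough to exercise RRHS pseudo-phasing, not a
model of linked heterozygosity.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .radmatrix import HET_CODES, IndividualInfo, Locus, LocusMatrix
from .rangeevol import (BiogeoParams, RangeData, anagenetic_rate_matrix,
                        cladogenesis_table, enumerate_range_states)
from .treeinfer import GTRModel

_PAIR_TO_CODE = {frozenset(v): k for k, v in HET_CODES.items()}


@dataclass
class SimConfig:
    seed: int = 0
    n_tips: int = 45
    birth_rate: float = 0.2          # Yule speciation rate, per Myr
    root_age: float = 20.0           # Ma
    mean_rate: float = 9.67e-4       # substitutions/site/Myr
    rate_sigma: float = 0.1          # lognormal autocorrelation (0 = clock)
    n_loci: int = 2000
    locus_length: int = 80
    heterozygosity: float = 0.005    # per-site second-allele probability
    dropout: float = 0.15            # per-individual, per-locus loss
    model: GTRModel = field(default_factory=lambda: GTRModel(alpha=1.0))
    range_model: str = "DIVALIKE+J"
    range_params: BiogeoParams = field(
        default_factory=lambda: BiogeoParams(d=1e-12, e=1e-12, j=0.0972))
    root_range: frozenset = frozenset({"E"})
    areas: tuple = ("E", "W")
    max_range: int = 2

    def __post_init__(self):
        if self.n_tips < 3:
            raise ValueError("n_tips must be >= 3")
        for p in (self.heterozygosity, self.dropout):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.mean_rate < 0 or self.rate_sigma < 0 or self.birth_rate <= 0:
            raise ValueError("rates must be non-negative")


def simulate_species_tree(cfg: SimConfig) -> dendropy.Tree:
    """Yule tree with ``n_tips`` rescaled so the root age equals
    ``root_age`` (Ma); ultrametric, tips at age 0, labels t01, t02, ..."""
    from dendropy.simulate import treesim

    tree = treesim.birth_death_tree(
        birth_rate=cfg.birth_rate, death_rate=0.0,
        num_extant_tips=cfg.n_tips, rng=random.Random(int(cfg.seed)),
    )
    tree.is_rooted = True
    # the simulator stops exactly at the n-th speciation, leaving the newest
    # cherry with zero-length tips; extend all tips by the waiting time to
    # the next event (the proper Yule sample conditioned on n tips)
    tail_rng = np.random.default_rng([int(cfg.seed), 7])
    tail = tail_rng.exponential(1.0 / (cfg.birth_rate * cfg.n_tips))
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + tail
    width = len(str(cfg.n_tips))
    tn = dendropy.TaxonNamespace()
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon = tn.new_taxon(label=f"t{i:0{width}d}")
    tree.taxon_namespace = tn
    tree.update_taxon_namespace()
    _set_ages(tree)
    scale = cfg.root_age / tree.seed_node.age
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = edge.length * scale
    _set_ages(tree)
    return tree


def _set_ages(tree) -> None:
    for node in tree.postorder_node_iter():
        node.age = 0.0 if node.is_leaf() else max(
            c.age + float(c.edge.length or 0.0) for c in node.child_nodes())


def simulate_branch_rates(tree: dendropy.Tree, cfg: SimConfig) -> dict:
    """Autocorrelated lognormal rates: each child branch's rate is its
    parent branch's rate times a lognormal(0, sigma^2) deviate; branches off
    the root start at the mean rate.  Keyed by child node."""
    rng = np.random.default_rng([int(cfg.seed), 1])
    rates: dict = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        if node.parent_node.parent_node is None:
            rates[node] = cfg.mean_rate
        else:
            rates[node] = (rates[node.parent_node]
                           * rng.lognormal(0.0, cfg.rate_sigma))
    return rates


def _second_allele(states, q, rng):
    """One jump-chain substitution from each state (off-diagonal draw)."""
    out = np.empty_like(states)
    for s in range(4):
        idx = np.flatnonzero(states == s)
        if len(idx) == 0:
            continue
        w = q[s].copy()
        w[s] = 0.0
        w = w / w.sum()
        out[idx] = rng.choice(4, size=len(idx), p=w)
    return out


def simulate_rad_matrix(tree: dendropy.Tree, rates: dict,
                        cfg: SimConfig,
                        ranges: RangeData | None = None) -> LocusMatrix:
    """Evolve ``n_loci`` loci of ``locus_length`` bp under GTR+Gamma along
    the dated tree with per-branch substitution lengths rate x duration,
    apply per-site heterozygosity (IUPAC-coded second alleles) and
    per-individual locus dropout."""
    rng = np.random.default_rng([int(cfg.seed), 2])
    model = cfg.model
    from .treeinfer import _Eigen

    eig = _Eigen(model)
    cat_rates = model.category_rates()
    q = model.q_matrix()
    L = cfg.n_loci * cfg.locus_length
    freqs = np.asarray(model.freqs)
    site_cat = rng.integers(0, len(cat_rates), size=L)
    states = {tree.seed_node: rng.choice(4, size=L, p=freqs)}
    bases = np.frombuffer(b"ACGT", dtype="S1")
    tip_chars: dict[str, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        blen = rates[node] * float(node.edge.length or 0.0)
        pmats = [eig.p_matrix(blen * r) for r in cat_rates]
        parent = states[node.parent_node]
        new = np.empty_like(parent)
        for c in range(len(cat_rates)):
            for s in range(4):
                idx = np.flatnonzero((site_cat == c) & (parent == s))
                if len(idx):
                    new[idx] = rng.choice(4, size=len(idx), p=pmats[c][s])
        states[node] = new
        if node.is_leaf():
            chars = bases[new].copy()
            if cfg.heterozygosity > 0:
                het = rng.random(L) < cfg.heterozygosity
                if het.any():
                    second = _second_allele(new[het], q, rng)
                    codes = [
                        _PAIR_TO_CODE[frozenset(("ACGT"[a], "ACGT"[b]))]
                        for a, b in zip(new[het], second)
                    ]
                    chars[het] = np.array([c.encode() for c in codes],
                                          dtype="S1")
            tip_chars[node.taxon.label] = chars
    individuals = sorted(tip_chars)
    metadata = {}
    region_of = {}
    if ranges is not None:
        for tip, rg in ranges.tip_ranges.items():
            region_of[tip] = sorted(rg)[0]
    for ind in individuals:
        metadata[ind] = IndividualInfo(population=ind, species=ind,
                                       region=region_of.get(ind, "E"))
    loci = []
    for li in range(cfg.n_loci):
        start = li * cfg.locus_length
        seqs = {}
        for ind in individuals:
            if cfg.dropout > 0 and rng.random() < cfg.dropout:
                continue
            chunk = tip_chars[ind][start:start + cfg.locus_length]
            seqs[ind] = chunk.tobytes().decode("ascii")
        loci.append(Locus(f"L{li + 1:05d}", cfg.locus_length, seqs))
    return LocusMatrix(loci, individuals, metadata)


def simulate_tip_ranges(tree: dendropy.Tree, cfg: SimConfig) -> RangeData:
    """Simulate ranges forward along the dated tree: Gillespie anagenesis
    from the rate matrix plus one cladogenetic draw per internal node."""
    rng = np.random.default_rng([int(cfg.seed), 3])
    states = enumerate_range_states(cfg.areas, cfg.max_range)
    index = {s: i for i, s in enumerate(states)}
    q = anagenetic_rate_matrix(cfg.range_params, states, cfg.areas)

    def gillespie(i, duration):
        t = 0.0
        while True:
            rate = -q[i, i]
            if rate <= 0:
                return i
            t += rng.exponential(1.0 / rate)
            if t >= duration:
                return i
            probs = q[i].copy()
            probs[i] = 0.0
            i = int(rng.choice(len(states), p=probs / rate))

    node_state = {tree.seed_node: index[frozenset(cfg.root_range)]}
    tip_ranges = {}
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            tip_ranges[node.taxon.label] = states[node_state[node]]
            continue
        table = cladogenesis_table(cfg.range_model, states[node_state[node]],
                                   cfg.range_params, cfg.areas, cfg.max_range)
        pairs = list(table.items())
        pick = int(rng.choice(len(pairs), p=[w for _, w in pairs]))
        daughters = pairs[pick][0]
        children = node.child_nodes()
        assert len(children) == 2, "range simulation needs a binary tree"
        for ch, dstate in zip(children, daughters):
            node_state[ch] = gillespie(index[dstate],
                                       float(ch.edge.length or 0.0))
    return RangeData(cfg.areas, tip_ranges, cfg.max_range)


@dataclass
class SimulatedDataset:
    config: SimConfig
    tree: dendropy.Tree           # true chronogram (ages in Ma)
    branch_rates: dict            # child node -> subs/site/Myr
    ranges: RangeData
    matrix: LocusMatrix


def simulate_dataset(cfg: SimConfig) -> SimulatedDataset:
    """Tree + rates + ranges + locus matrix, all from one seed."""
    tree = simulate_species_tree(cfg)
    rates = simulate_branch_rates(tree, cfg)
    ranges = simulate_tip_ranges(tree, cfg)
    matrix = simulate_rad_matrix(tree, rates, cfg, ranges=ranges)
    return SimulatedDataset(cfg, tree, rates, ranges, matrix)
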