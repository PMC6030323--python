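"""Ancestral range estimation under DEC, DIVALIKE, BAYAREALIKE and +J.

Ranges are non-empty subsets of a small area list (capped at ``max_range``
areas; the null range is excluded from the state space).  Anagenetic change
along branches is a continuous-time Markov chain: single-area gains at rate
``d`` per addable area and single-area losses at rate ``e`` per removable
area (losses from singleton ranges are disallowed, as the null range is not
a state).  At cladogenesis the ancestral range is partitioned between the
two daughters according to a model-specific table over ordered daughter
pairs:

* narrow sympatry  (y): singleton ancestor copied to both daughters;
* subset sympatry  (s): one daughter keeps the full range, the other one
  area of it (widespread ancestors only);
* vicariance       (v): the range is split into two disjoint parts, at
  least one a singleton;
* widespread copy  (w): a widespread range copied to both daughters;
* founder event    (j): one daughter keeps the range, the other jumps to a
  single area *outside* it.

DEC allows {y,s,v}, DIVALIKE {y,v}, BAYAREALIKE {y,w}; the +J variants add
founder events with weight ``j`` while scaling the other allowed event types
by ``(3-j)/3``.  Each ordered event's probability is its weight over the
state's total weight.  Likelihoods are computed by pruning with matrix
exponentials along branches and the cladogenesis distribution at internal
nodes (including the root), with a uniform root prior over states; fits are
compared by AIC = 2k - 2 lnL.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import minimize

MODELS = ("DEC", "DEC+J", "DIVALIKE", "DIVALIKE+J",
          "BAYAREALIKE", "BAYAREALIKE+J")


class RangeModelError(ValueError):
    pass


@dataclass(frozen=True)
class BiogeoParams:
    d: float  # per-area dispersal (gain) rate, per Myr
    e: float  # per-area extinction (loss) rate, per Myr
    j: float = 0.0  # founder-event weight, in [0, 3]

    def __post_init__(self):
        if self.d < 0 or self.e < 0 or not 0 <= self.j <= 3:
            raise RangeModelError("need d, e >= 0 and 0 <= j <= 3")


@dataclass
class RangeData:
    areas: tuple
    tip_ranges: dict  # tip label -> frozenset of areas
    max_range: int = 2

    def __post_init__(self):
        areas = set(self.areas)
        for tip, rng in self.tip_ranges.items():
            rng = frozenset(rng)
            self.tip_ranges[tip] = rng
            if not rng or not rng <= areas or len(rng) > self.max_range:
                raise RangeModelError(f"invalid range for tip {tip}: {rng}")


@dataclass
class RangeModelFit:
    model: str
    params: BiogeoParams
    lnl: float
    k: int
    aic: float
    node_marginals: pd.DataFrame  # node clade x state probability


# ---------------------------------------------------------------------------
# State space and rates
# ---------------------------------------------------------------------------

def enumerate_range_states(areas, max_range: int) -> list[frozenset]:
    """All non-empty subsets of <= max_range areas; singletons first, then
    pairs, etc., in area-list order within each size."""
    if max_range < 1:
        raise RangeModelError("max_range must be >= 1")
    states = []
    for size in range(1, min(max_range, len(areas)) + 1):
        for combo in itertools.combinations(areas, size):
            states.append(frozenset(combo))
    return states


def anagenetic_rate_matrix(p: BiogeoParams, states: list[frozenset],
                           areas=None) -> np.ndarray:
    """Gain/loss rate matrix over range states (rows sum to zero)."""
    if areas is None:
        areas = sorted(set().union(*states))
    index = {s: i for i, s in enumerate(states)}
    n = len(states)
    q = np.zeros((n, n))
    for s, i in index.items():
        for a in areas:
            if a not in s:
                gained = s | {a}
                if gained in index:
                    q[i, index[gained]] += p.d
            elif len(s) > 1:
                lost = s - {a}
                if lost in index:
                    q[i, index[lost]] += p.e
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


# ---------------------------------------------------------------------------
# Cladogenesis
# ---------------------------------------------------------------------------

def _event_weights(model: str, j: float) -> dict:
    base = {"DEC": {"y": 1.0, "s": 1.0, "v": 1.0, "w": 0.0},
            "DIVALIKE": {"y": 1.0, "s": 0.0, "v": 1.0, "w": 0.0},
            "BAYAREALIKE": {"y": 1.0, "s": 0.0, "v": 0.0, "w": 1.0}}
    plus_j = model.endswith("+J")
    stem = model[:-2] if plus_j else model
    if stem not in base:
        raise RangeModelError(f"unknown model '{model}'")
    w = dict(base[stem])
    if plus_j:
        scale = (3.0 - j) / 3.0
        w = {k: v * scale for k, v in w.items()}
        w["j"] = j
    else:
        w["j"] = 0.0
    return w


def cladogenesis_table(model: str, state: frozenset, p: BiogeoParams,
                       areas, max_range: int = 2) -> dict:
    """Distribution over ordered daughter-range pairs for one parent state."""
    if not state:
        raise RangeModelError("empty parent state")
    if len(state) > max_range:
        raise RangeModelError("state exceeds max range")
    w = _event_weights(model, p.j)
    events: dict[tuple, float] = {}

    def add(left, right, weight):
        if weight <= 0:
            return
        key = (frozenset(left), frozenset(right))
        events[key] = events.get(key, 0.0) + weight

    if len(state) == 1:
        add(state, state, w["y"])
    else:
        for a in sorted(state):
            add(state, {a}, w["s"])
            add({a}, state, w["s"])
        for size in range(1, len(state)):
            for part in itertools.combinations(sorted(state), size):
                left = frozenset(part)
                right = state - left
                if min(len(left), len(right)) == 1:
                    add(left, right, w["v"])
        add(state, state, w["w"])
    for a in areas:
        if a not in state:
            add(state, {a}, w["j"])
            add({a}, state, w["j"])
    total = sum(events.values())
    if total <= 0:
        # degenerate weighting (e.g. j == 3): fall back to narrow sympatry
        return {(state, state): 1.0}
    # canonical order, independent of per-process hash randomization
    ordered = sorted(events.items(),
                     key=lambda kv: (sorted(kv[0][0]), sorted(kv[0][1])))
    return {k: v / total for k, v in ordered}


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

def _tables_by_state(model, p, states, areas, max_range):
    index = {s: i for i, s in enumerate(states)}
    out = []
    for s in states:
        table = cladogenesis_table(model, s, p, areas, max_range)
        out.append([(index[a], index[b], prob)
                    for (a, b), prob in table.items()])
    return out


def range_log_likelihood(chron, rd: RangeData, model: str, p: BiogeoParams,
                         root_cladogenesis: bool = True,
                         clamp: dict | None = None) -> float:
    """Pruning log-likelihood of tip ranges on a dated tree.

    ``chron`` is a Chronogram or a dendropy Tree with branch lengths in Myr.
    ``clamp`` optionally restricts named internal nodes (frozenset of tip
    labels -> state index) for marginal computation.
    """
    tree = chron.tree if hasattr(chron, "tree") else chron
    states = enumerate_range_states(rd.areas, rd.max_range)
    index = {s: i for i, s in enumerate(states)}
    tips = {lf.taxon.label for lf in tree.leaf_node_iter()}
    if tips != set(rd.tip_ranges):
        raise RangeModelError("chronogram tips and range data tips differ")
    q = anagenetic_rate_matrix(p, states, rd.areas)
    tables = _tables_by_state(model, p, states, rd.areas, rd.max_range)
    nst = len(states)
    part: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            v = np.zeros(nst)
            v[index[rd.tip_ranges[node.taxon.label]]] = 1.0
        else:
            downs = []
            for ch in node.child_nodes():
                pmat = expm(q * float(ch.edge.length or 0.0))
                downs.append(pmat @ part[ch])
            if len(downs) == 1:  # unifurcate root: no cladogenetic event
                v = downs[0]
            elif len(downs) != 2:
                raise RangeModelError("tree must be binary for cladogenesis")
            elif node.parent_node is None and not root_cladogenesis:
                v = downs[0] * downs[1]
            else:
                v = np.zeros(nst)
                for i in range(nst):
                    v[i] = sum(prob * downs[0][a] * downs[1][b]
                               for a, b, prob in tables[i])
        if clamp is not None and not node.is_leaf():
            clade = frozenset(lf.taxon.label for lf in node.leaf_iter())
            if clade in clamp:
                keep = clamp[clade]
                masked = np.zeros(nst)
                masked[keep] = v[keep]
                v = masked
        part[node] = v
    root_lik = part[tree.seed_node].sum() / nst  # uniform prior over states
    if root_lik <= 0:
        return -math.inf
    return float(math.log(root_lik))


def node_marginals(chron, rd: RangeData, model: str, p: BiogeoParams,
                   root_cladogenesis: bool = True) -> pd.DataFrame:
    """Marginal probability of each range state at each internal node,
    computed by state clamping (relative clamped likelihoods)."""
    tree = chron.tree if hasattr(chron, "tree") else chron
    states = enumerate_range_states(rd.areas, rd.max_range)
    labels = ["+".join(sorted(s)) for s in states]
    total = range_log_likelihood(chron, rd, model, p, root_cladogenesis)
    rows = []
    for node in tree.postorder_internal_node_iter():
        clade = frozenset(lf.taxon.label for lf in node.leaf_iter())
        liks = []
        for i in range(len(states)):
            lnl = range_log_likelihood(chron, rd, model, p,
                                       root_cladogenesis, clamp={clade: i})
            liks.append(math.exp(lnl - total) if lnl > -math.inf else 0.0)
        liks = np.array(liks)
        liks = liks / liks.sum()
        rows.append({"clade": "|".join(sorted(clade)),
                     **dict(zip(labels, liks))})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Fitting and model comparison
# ---------------------------------------------------------------------------

def aic(lnl: float, k: int) -> float:
    """Akaike information criterion, 2k - 2 lnL."""
    if k < 0:
        raise RangeModelError("k must be >= 0")
    return 2.0 * k - 2.0 * lnl


D_E_BOUNDS = (1e-12, 10.0)
J_BOUNDS = (0.0, 3.0)


def fit_range_model(chron, rd: RangeData, model: str, n_starts: int = 4,
                    seed: int = 0, root_cladogenesis: bool = True,
                    compute_marginals: bool = True) -> RangeModelFit:
    """Maximum-likelihood fit of one range model (bounded multi-start)."""
    plus_j = model.endswith("+J")
    k = 3 if plus_j else 2
    lo_d, hi_d = math.log10(D_E_BOUNDS[0]), math.log10(D_E_BOUNDS[1])

    def unpack(x):
        d, e = 10.0 ** x[0], 10.0 ** x[1]
        j = min(max(x[2], J_BOUNDS[0]), J_BOUNDS[1] - 1e-9) if plus_j else 0.0
        return BiogeoParams(d=d, e=e, j=j)

    def nll(x):
        try:
            lnl = range_log_likelihood(chron, rd, model, unpack(x),
                                       root_cladogenesis)
        except (RangeModelError, ValueError):
            return 1e10
        return -lnl if math.isfinite(lnl) else 1e10

    rng = np.random.default_rng([seed, 99])
    starts = [np.array([-2.0, -2.0, 0.1]), np.array([-2.0, -2.0, 0.0])]
    for _ in range(n_starts - 1):
        starts.append(np.array([
            rng.uniform(-8, 0), rng.uniform(-8, 0), rng.uniform(0.0, 1.0),
        ]))
    bounds = [(lo_d, hi_d), (lo_d, hi_d),
              (J_BOUNDS[0], J_BOUNDS[1] - 1e-6)]
    best = None
    for x0 in starts:
        if not plus_j:
            x0 = x0.copy()
            x0[2] = 0.0
        res = minimize(nll, x0, method="L-BFGS-B", bounds=bounds
                       if plus_j else bounds[:2] + [(0.0, 0.0)])
        if not math.isfinite(res.fun):
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise RangeModelError(
            f"optimizer failed for {model}: no start reached a finite "
            "likelihood")
    params = unpack(best.x)
    lnl = -float(best.fun)
    marg = (node_marginals(chron, rd, model, params, root_cladogenesis)
            if compute_marginals else pd.DataFrame())
    return RangeModelFit(model, params, lnl, k, aic(lnl, k), marg)


def compare_models(fits: list[RangeModelFit]) -> pd.DataFrame:
    """Model-comparison table sorted by AIC with a delta-AIC column."""
    if not fits:
        raise RangeModelError("no fits to compare")
    rows = [{"model": f.model, "lnL": f.lnl, "d": f.params.d,
             "e": f.params.e, "J": f.params.j, "k": f.k, "AIC": f.aic}
            for f in fits]
    frame = pd.DataFrame(rows).sort_values("AIC", kind="stable")
    frame["dAIC"] = frame["AIC"] - frame["AIC"].min()
    return frame.reset_index(drop=True)


def fit_all_models(chron, rd: RangeData, seed: int = 0,
                   root_cladogenesis: bool = True,
                   compute_marginals: bool = True) -> list[RangeModelFit]:
    return [fit_range_model(chron, rd, m, seed=seed,
                            root_cladogenesis=root_cladogenesis,
                            compute_marginals=compute_marginals)
            for m in MODELS]


# ---------------------------------------------------------------------------
# Species-tree collapse
# ---------------------------------------------------------------------------

def collapse_to_species_tree(chron, mapping: dict):
    """Collapse a dated individual-level tree to one tip per species.

    Each species' tips must be monophyletic.  The representative tip's
    pendant branch is extended to the species crown's parent edge, so all
    between-species node ages are preserved.  Returns a new dendropy tree
    (ultrametric, tips at age 0) with tips renamed to species.
    """
    tree = (chron.tree if hasattr(chron, "tree") else chron).clone(depth=1)
    # node ages from current edge lengths
    for node in tree.postorder_node_iter():
        node.age = 0.0 if node.is_leaf() else (
            max(c.age + float(c.edge.length or 0.0)
                for c in node.child_nodes()))
    species_tips: dict[str, list] = {}
    for leaf in tree.leaf_node_iter():
        sp = mapping[leaf.taxon.label]
        species_tips.setdefault(sp, []).append(leaf)
    crowns = {}
    for sp, leaves in species_tips.items():
        if len(leaves) == 1:
            continue
        labels = [lf.taxon.label for lf in leaves]
        crown = tree.mrca(taxon_labels=labels)
        below = {lf.taxon.label for lf in crown.leaf_iter()}
        if below != set(labels):
            raise RangeModelError(
                f"species '{sp}' is not monophyletic "
                f"(clade below MRCA: {sorted(below)})"
            )
        crowns[sp] = crown
    for sp, crown in crowns.items():
        leaves = species_tips[sp]
        # replace the crown clade by a single tip spanning the crown's edge
        parent = crown.parent_node
        keep = leaves[0]
        if parent is None:
            raise RangeModelError(
                f"species '{sp}' spans the root; cannot collapse"
            )
        stem_len = crown.age + float(crown.edge.length or 0.0)
        parent.remove_child(crown)
        new_leaf = dendropy.Node(taxon=keep.taxon)
        parent.add_child(new_leaf)
        new_leaf.edge.length = stem_len
        new_leaf.age = 0.0
    # rename representative tips to species labels
    tn = dendropy.TaxonNamespace()
    for leaf in tree.leaf_node_iter():
        leaf.taxon = tn.new_taxon(label=mapping[leaf.taxon.label])
    tree.taxon_namespace = tn
    tree.update_taxon_namespace()
    return tree
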