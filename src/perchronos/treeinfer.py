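"""Maximum-likelihood tree inference under GTR+Gamma and tree-set summaries.

The likelihood engine implements Felsenstein pruning over site patterns with
a discrete-gamma model of among-site rate variation (4 equal-probability
categories, conditional-mean rates, mean-normalized).  No invariant-sites
class is modelled.  Ambiguity codes and missing characters enter as partial
likelihoods (1 for every compatible state).

Topology search is neighbour-joining followed by NNI hill-climbing; bootstrap
supports come from standard nonparametric site resampling (implemented as a
multinomial draw over site patterns, which is distributionally identical).
Tree containers are :class:`dendropy.Tree`; tree sets are summarized either
as a maximum clade credibility (MCC) tree — the member tree maximizing the
sum of log clade frequencies — or as a majority-rule consensus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import dendropy
import numpy as np
from dendropy.calculate import treecompare
from scipy.optimize import minimize, minimize_scalar
from scipy.stats import gamma as gamma_dist

from .radmatrix import ConcatenatedAlignment, HET_CODES

BL_MIN = 1e-8  # floor for zero-length branches (numerical stability)
BL_MAX = 10.0

_EXCH_ORDER = ("AC", "AG", "AT", "CG", "CT", "GT")  # GT fixed to 1


class TreeInferError(ValueError):
    pass


class TipMismatchError(TreeInferError):
    pass


# ---------------------------------------------------------------------------
# Substitution model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GTRModel:
    """GTR+Gamma model: 6 exchangeabilities (GT == 1), base frequencies,
    gamma shape alpha, and the number of discrete rate categories."""

    exchangeabilities: tuple = (1.0, 1.0, 1.0, 1.0, 1.0, 1.0)
    freqs: tuple = (0.25, 0.25, 0.25, 0.25)
    alpha: float = 1.0
    ncat: int = 4

    def __post_init__(self):
        if len(self.exchangeabilities) != 6 or any(
            x <= 0 for x in self.exchangeabilities
        ):
            raise TreeInferError("need 6 positive exchangeabilities")
        if len(self.freqs) != 4 or any(f <= 0 for f in self.freqs):
            raise TreeInferError("need 4 positive base frequencies")
        if abs(sum(self.freqs) - 1.0) > 1e-6:
            raise TreeInferError("base frequencies must sum to 1")
        if self.alpha <= 0 or self.ncat < 1:
            raise TreeInferError("alpha > 0 and ncat >= 1 required")

    def q_matrix(self) -> np.ndarray:
        """Rate matrix normalized to mean rate 1 at stationarity."""
        s = np.zeros((4, 4))
        ac, ag, at, cg, ct, gt = self.exchangeabilities
        s[0, 1] = s[1, 0] = ac
        s[0, 2] = s[2, 0] = ag
        s[0, 3] = s[3, 0] = at
        s[1, 2] = s[2, 1] = cg
        s[1, 3] = s[3, 1] = ct
        s[2, 3] = s[3, 2] = gt
        pi = np.asarray(self.freqs)
        q = s * pi[None, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        mu = -float(np.dot(pi, np.diag(q)))
        return q / mu

    def category_rates(self) -> np.ndarray:
        """Conditional-mean rates of ``ncat`` equal-probability gamma slices,
        renormalized to mean exactly 1."""
        if self.ncat == 1:
            return np.ones(1)
        a = self.alpha
        cuts = gamma_dist.ppf(np.arange(1, self.ncat) / self.ncat, a,
                              scale=1.0 / a)
        upper = np.concatenate([cuts, [np.inf]])
        lower = np.concatenate([[0.0], cuts])
        # E[X; X<c] for Gamma(a, 1/a) is F_{a+1,1/a}(c) since the mean is 1
        mass = (gamma_dist.cdf(upper, a + 1, scale=1.0 / a)
                - gamma_dist.cdf(lower, a + 1, scale=1.0 / a))
        rates = self.ncat * mass
        return rates / rates.mean()


class _Eigen:
    """Spectral decomposition of a reversible Q for fast P(t)."""

    def __init__(self, model: GTRModel):
        q = model.q_matrix()
        pi = np.asarray(model.freqs)
        d = np.sqrt(pi)
        b = (q * d[:, None]) / d[None, :]
        b = 0.5 * (b + b.T)  # enforce symmetry against roundoff
        w, v = np.linalg.eigh(b)
        self.w = w
        self.left = v / d[:, None]
        self.right = v.T * d[None, :]

    def p_matrix(self, t: float) -> np.ndarray:
        p = (self.left * np.exp(self.w * t)) @ self.right
        return np.clip(p, 0.0, None)


def _optimize_blen(neg_lnl, b0, widen=8.0):
    """1-D branch-length optimization in a relative bracket around ``b0``,
    re-expanding (up to 3 times) when the optimum lands on the bracket edge."""
    b0 = min(max(b0, BL_MIN), BL_MAX)
    lo, hi = max(BL_MIN, b0 / widen), min(BL_MAX, b0 * widen + 1e-4)
    for _ in range(3):
        res = minimize_scalar(neg_lnl, bounds=(lo, hi), method="bounded",
                              options={"xatol": max(1e-8, 0.005 * b0)})
        edge_lo = res.x < lo * 1.05 and lo > BL_MIN
        edge_hi = res.x > hi * 0.95 and hi < BL_MAX
        if not (edge_lo or edge_hi):
            break
        b0 = float(res.x)
        lo, hi = max(BL_MIN, b0 / widen ** 2), min(BL_MAX, b0 * widen ** 2)
    return res


def empirical_frequencies(a: ConcatenatedAlignment) -> tuple:
    """Observed A/C/G/T frequencies with a half-count prior."""
    flat = a.matrix.view(np.uint8).ravel()
    counts = np.array([np.sum(flat == ord(b)) for b in "ACGT"], dtype=float)
    counts += 0.5
    return tuple(counts / counts.sum())


# ---------------------------------------------------------------------------
# Tip partials & pattern compression
# ---------------------------------------------------------------------------

def _char_partial_table() -> np.ndarray:
    table = np.zeros((256, 4))
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    for b, i in base_idx.items():
        table[ord(b), i] = 1.0
    for code, pair in HET_CODES.items():
        for b in pair:
            table[ord(code), base_idx[b]] = 1.0
    for c in "N-?":
        table[ord(c)] = 1.0
    return table


_CHAR_PARTIAL = _char_partial_table()


def compress_alignment(a: ConcatenatedAlignment):
    """Unique site patterns and their counts: ((ntaxa, npat) uint8, counts)."""
    cols = np.ascontiguousarray(a.matrix.view(np.uint8).T)
    patterns, counts = np.unique(cols, axis=0, return_counts=True)
    return patterns.T, counts.astype(float)


# ---------------------------------------------------------------------------
# Likelihood engine
# ---------------------------------------------------------------------------

class LikelihoodEngine:
    """Felsenstein pruning over compressed site patterns for one alignment."""

    def __init__(self, alignment: ConcatenatedAlignment, model: GTRModel,
                 patterns=None, counts=None):
        self.alignment = alignment
        self.tip_index = {ind: i for i, ind in enumerate(alignment.individuals)}
        if patterns is None:
            patterns, counts = compress_alignment(alignment)
        self.patterns = patterns
        self.counts = counts
        self.n_sites = float(counts.sum())
        # tip partials: (ntaxa, npat, 4)
        self.tip_partials = _CHAR_PARTIAL[patterns]
        self.set_model(model)

    def set_model(self, model: GTRModel) -> None:
        self.model = model
        self._eigen = _Eigen(model)
        self.cat_rates = model.category_rates()
        self.pi = np.asarray(model.freqs)

    def with_counts(self, counts: np.ndarray) -> "LikelihoodEngine":
        eng = object.__new__(LikelihoodEngine)
        eng.alignment = self.alignment
        eng.tip_index = self.tip_index
        mask = counts > 0  # patterns drawn zero times carry no information
        eng.patterns = self.patterns[:, mask]
        eng.counts = counts[mask].astype(float)
        eng.n_sites = float(eng.counts.sum())
        eng.tip_partials = self.tip_partials[:, mask, :]
        eng.set_model(self.model)
        return eng

    # -- internals ----------------------------------------------------------

    def _pmats(self, blen: float) -> np.ndarray:
        b = max(float(blen), BL_MIN)
        return np.stack([self._eigen.p_matrix(b * r) for r in self.cat_rates])

    def _check_tips(self, tree: dendropy.Tree) -> None:
        labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
        unknown = labels - set(self.tip_index)
        if unknown:
            raise TipMismatchError(f"tree tips not in alignment: {sorted(unknown)}")

    def _lowers(self, tree: dendropy.Tree):
        """Postorder partials.  Returns dicts: L[node] (ncat,npat,4),
        ls[node] (npat,) log-scale, contrib[node] = P_edge applied to L."""
        ncat, npat = len(self.cat_rates), self.patterns.shape[1]
        L, ls, contrib = {}, {}, {}
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                tp = self.tip_partials[self.tip_index[node.taxon.label]]
                L[node] = np.broadcast_to(tp, (ncat, npat, 4))
                ls[node] = np.zeros(npat)
            else:
                kids = node.child_nodes()
                part = contrib[kids[0]].copy()
                scale = ls[kids[0]].copy()
                for ch in kids[1:]:
                    part *= contrib[ch]
                    scale += ls[ch]
                m = part.max(axis=(0, 2))
                m = np.where(m > 0, m, 1.0)
                L[node] = part / m[None, :, None]
                ls[node] = scale + np.log(m)
            if node.parent_node is not None:
                p = self._pmats(node.edge.length or BL_MIN)
                # contrib(x) = sum_y P_xy L(y), per category
                contrib[node] = L[node] @ p.transpose(0, 2, 1)
        return L, ls, contrib

    def log_likelihood(self, tree: dendropy.Tree) -> float:
        self._check_tips(tree)
        L, ls, _ = self._lowers(tree)
        root = tree.seed_node
        site = np.einsum("cpi,i->p", L[root], self.pi) / len(self.cat_rates)
        site = np.maximum(site, 1e-300)
        return float(np.dot(self.counts, np.log(site) + ls[root]))

    def _outs(self, tree, L, ls, contrib):
        """Preorder outside partials Out[node] with log-scales lsOut[node]."""
        Out, lsOut = {}, {}
        root = tree.seed_node
        ncat, npat = len(self.cat_rates), self.patterns.shape[1]
        Out[root] = np.ones((ncat, npat, 4))
        lsOut[root] = np.zeros(npat)
        for node in tree.preorder_node_iter():
            if node.is_leaf():
                continue
            children = node.child_nodes()
            for ch in children:
                m = Out[node].copy()
                sc = lsOut[node].copy()
                for sib in children:
                    if sib is not ch:
                        m = m * contrib[sib]
                        sc = sc + ls[sib]
                p = self._pmats(ch.edge.length or BL_MIN)
                # Out_c(y) = sum_x P_yx(b_c) M(x)
                o = m @ p.transpose(0, 2, 1)
                mx = o.max(axis=(0, 2))
                mx = np.where(mx > 0, mx, 1.0)
                Out[ch] = o / mx[None, :, None]
                lsOut[ch] = sc + np.log(mx)
        return Out, lsOut

    def _edge_context(self, tree, child):
        """Precompute (E, L_child, scale) so the likelihood is a cheap
        function of this one edge's length."""
        L, ls, contrib = self._lowers(tree)
        Out, lsOut = self._outs(tree, L, ls, contrib)
        v = child.parent_node
        e = Out[v] * self.pi[None, None, :]
        sc = lsOut[v].copy()
        for sib in v.child_nodes():
            if sib is not child:
                e = e * contrib[sib]
                sc = sc + ls[sib]
        return e, L[child], sc + ls[child]

    def _edge_lnl(self, e, lchild, scale, blen) -> float:
        p = self._pmats(blen)
        c = lchild @ p.transpose(0, 2, 1)
        site = np.multiply(e, c).sum(axis=(0, 2)) / len(self.cat_rates)
        site = np.maximum(site, 1e-300)
        return float(np.dot(self.counts, np.log(site) + scale))

    def _edge_w(self, e, lchild) -> np.ndarray:
        """Per-pattern outer product e_i * L_j flattened over (cat, i, j), so
        the site likelihood is a single mat-vec in the P(t) entries."""
        ncat, npat = e.shape[0], e.shape[1]
        # build in (pat, cat, i, j) layout so the final reshape is a view
        et = np.swapaxes(e, 0, 1)[:, :, :, None]
        lt = np.swapaxes(lchild, 0, 1)[:, :, None, :]
        return np.multiply(et, lt).reshape(npat, ncat * 16)

    def _edge_lnl_w(self, w, scale, blen) -> float:
        pvec = self._pmats(blen).reshape(-1) / len(self.cat_rates)
        site = w @ pvec
        site = np.maximum(site, 1e-300)
        return float(np.dot(self.counts, np.log(site) + scale))

    # -- optimization -------------------------------------------------------

    def optimize_edge(self, tree, child, xatol=1e-6) -> float:
        """Optimize a single branch length in place; returns the lnL."""
        e, lch, sc = self._edge_context(tree, child)
        b0 = child.edge.length or BL_MIN
        lnl0 = self._edge_lnl(e, lch, sc, b0)
        res = minimize_scalar(lambda b: -self._edge_lnl(e, lch, sc, b),
                              bounds=(BL_MIN, BL_MAX), method="bounded",
                              options={"xatol": xatol})
        if -res.fun > lnl0:
            child.edge.length = float(res.x)
            return float(-res.fun)
        return lnl0

    def optimize_branch_lengths(self, tree, max_sweeps=3, tol=1e-4) -> float:
        """Coordinate ascent over all branch lengths; returns the final lnL.

        Each sweep makes one postorder pass (lower partials), then walks the
        tree in preorder maintaining exact outside partials, optimizing every
        branch against cached contexts and updating the caches incrementally
        — so every 1-D optimization sees the true current likelihood.
        """
        self._check_tips(tree)
        lnl = self.log_likelihood(tree)
        pit = self.pi[None, None, :]
        for _ in range(max_sweeps):
            L, ls, contrib = self._lowers(tree)
            root = tree.seed_node
            ncat, npat = len(self.cat_rates), self.patterns.shape[1]
            Out = {root: np.ones((ncat, npat, 4))}
            lsOut = {root: np.zeros(npat)}
            stack = [root]
            lnl_sweep = lnl
            while stack:
                v = stack.pop()
                children = v.child_nodes()
                for c in children:
                    e = Out[v] * pit
                    sc = lsOut[v].copy()
                    for s in children:
                        if s is not c:
                            e = e * contrib[s]
                            sc = sc + ls[s]
                    scale = sc + ls[c]
                    b0 = c.edge.length or BL_MIN
                    w = self._edge_w(e, L[c])
                    res = _optimize_blen(
                        lambda b: -self._edge_lnl_w(w, scale, b), b0)
                    lnl_here = self._edge_lnl_w(w, scale, b0)
                    if -res.fun > lnl_here:
                        c.edge.length = float(res.x)
                        lnl_sweep = float(-res.fun)
                        p = self._pmats(c.edge.length)
                        contrib[c] = L[c] @ p.transpose(0, 2, 1)
                    else:
                        lnl_sweep = lnl_here
                for c in children:
                    if c.is_leaf():
                        continue
                    m = Out[v]
                    sc = lsOut[v]
                    for s in children:
                        if s is not c:
                            m = m * contrib[s]
                            sc = sc + ls[s]
                    p = self._pmats(c.edge.length or BL_MIN)
                    o = m @ p.transpose(0, 2, 1)
                    mx = o.max(axis=(0, 2))
                    mx = np.where(mx > 0, mx, 1.0)
                    Out[c] = o / mx[None, :, None]
                    lsOut[c] = sc + np.log(mx)
                    stack.append(c)
            if lnl_sweep - lnl < tol:
                lnl = max(lnl, lnl_sweep)
                break
            lnl = lnl_sweep
        return lnl


def _nni_scan(engine: LikelihoodEngine, tree, tol):
    """One NNI round from cached partials: for every internal edge, score
    both neighbour topologies with the central branch re-optimized, all
    without touching the tree.  Returns the best improving move or None."""
    L, ls, contrib = engine._lowers(tree)
    Out, lsOut = engine._outs(tree, L, ls, contrib)
    pit = engine.pi[None, None, :]
    best = None
    for c, d in _internal_edges(tree):
        kids = c.child_nodes()
        if len(kids) != 2:
            continue
        a_n, b_n = kids
        v = c.parent_node
        rest = [s for s in v.child_nodes() if s is not c and s is not d]
        base = Out[v] * pit
        sc_base = lsOut[v].copy()
        for s in rest:
            base = base * contrib[s]
            sc_base = sc_base + ls[s]
        cur_e = base * contrib[d]
        cur = engine._edge_lnl(cur_e, L[c], sc_base + ls[d] + ls[c],
                               c.edge.length or BL_MIN)
        for swap_in, keep in ((a_n, b_n), (b_n, a_n)):
            # neighbour topology: swap_in moves up beside v, d down beside keep
            e = base * contrib[swap_in]
            lc = contrib[d] * contrib[keep]
            scale = sc_base + ls[swap_in] + ls[d] + ls[keep]
            w = engine._edge_w(e, lc)
            res = _optimize_blen(
                lambda b: -engine._edge_lnl_w(w, scale, b),
                c.edge.length or BL_MIN)
            delta = float(-res.fun) - cur
            if delta > tol and (best is None or delta > best[0]):
                best = (delta, c, d, swap_in, float(res.x))
    return best


def tree_log_likelihood(tree: dendropy.Tree, a: ConcatenatedAlignment,
                        model: GTRModel) -> float:
    """Pruning-algorithm log-likelihood of ``tree`` under GTR+Gamma."""
    return LikelihoodEngine(a, model).log_likelihood(tree)


def optimize_parameters(tree: dendropy.Tree, a: ConcatenatedAlignment,
                        model: GTRModel, optimize_model: str = "alpha",
                        max_rounds: int = 5, tol: float = 1e-3):
    """Coordinate ascent over branch lengths and model parameters.

    ``optimize_model``: 'none' (branch lengths only), 'alpha', or 'full'
    (alpha + exchangeabilities + frequencies).  Returns
    ``(tree, model, lnL)``; the tree is modified in place.
    """
    engine = LikelihoodEngine(a, model)
    lnl = engine.optimize_branch_lengths(tree)
    for _ in range(max_rounds):
        lnl_prev = lnl
        if optimize_model in ("alpha", "full") and model.ncat > 1:
            def f_alpha(log_a):
                engine.set_model(replace(model, alpha=math.exp(log_a)))
                return -engine.log_likelihood(tree)
            res = minimize_scalar(f_alpha, bounds=(math.log(0.02),
                                                   math.log(100.0)),
                                  method="bounded", options={"xatol": 1e-3})
            model = replace(model, alpha=float(math.exp(res.x)))
            engine.set_model(model)
        if optimize_model == "full":
            def f_full(x):
                exch = tuple(np.exp(x[:5])) + (1.0,)
                fr = np.exp(x[5:8])
                fr = np.concatenate([fr, [1.0]])
                fr = tuple(fr / fr.sum())
                try:
                    engine.set_model(replace(model, exchangeabilities=exch,
                                             freqs=fr))
                except TreeInferError:
                    return 1e12
                return -engine.log_likelihood(tree)
            x0 = np.concatenate([
                np.log(np.asarray(model.exchangeabilities[:5])),
                np.log(np.asarray(model.freqs[:3]) / model.freqs[3]),
            ])
            res = minimize(f_full, x0, method="L-BFGS-B",
                           options={"maxiter": 60})
            exch = tuple(np.exp(res.x[:5])) + (1.0,)
            fr = np.exp(res.x[5:8])
            fr = np.concatenate([fr, [1.0]])
            model = replace(model, exchangeabilities=exch,
                            freqs=tuple(fr / fr.sum()))
            engine.set_model(model)
        lnl = engine.optimize_branch_lengths(tree)
        if lnl - lnl_prev < tol:
            break
    return tree, model, lnl


# ---------------------------------------------------------------------------
# Start tree & topology search
# ---------------------------------------------------------------------------

def neighbor_joining_tree(a: ConcatenatedAlignment,
                          taxon_namespace=None) -> dendropy.Tree:
    """NJ start tree on uncorrected P distances (NaN overlaps imputed to the
    largest finite distance; negative NJ branch lengths floored)."""
    from skbio import DistanceMatrix as SkDM
    from skbio.tree import nj

    from .radmatrix import p_distance_matrix

    d = p_distance_matrix(a)
    vals = d.values.copy()
    if np.isnan(vals).any():
        finite_max = np.nanmax(vals)
        vals = np.where(np.isnan(vals), finite_max if finite_max > 0 else 0.5,
                        vals)
    np.fill_diagonal(vals, 0.0)
    tn = nj(SkDM(vals, ids=list(a.individuals)))
    tree = dendropy.Tree.get(data=str(tn), schema="newick",
                             taxon_namespace=taxon_namespace)
    tree.is_rooted = False
    for edge in tree.preorder_edge_iter():
        if edge.length is None or edge.length < BL_MIN:
            edge.length = BL_MIN
    return tree


@dataclass
class SearchConfig:
    max_nni_rounds: int = 20
    bl_sweeps: int = 2
    tol: float = 1e-3
    final_bl_sweeps: int = 3


def _nni_swap(x, y):
    """Exchange subtrees x and y (children of adjacent internal nodes)."""
    px, py = x.parent_node, y.parent_node
    px.remove_child(x)
    py.remove_child(y)
    px.add_child(y)
    py.add_child(x)


def _internal_edges(tree):
    edges = []
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        v = node.parent_node
        others = [c for c in v.child_nodes() if c is not node]
        if not others:
            continue
        edges.append((node, others[0]))
    return edges


def search_topology(a: ConcatenatedAlignment, model: GTRModel,
                    config: SearchConfig | None = None,
                    engine: LikelihoodEngine | None = None,
                    start_tree: dendropy.Tree | None = None) -> dendropy.Tree:
    """NNI hill-climbing ML search from a neighbour-joining start tree.

    Deterministic: edges are scanned in preorder and the best improving
    swap (first index on ties) is accepted each round.
    """
    if a.n_individuals < 3:
        raise TreeInferError("topology search needs >= 3 taxa")
    config = config or SearchConfig()
    engine = engine or LikelihoodEngine(a, model)
    tree = start_tree if start_tree is not None else neighbor_joining_tree(a)
    engine.optimize_branch_lengths(tree, max_sweeps=config.bl_sweeps)
    for _ in range(config.max_nni_rounds):
        best = _nni_scan(engine, tree, config.tol)
        if best is None:
            break
        _, c, d, grand, blen = best
        _nni_swap(d, grand)
        c.edge.length = blen
        engine.optimize_branch_lengths(tree, max_sweeps=config.bl_sweeps)
    engine.optimize_branch_lengths(tree, max_sweeps=config.final_bl_sweeps)
    return tree


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def bootstrap_support(a: ConcatenatedAlignment, model: GTRModel, n: int,
                      seed: int, best_tree: dendropy.Tree | None = None,
                      config: SearchConfig | None = None):
    """Nonparametric bootstrap clade support mapped onto the ML tree.

    Site resampling is performed as a multinomial draw over compressed site
    patterns (equivalent in distribution to resampling columns).  Replicate
    searches hill-climb from the ML tree.  Returns ``(tree, supports)`` where
    internal-node labels carry percentages.
    """
    if n < 1:
        raise TreeInferError("n must be >= 1")
    config = config or SearchConfig(bl_sweeps=1, final_bl_sweeps=1)
    engine = LikelihoodEngine(a, model)
    if best_tree is None:
        best_tree = search_topology(a, model, engine=engine)
    tn = best_tree.taxon_namespace
    rng = np.random.default_rng([seed, 777])
    nsites = int(engine.n_sites)
    probs = engine.counts / engine.n_sites
    rep_splits = []
    for _ in range(n):
        counts = rng.multinomial(nsites, probs).astype(float)
        rep_engine = engine.with_counts(counts)
        start = best_tree.clone(depth=1)
        start.taxon_namespace = tn
        rep_tree = search_topology(a, model, config=config, engine=rep_engine,
                                   start_tree=start)
        rep_tree.is_rooted = False
        rep_tree.encode_bipartitions()
        rep_splits.append({b.split_bitmask for b in rep_tree.bipartition_encoding})
    out = best_tree.clone(depth=1)
    out.taxon_namespace = tn
    out.is_rooted = False
    out.encode_bipartitions()
    supports = {}
    for edge in out.preorder_edge_iter():
        node = edge.head_node
        if node.parent_node is None or node.is_leaf():
            continue
        mask = edge.bipartition.split_bitmask
        pct = 100.0 * sum(mask in s for s in rep_splits) / n
        node.label = f"{pct:g}"
        supports[mask] = pct
    return out, supports


# ---------------------------------------------------------------------------
# Tree-set summaries
# ---------------------------------------------------------------------------

def _clades(tree) -> set[frozenset]:
    out = set()
    for node in tree.preorder_node_iter():
        out.add(frozenset(lf.taxon.label for lf in node.leaf_iter()))
    return out


def clade_frequencies(trees: list[dendropy.Tree]) -> dict[frozenset, float]:
    """Fraction of (rooted) trees containing each clade (tip subset)."""
    if not trees:
        raise TreeInferError("empty tree set")
    tipsets = [frozenset(lf.taxon.label for lf in t.leaf_node_iter())
               for t in trees]
    if len(set(tipsets)) != 1:
        raise TreeInferError("trees have mixed tip sets")
    freq: dict[frozenset, float] = {}
    for t in trees:
        for clade in _clades(t):
            freq[clade] = freq.get(clade, 0.0) + 1.0
    return {c: k / len(trees) for c, k in freq.items()}


def mcc_score(tree: dendropy.Tree, freq: dict[frozenset, float]) -> float:
    return sum(math.log(freq[c]) for c in _clades(tree))


def mcc_tree(trees: list[dendropy.Tree]) -> dendropy.Tree:
    """Maximum clade credibility tree: the member maximizing the sum of log
    clade frequencies; ties broken by lowest index."""
    freq = clade_frequencies(trees)
    scores = [mcc_score(t, freq) for t in trees]
    best = int(np.argmax(scores))  # argmax returns the first maximum
    return trees[best]


def majority_consensus(trees: list[dendropy.Tree],
                       threshold: float = 0.5) -> dendropy.Tree:
    """Rooted majority-rule consensus: exactly the clades with frequency
    strictly above ``threshold`` (>= 0.5), polytomies elsewhere."""
    if threshold < 0.5:
        raise TreeInferError("threshold must be >= 0.5")
    freq = clade_frequencies(trees)
    tipset = frozenset(lf.taxon.label for lf in trees[0].leaf_node_iter())
    selected = [c for c, f in freq.items() if f > threshold and len(c) >= 2]
    if tipset not in selected:
        selected.append(tipset)
    selected.sort(key=lambda c: (-len(c), sorted(c)))
    tn = dendropy.TaxonNamespace(sorted(tipset))
    tree = dendropy.Tree(taxon_namespace=tn)
    tree.is_rooted = True
    nodes: list[tuple[frozenset, dendropy.Node]] = []
    for clade in selected:
        node = tree.seed_node if clade == tipset else dendropy.Node()
        node.label = f"{freq[clade]:.3f}" if clade != tipset else None
        parent = None
        for pc, pn in nodes:
            if clade < pc and (parent is None or len(pc) < len(parent[0])):
                parent = (pc, pn)
        if parent is not None:
            parent[1].add_child(node)
        nodes.append((clade, node))
    for label in sorted(tipset):
        parent = min((pair for pair in nodes if label in pair[0]),
                     key=lambda pair: len(pair[0]))
        leaf = dendropy.Node(taxon=tn.get_taxon(label))
        parent[1].add_child(leaf)
    return tree


# ---------------------------------------------------------------------------
# Tree utilities
# ---------------------------------------------------------------------------

def prune_tip(tree: dendropy.Tree, label: str) -> dendropy.Tree:
    """Remove one tip; the freed degree-2 node is suppressed with branch
    lengths summed, so remaining tip-to-tip path lengths are unchanged."""
    leaves = [lf for lf in tree.leaf_node_iter() if lf.taxon.label == label]
    if not leaves:
        raise TreeInferError(f"tip '{label}' not found")
    if len(tree.leaf_nodes()) <= 2:
        raise TreeInferError("cannot prune to fewer than 2 tips")
    out = tree.clone(depth=1)
    taxon = out.taxon_namespace.get_taxon(label)
    out.prune_taxa([taxon], suppress_unifurcations=True)
    return out


def topologies_identical(t1: dendropy.Tree, t2: dendropy.Tree) -> bool:
    """True iff the unrooted Robinson-Foulds distance is zero."""
    tn = dendropy.TaxonNamespace()
    a = dendropy.Tree.get(data=t1.as_string(schema="newick"),
                          schema="newick", taxon_namespace=tn)
    b = dendropy.Tree.get(data=t2.as_string(schema="newick"),
                          schema="newick", taxon_namespace=tn)
    tips_a = {lf.taxon.label for lf in a.leaf_node_iter()}
    tips_b = {lf.taxon.label for lf in b.leaf_node_iter()}
    if tips_a != tips_b:
        raise TreeInferError("tip sets differ")
    a.is_rooted = False
    b.is_rooted = False
    a.encode_bipartitions()
    b.encode_bipartitions()
    return treecompare.symmetric_difference(a, b) == 0


def root_with_outgroup(tree: dendropy.Tree, outgroup: str) -> dendropy.Tree:
    """Root (a copy of) the tree on the pendant edge of the outgroup tip."""
    out = tree.clone(depth=1)
    leaves = [lf for lf in out.leaf_node_iter() if lf.taxon.label == outgroup]
    if not leaves:
        raise TreeInferError(f"outgroup tip '{outgroup}' not found")
    edge = leaves[0].edge
    blen = edge.length or BL_MIN
    out.reroot_at_edge(edge, length1=blen / 2, length2=blen / 2,
                       suppress_unifurcations=True)
    out.is_rooted = True
    return out


def read_newick(source: str, taxon_namespace=None, path: bool = False) -> dendropy.Tree:
    if path:
        return dendropy.Tree.get(path=source, schema="newick",
                                 taxon_namespace=taxon_namespace)
    return dendropy.Tree.get(data=source, schema="newick",
                             taxon_namespace=taxon_namespace)


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick",
               suppress_rooting=True, real_value_format_specifier=".10g")
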