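"""Penalized-likelihood divergence dating on a fixed topology.

Branch lengths (expected substitutions/site) are converted to expected
substitution counts ``x_k = blen_k * nsites`` and modelled as continuous
Poisson observations with mean ``r_k * dt_k`` (rate in subs/site/Myr times
branch duration in Myr).  Rate variation across the tree is discouraged by a
roughness penalty: the squared difference between each branch's rate and its
parent branch's rate, plus (at the root, which has no parent branch) the
variance among the root's child-branch rates.  The smoothing parameter
``lambda`` weighs the penalty; it can be chosen by leave-one-terminal-branch-
out cross-validation with a chi-square prediction error.

Node ages and branch rates are optimized jointly (SLSQP with explicit
parent-older-than-child constraints and calibration bounds, multi-start with
seeded jitter); only the optimum is contractually specified, so a generic
constrained quasi-Newton stands in for truncated Newton.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy.optimize import minimize

from . import treeinfer


class DatingError(ValueError):
    pass


@dataclass(frozen=True)
class CalibrationConstraint:
    """Age bounds (Ma) on the MRCA of ``tips``; fixed age when min == max."""

    tips: tuple
    min_age: float
    max_age: float

    def __post_init__(self):
        if self.min_age > self.max_age:
            raise DatingError("calibration min_age > max_age")

    @classmethod
    def fixed(cls, tips, age):
        return cls(tuple(tips), age, age)


@dataclass
class PLConfig:
    nsites: int
    smoothing: float = 10.0
    cv_grid: tuple = tuple(10.0 ** (k / 4) for k in range(0, 9))  # 1 .. 100
    n_starts: int = 5
    max_iter: int = 500
    tol: float = 1e-8
    min_duration: float = 1e-6

    def __post_init__(self):
        if self.smoothing < 0 or self.nsites < 1:
            raise DatingError("need smoothing >= 0 and nsites >= 1")


@dataclass
class Chronogram:
    """Dated tree: edge lengths are durations in Myr, tips at age 0."""

    tree: dendropy.Tree
    node_ages: dict          # frozenset(tip labels) -> age (Ma)
    branch_rates: dict       # frozenset(tip labels below branch) -> rate
    objective: float
    nsites: int

    def age_of(self, tips) -> float:
        node = self.tree.mrca(taxon_labels=list(tips))
        return float(node.age)

    def root_age(self) -> float:
        return float(self.tree.seed_node.age)

    def rate_summary(self) -> tuple[float, float]:
        """Mean and sample s.d. of per-branch rates (subs/site/Myr)."""
        rates = np.array(list(self.branch_rates.values()))
        sd = float(rates.std(ddof=1)) if len(rates) > 1 else 0.0
        return float(rates.mean()), sd

    def ages_frame(self) -> pd.DataFrame:
        rows = [{"clade": "|".join(sorted(c)), "age_ma": a}
                for c, a in sorted(self.node_ages.items(),
                                   key=lambda kv: -kv[1])]
        return pd.DataFrame(rows)


@dataclass
class CVResult:
    errors: dict              # lambda -> chi-square prediction error
    selected: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"smoothing": lam, "chi_square_error": err}
             for lam, err in self.errors.items()]
        )


# ---------------------------------------------------------------------------
# Compilation of the dating problem
# ---------------------------------------------------------------------------

class _Problem:
    """Arrays for one rooted (binary or not) tree with branch lengths."""

    def __init__(self, tree: dendropy.Tree, cals, cfg: PLConfig,
                 require_cal: bool = True):
        self.cfg = cfg
        self.tree = tree
        nodes = list(tree.postorder_node_iter())
        self.nodes = nodes
        self.index = {n: i for i, n in enumerate(nodes)}
        self.is_tip = np.array([n.is_leaf() for n in nodes])
        self.internal = np.flatnonzero(~self.is_tip)
        self.n_int = len(self.internal)
        self.var_of_node = {nodes[i]: k for k, i in enumerate(self.internal)}
        self.node_var = np.full(len(nodes), -1)
        self.node_var[self.internal] = np.arange(self.n_int)
        # edges indexed by child node
        self.edges = [n for n in nodes if n.parent_node is not None]
        self.n_edges = len(self.edges)
        self.x = np.array([(n.edge.length or 0.0) * cfg.nsites
                           for n in self.edges])
        self.child_idx = np.array([self.index[n] for n in self.edges])
        self.parent_idx = np.array([self.index[n.parent_node]
                                    for n in self.edges])
        # penalty wiring: parent edge of each edge (None if parent is root)
        eidx = {n: k for k, n in enumerate(self.edges)}
        self.eidx = eidx
        self.parent_edge = np.array([
            eidx.get(n.parent_node, -1) for n in self.edges
        ])
        self.root_child_edges = np.array(
            [eidx[c] for c in tree.seed_node.child_nodes()]
        )
        # calibration bounds per internal variable
        lo = np.zeros(self.n_int)
        hi = np.full(self.n_int, np.inf)
        self.max_cal = 0.0
        for cal in cals:
            node = tree.mrca(taxon_labels=list(cal.tips))
            if node is None or node.is_leaf():
                raise DatingError(f"calibration MRCA not found for {cal.tips}")
            k = self.var_of_node[node]
            lo[k] = max(lo[k], cal.min_age)
            hi[k] = min(hi[k], cal.max_age)
            self.max_cal = max(self.max_cal, cal.max_age)
        if require_cal and self.max_cal <= 0:
            raise DatingError("at least one calibration with max_age > 0 needed")
        if np.any(lo > hi):
            raise DatingError("conflicting calibrations on one node")
        self.age_cap = 50.0 * max(self.max_cal, 1.0)
        hi = np.minimum(hi, self.age_cap)
        # infeasibility across nested nodes: a descendant's minimum age may
        # not exceed any ancestor's maximum age
        eff_lo = lo.copy()
        for n in self.nodes:  # postorder: children first
            if n.is_leaf():
                continue
            k = self.var_of_node[n]
            for c in n.child_nodes():
                if not c.is_leaf():
                    eff_lo[k] = max(eff_lo[k], eff_lo[self.var_of_node[c]])
            if eff_lo[k] > hi[k]:
                raise DatingError(
                    "infeasible calibrations: a descendant's minimum age "
                    "exceeds an ancestor's maximum age")
        self.age_lo, self.age_hi = lo, hi

    def ages_vector_to_node_ages(self, ages):
        """Full per-node age array from internal-node variables."""
        full = np.zeros(len(self.nodes))
        full[self.internal] = ages
        return full

    def durations(self, ages_full):
        return ages_full[self.parent_idx] - ages_full[self.child_idx]

    def objective(self, ages, log_rates, lam, excluded=()):
        """Penalized negative log-likelihood.  Rates here are per-sequence
        (expected substitutions per Myr, matching the counts x_k)."""
        val, _ = self._obj_grad(ages, log_rates, lam, excluded,
                                want_grad=False)
        return val

    def _obj_grad(self, ages, log_rates, lam, excluded=(), want_grad=True):
        full = self.ages_vector_to_node_ages(ages)
        dt = np.maximum(self.durations(full), 1e-12)
        r = np.exp(log_rates)
        mu = r * dt
        keep = np.ones(self.n_edges, dtype=bool)
        for k in excluded:
            keep[k] = False
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = np.where(self.x > 0, self.x * np.log(mu), 0.0) - mu
        ll = float(ll[keep].sum())
        pe = self.parent_edge
        kept_set = np.flatnonzero(keep)
        mask = (pe >= 0) & keep & np.isin(pe, kept_set)
        diffs = np.zeros(self.n_edges)
        diffs[mask] = r[mask] - r[pe[mask]]
        pen = float((diffs ** 2).sum())
        rc = np.array([k for k in self.root_child_edges if keep[k]])
        if len(rc) > 1:
            pen += float(np.var(r[rc]))
        val = -ll + lam * pen
        if not want_grad:
            return val, None
        # gradient wrt per-edge durations
        g_dt = np.where(keep, -(np.where(self.x > 0, self.x / dt, 0.0) - r),
                        0.0)
        g_ages = np.zeros(self.n_int)
        np.add.at(g_ages, self.node_var[self.parent_idx], g_dt)
        child_int = self.node_var[self.child_idx] >= 0
        np.subtract.at(g_ages, self.node_var[self.child_idx[child_int]],
                       g_dt[child_int])
        # gradient wrt rates
        g_r = np.where(keep, -(np.where(self.x > 0, self.x / r, 0.0) - dt),
                       0.0)
        dpen = np.zeros(self.n_edges)
        dpen[mask] += 2.0 * diffs[mask]
        np.add.at(dpen, pe[mask], -2.0 * diffs[mask])
        if len(rc) > 1:
            m = len(rc)
            dpen[rc] += (2.0 / m) * (r[rc] - r[rc].mean())
        g_logr = (g_r + lam * dpen) * r
        return val, np.concatenate([g_ages, g_logr])

    def initial_state(self, rng=None):
        """Feasible ages from substitution-tree node heights scaled to the
        calibration window, optionally jittered; rates from x/dt."""
        heights = np.zeros(len(self.nodes))
        for n in self.nodes:
            if not n.is_leaf():
                i = self.index[n]
                heights[i] = max(
                    heights[self.index[c]] + max(c.edge.length or 0.0, 1e-9)
                    for c in n.child_nodes()
                )
        # scale so the most constrained calibrated node sits mid-window
        k_cal = int(np.argmin(self.age_hi - self.age_lo))
        target = 0.5 * (self.age_lo[k_cal]
                        + min(self.age_hi[k_cal], 4 * self.age_lo[k_cal] + 1))
        h_cal = heights[self.internal[k_cal]]
        scale = target / h_cal if h_cal > 0 else 1.0
        ages = heights[self.internal] * scale
        if rng is not None:
            ages = ages * rng.lognormal(0.0, 0.15, size=ages.shape)
        ages = np.clip(ages, self.age_lo, self.age_hi)
        # enforce strict parent > child ordering by a postorder sweep
        full = self.ages_vector_to_node_ages(ages)
        for n in self.nodes:
            if n.is_leaf() or n.parent_node is None:
                continue
            i, p = self.index[n], self.index[n.parent_node]
            if full[p] <= full[i]:
                full[p] = full[i] * 1.05 + self.cfg.min_duration
        full[self.internal] = np.clip(full[self.internal],
                                      self.age_lo, self.age_hi)
        # second sweep in case clipping re-broke ordering at a calibrated node
        for n in reversed(self.nodes):  # preorder: push children down
            if n.parent_node is None or n.is_leaf():
                continue
            i, p = self.index[n], self.index[n.parent_node]
            if full[i] >= full[p]:
                full[i] = full[p] * 0.95
        ages = full[self.internal]
        dt = np.maximum(self.durations(self.ages_vector_to_node_ages(ages)),
                        self.cfg.min_duration)
        rates = np.maximum(self.x / dt, 1e-10)  # per-sequence rates
        rates = np.where(self.x > 0, rates, max(np.median(rates), 1e-10))
        return ages, np.log(rates)

    def fit(self, lam, seed=0, excluded=(), n_starts=None):
        cfg = self.cfg
        n_starts = n_starts if n_starts is not None else cfg.n_starts
        n_int, n_edges = self.n_int, self.n_edges

        def pack(ages, logr):
            return np.concatenate([ages, logr])

        def unpack(z):
            return z[:n_int], z[n_int:]

        def f(z):
            ages, logr = unpack(z)
            val, grad = self._obj_grad(ages, logr, lam, excluded)
            return val, grad

        # ordering constraints: parent age - child age >= min_duration
        rows = []
        for k, n in enumerate(self.edges):
            p = self.var_of_node[n.parent_node]
            row = np.zeros(n_int + n_edges)
            row[p] = 1.0
            if not n.is_leaf():
                row[self.var_of_node[n]] = -1.0
            rows.append(row)
        amat = np.array(rows)
        cons = [{"type": "ineq",
                 "fun": lambda z: amat @ z - cfg.min_duration,
                 "jac": lambda z: amat}]
        r_hi = math.log(max(float(self.x.max()), 1.0)
                        / cfg.min_duration * 10.0)
        bounds = ([(self.age_lo[k], self.age_hi[k]) for k in range(n_int)]
                  + [(math.log(1e-12), r_hi)] * n_edges)
        best = None
        for s in range(n_starts):
            rng = None if s == 0 else np.random.default_rng([seed, s])
            ages0, logr0 = self.initial_state(rng)
            res = minimize(f, pack(ages0, logr0), method="SLSQP", jac=True,
                           bounds=bounds, constraints=cons,
                           options={"maxiter": cfg.max_iter,
                                    "ftol": cfg.tol})
            if best is None or res.fun < best.fun:
                best = res
        ages, logr = unpack(best.x)
        return ages, np.exp(logr), float(best.fun)


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def pl_objective(tree: dendropy.Tree, ages: dict, rates: dict,
                 cfg: PLConfig) -> float:
    """Objective value (lower is better) for explicit ages and rates.

    ``ages`` maps frozenset(tip labels below node) -> age for every internal
    node; ``rates`` maps frozenset(tip labels below branch) -> rate for every
    branch, in the objective's own units (expected substitutions per Myr over
    the whole sequence, i.e. per-site rate times ``nsites``).
    """
    prob = _Problem(tree, [], cfg, require_cal=False)
    avec = np.zeros(prob.n_int)
    for k, i in enumerate(prob.internal):
        clade = frozenset(lf.taxon.label for lf in prob.nodes[i].leaf_iter())
        avec[k] = ages[clade]
    logr = np.zeros(prob.n_edges)
    for k, n in enumerate(prob.edges):
        clade = frozenset(lf.taxon.label for lf in n.leaf_iter())
        if rates[clade] <= 0:
            raise DatingError("rates must be positive")
        logr[k] = math.log(rates[clade])
    full = prob.ages_vector_to_node_ages(avec)
    dt = prob.durations(full)
    if np.any((dt <= 0) & (prob.x > 0)):
        raise DatingError("non-positive duration on a branch with substitutions")
    return prob.objective(avec, logr, cfg.smoothing)


def _chronogram_from_solution(prob: _Problem, ages, rates, obj,
                              cfg: PLConfig) -> Chronogram:
    tree = prob.tree.clone(depth=1)
    src_nodes = list(prob.tree.postorder_node_iter())
    dst_nodes = list(tree.postorder_node_iter())
    full = prob.ages_vector_to_node_ages(ages)
    node_ages, branch_rates = {}, {}
    for s, d, age in zip(src_nodes, dst_nodes, full):
        d.age = float(age)
        if not d.is_leaf():
            clade = frozenset(lf.taxon.label for lf in d.leaf_iter())
            node_ages[clade] = float(age)
    src_pos = {n: i for i, n in enumerate(src_nodes)}
    for k, n in enumerate(prob.edges):
        d = dst_nodes[src_pos[n]]
        d.edge.length = float(full[prob.parent_idx[k]]
                              - full[prob.child_idx[k]])
        # optimization rates are per-sequence; report per site
        d.edge.rate = float(rates[k]) / cfg.nsites
        clade = frozenset(lf.taxon.label for lf in n.leaf_iter())
        branch_rates[clade] = float(rates[k]) / cfg.nsites
    return Chronogram(tree, node_ages, branch_rates, obj, cfg.nsites)


def pl_date(tree: dendropy.Tree, cals, cfg: PLConfig,
            seed: int = 0) -> Chronogram:
    """Date a rooted tree with branch lengths under penalized likelihood."""
    if not cals:
        raise DatingError("at least one calibration is required")
    prob = _Problem(tree, cals, cfg)
    ages, rates, obj = prob.fit(cfg.smoothing, seed=seed)
    return _chronogram_from_solution(prob, ages, rates, obj, cfg)


def cross_validate_smoothing(tree: dendropy.Tree, cals, cfg: PLConfig,
                             seed: int = 0, n_starts: int = 2) -> CVResult:
    """Leave-one-terminal-branch-out cross-validation over ``cfg.cv_grid``.

    For each smoothing value and each terminal branch, the model is refit
    with that branch's substitution datum (and its penalty terms) removed;
    the branch's expected substitutions are then predicted from the fitted
    parent-branch rate times its duration, and prediction errors accumulate
    as chi-square.
    """
    if not cfg.cv_grid:
        raise DatingError("cv grid is empty")
    if len(tree.leaf_nodes()) < 4:
        raise DatingError("cross-validation needs >= 4 tips")
    prob = _Problem(tree, cals, cfg)
    terminals = [k for k, n in enumerate(prob.edges) if n.is_leaf()]
    errors = {}
    for lam in cfg.cv_grid:
        chi2 = 0.0
        for k in terminals:
            ages, rates, _ = prob.fit(lam, seed=seed, excluded=(k,),
                                      n_starts=n_starts)
            full = prob.ages_vector_to_node_ages(ages)
            dt = prob.durations(full)
            pk = prob.parent_edge[k]
            if pk >= 0:
                r_pred = rates[pk]
            else:
                sibs = [j for j in prob.root_child_edges if j != k]
                r_pred = float(np.mean(rates[sibs]))
            x_pred = max(r_pred * dt[k] * cfg.nsites, 1e-12)
            chi2 += (prob.x[k] - x_pred) ** 2 / x_pred
        errors[lam] = float(chi2)
    selected = min(errors, key=lambda lam: (errors[lam], lam))
    return CVResult(errors, float(selected))


def age_profile(chronograms: list[Chronogram],
                node_defs: list[tuple]) -> pd.DataFrame:
    """Mean and sample s.d. of node ages across chronograms."""
    rows = []
    for tips in node_defs:
        ages = []
        for ch in chronograms:
            node = ch.tree.mrca(taxon_labels=list(tips))
            if node is None:
                raise DatingError(f"node {tips} absent from a chronogram")
            ages.append(float(node.age))
        ages = np.array(ages)
        sd = float(ages.std(ddof=1)) if len(ages) > 1 else 0.0
        rows.append({"node": "|".join(sorted(tips)),
                     "mean_age_ma": float(ages.mean()), "sd_ma": sd,
                     "n": len(ages)})
    return pd.DataFrame(rows)


def dating_ci_pipeline(trees: list[dendropy.Tree], reference: dendropy.Tree,
                       k: int, cals, cfg: PLConfig, seed: int = 0,
                       node_defs: list[tuple] | None = None):
    """Reference point estimates plus resampled confidence intervals.

    Filters ``trees`` to those topologically identical to ``reference``
    (unrooted RF = 0), samples ``k`` without replacement, dates each, and
    profiles node ages.  Returns ``(reference_chronogram, profile_frame)``.
    """
    matching = [t for t in trees
                if treeinfer.topologies_identical(t, reference)]
    if len(matching) < k:
        raise DatingError(
            f"only {len(matching)} of {len(trees)} trees match the reference "
            f"topology; cannot subsample k={k}"
        )
    rng = np.random.default_rng([seed, 4242])
    chosen = rng.choice(len(matching), size=k, replace=False)
    ref_chron = pl_date(reference, cals, cfg, seed=seed)
    if node_defs is None:
        node_defs = [tuple(sorted(c)) for c in ref_chron.node_ages]
    chrons = [pl_date(matching[int(i)], cals, cfg, seed=seed)
              for i in sorted(chosen)]
    profile = age_profile(chrons, node_defs)
    ref_ages = {r: ref_chron.node_ages[frozenset(nd)]
                for r, nd in enumerate(node_defs)}
    profile["reference_age_ma"] = [ref_ages[r] for r in range(len(node_defs))]
    return ref_chron, profile
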