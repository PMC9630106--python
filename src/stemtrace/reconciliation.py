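"""Dated gene-tree/species-tree reconciliation under a DTL model.

The engine computes the probability of a gene family's evidence -- a gene
tree, a sample of gene trees summarized by conditional clade probabilities
(CCPs), or a profile of tip copy numbers -- given a dated species tree and
per-Myr rates of duplication (``delta``), horizontal transfer (``tau``) and
loss (``lambda``).

The species tree is discretized into time slices whose boundaries include
every speciation age.  Within a slice the set of contemporaneous branches is
constant, and transfers are only allowed between branches alive in the same
slice, which is what makes reconciliations time-consistent (no transfers into
the past).  Partial likelihoods are propagated from the tips (age 0) towards
the root with first-order transition probabilities per slice step; extinction
(unobserved survival) probabilities are propagated alongside so that events
leaving no sampled descendants are integrated out.

Conditional on a computed likelihood the dynamic program can be traversed
stochastically backwards to draw explicit reconciliations: event ledgers with
per-branch duplication/transfer/loss/origination counts and per-node copy
numbers, including the lineages that go extinct.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .synthetic_data import Event, SimulatedFamily
from .trees import DatedSpeciesTree, TreeError

__all__ = [
    "DTLRates",
    "GeneFamily",
    "CCPTable",
    "TimeSlicedTree",
    "ReconciliationResult",
    "build_ccp_table",
    "discretize",
    "family_loglik",
    "fit_rates",
    "sample_events",
    "profile_loglik",
]

# hard ceiling on per-step event probability; larger steps are subdivided
_MAX_STEP_MASS = 0.1


@dataclass(frozen=True)
class DTLRates:
    """Per-gene-lineage, per-Myr rates of the DTL model."""

    duplication: float
    transfer: float
    loss: float

    def __post_init__(self):
        for v in (self.duplication, self.transfer, self.loss):
            if not np.isfinite(v) or v < 0:
                raise ValueError("DTL rates must be finite and non-negative")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.duplication, self.transfer, self.loss)


# --------------------------------------------------------------------------
# conditional clade probabilities
# --------------------------------------------------------------------------

@dataclass
class CCPTable:
    """Clade and conditional split frequencies from a rooted gene-tree sample.

    Clades are bitmasks over the sorted leaf set.  ``splits[c]`` lists
    ``(child1_index, child2_index, probability)`` for clade index ``c``; the
    probabilities for each observed clade sum to one.
    """

    leaves: list[str]
    clades: list[int]                      # bitmasks, sorted by size then value
    freq: np.ndarray                       # per clade, fraction of sample trees
    splits: list[list[tuple[int, int, float]]]
    n_trees: int

    @property
    def n_clades(self) -> int:
        return len(self.clades)

    @property
    def root_index(self) -> int:
        return self.clades.index((1 << len(self.leaves)) - 1)

    def leaf_index(self, leaf: str) -> int:
        return self.clades.index(1 << self.leaves.index(leaf))


def _tree_clades(tree: dendropy.Tree, leaf_pos: dict[str, int]):
    """Yield (clade_mask, left_mask, right_mask) per internal node."""
    masks: dict[int, int] = {}
    for nd in tree.postorder_node_iter():
        kids = nd.child_nodes()
        if not kids:
            masks[id(nd)] = 1 << leaf_pos[nd.taxon.label]
        else:
            if len(kids) != 2:
                raise TreeError("gene trees must be strictly bifurcating")
            l, r = masks[id(kids[0])], masks[id(kids[1])]
            masks[id(nd)] = l | r
            yield masks[id(nd)], l, r


def build_ccp_table(trees) -> CCPTable:
    """Estimate clade / conditional split frequencies from a tree sample.

    ``trees`` is a list of Newick strings (or dendropy Trees), all on the same
    leaf set.  A single-tree sample degenerates to an indicator table.
    """
    if not trees:
        raise ValueError("need at least one gene tree")
    parsed = []
    tns = dendropy.TaxonNamespace()
    for t in trees:
        if isinstance(t, dendropy.Tree):
            parsed.append(t)
        else:
            parsed.append(dendropy.Tree.get(
                data=t, schema="newick", taxon_namespace=tns,
                preserve_underscores=True))
    leafsets = [frozenset(l.taxon.label for l in t.leaf_node_iter())
                for t in parsed]
    if len(set(leafsets)) != 1:
        raise TreeError("all sample trees must share the same leaf set")
    leaves = sorted(leafsets[0])
    leaf_pos = {l: i for i, l in enumerate(leaves)}

    clade_count: dict[int, int] = {}
    split_count: dict[tuple[int, int], int] = {}
    for t in parsed:
        for mask, l, r in _tree_clades(t, leaf_pos):
            clade_count[mask] = clade_count.get(mask, 0) + 1
            key = (mask, min(l, r))
            split_count[key] = split_count.get(key, 0) + 1
    n_trees = len(parsed)
    for i in range(len(leaves)):
        clade_count[1 << i] = n_trees

    clades = sorted(clade_count, key=lambda m: (bin(m).count("1"), m))
    index = {m: i for i, m in enumerate(clades)}
    freq = np.array([clade_count[m] / n_trees for m in clades])
    splits: list[list[tuple[int, int, float]]] = [[] for _ in clades]
    full = (1 << len(leaves)) - 1
    for (mask, l), cnt in split_count.items():
        r = mask & ~l & full
        splits[index[mask]].append((index[l], index[r], cnt / clade_count[mask]))
    return CCPTable(leaves=leaves, clades=clades, freq=freq, splits=splits,
                    n_trees=n_trees)


# --------------------------------------------------------------------------
# gene families
# --------------------------------------------------------------------------

@dataclass
class GeneFamily:
    """A family's evidence: gene tree(s) and/or tip copy numbers."""

    family_id: str
    trees: list[str] | None = None
    leaf_to_species: dict[str, str] = field(default_factory=dict)
    tip_copy_numbers: dict[str, int] | None = None
    _ccp: CCPTable | None = field(default=None, repr=False)

    @classmethod
    def from_simulated(cls, fam: SimulatedFamily) -> "GeneFamily":
        if fam.true_gene_tree is None:
            raise ValueError(f"family {fam.family_id} left no descendants")
        return cls(
            family_id=fam.family_id,
            trees=[fam.true_gene_tree],
            leaf_to_species=dict(fam.leaf_to_species),
            tip_copy_numbers=dict(fam.tip_copy_numbers),
        )

    @property
    def ccp(self) -> CCPTable:
        if self._ccp is None:
            if not self.trees:
                raise ValueError("family has no gene trees")
            self._ccp = build_ccp_table(self.trees)
        return self._ccp


# --------------------------------------------------------------------------
# time discretization
# --------------------------------------------------------------------------

@dataclass
class TimeSlicedTree:
    """A dated tree plus its slice grid and per-slice live branch sets."""

    tree: DatedSpeciesTree
    times: np.ndarray                  # grid ages, times[0]=0 .. times[-1]=root
    live: list[np.ndarray]             # per segment g: nodes live in (t_g, t_g+1)
    nodes_at: dict[int, list[int]]     # grid index -> internal nodes at that age
    n_slices_per_interval: int

    @property
    def n_segments(self) -> int:
        return len(self.times) - 1

    @property
    def steps(self) -> np.ndarray:
        return np.diff(self.times)


def discretize(tree: DatedSpeciesTree, n_slices_per_interval: int = 3
               ) -> TimeSlicedTree:
    """Build the time-slice grid whose boundaries include every node age."""
    if n_slices_per_interval < 1:
        raise ValueError("n_slices_per_interval must be >= 1")
    tree.validate()
    bounds = np.unique(np.concatenate([[0.0], tree.ages[tree.internal_nodes]]))
    grid = [0.0]
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        grid.extend(np.linspace(lo, hi, n_slices_per_interval + 1)[1:])
    times = np.asarray(grid)

    parent = tree.parent
    live = []
    eps = 1e-9 * max(tree.root_age, 1.0)
    branch_nodes = tree.branch_nodes
    for g in range(len(times) - 1):
        lo, hi = times[g], times[g + 1]
        mask = (tree.ages[branch_nodes] <= lo + eps) & \
               (tree.ages[parent[branch_nodes]] >= hi - eps)
        live.append(branch_nodes[mask])

    nodes_at: dict[int, list[int]] = {}
    for v in tree.internal_nodes:
        if v == tree.root:
            continue
        j = int(np.argmin(np.abs(times - tree.ages[v])))
        nodes_at.setdefault(j, []).append(int(v))
    return TimeSlicedTree(tree=tree, times=times, live=live, nodes_at=nodes_at,
                          n_slices_per_interval=n_slices_per_interval)


# --------------------------------------------------------------------------
# the dynamic program
# --------------------------------------------------------------------------

class _PreparedFamily:
    """CCP table mapped onto a species tree: flat arrays for the DP."""

    def __init__(self, family: GeneFamily, tree: DatedSpeciesTree):
        ccp = family.ccp
        self.family_id = family.family_id
        self.ccp = ccp
        self.C = ccp.n_clades
        self.root_clade = ccp.root_index
        tip_index = {tree.labels[i]: int(i) for i in tree.tips}
        self.leaf_cols: list[tuple[int, int]] = []
        for leaf in ccp.leaves:
            sp = family.leaf_to_species.get(leaf)
            if sp is None or sp not in tip_index:
                raise TreeError(
                    f"family {family.family_id}: leaf {leaf!r} maps to species "
                    f"{sp!r} absent from the species tree")
            self.leaf_cols.append((ccp.leaf_index(leaf), tip_index[sp]))
        I1, I2, W, OUT = [], [], [], []
        for c, sp in enumerate(ccp.splits):
            for (a, b, w) in sp:
                I1.append(a)
                I2.append(b)
                W.append(w)
                OUT.append(c)
        self.I1 = np.asarray(I1, dtype=int)
        self.I2 = np.asarray(I2, dtype=int)
        self.W = np.asarray(W)
        self.OUT = np.asarray(OUT, dtype=int)
        self.out_unique = len(set(OUT)) == len(OUT)


def _scatter(C, n, OUT, vals, unique):
    if unique:
        out = np.zeros((C, n))
        out[OUT] = vals
        return out
    out = np.zeros((C, n))
    np.add.at(out, OUT, vals)
    return out


class _DP:
    """One likelihood evaluation; optionally stores states for backtracking."""

    def __init__(self, prep: _PreparedFamily, sliced: TimeSlicedTree,
                 rates: DTLRates, origination: str, store: bool,
                 dtype=np.float64):
        self.dtype = dtype
        self.prep = prep
        self.sliced = sliced
        self.rates = rates
        self.origination = origination
        self.store = store
        self.log_scale = 0.0
        self.bottom_states: list[tuple[np.ndarray, np.ndarray]] = []
        self.pre_states: list[tuple[np.ndarray, np.ndarray] | None] = []
        self.orig_weights: list[np.ndarray] = []  # per segment, per live branch
        self._run()

    def _run(self):
        prep, sl = self.prep, self.sliced
        tree = sl.tree
        d, t, l = self.rates.as_tuple()
        N = tree.n_nodes
        C = prep.C
        E = np.zeros(N, dtype=self.dtype)
        P = np.zeros((C, N), dtype=self.dtype)
        for ci, col in prep.leaf_cols:
            P[ci, col] = 1.0
        T_tot = tree.total_branch_duration
        orig_sum = 0.0
        unobs_sum = 0.0

        if self.store:
            self.pre_states.append(None)
            self.bottom_states.append((E.copy(), P.copy()))

        for g in range(sl.n_segments):
            h_full = sl.times[g + 1] - sl.times[g]
            live = sl.live[g]
            n = len(live)
            n_sub = 1
            total = d + t + l
            if not self.store and h_full * total > _MAX_STEP_MASS:
                n_sub = int(math.ceil(h_full * total / _MAX_STEP_MASS))
            if self.store and h_full * total > 0.5:
                raise ValueError(
                    "slice step too coarse for event sampling; increase "
                    "n_slices_per_interval")
            h = h_full / n_sub
            for _s in range(n_sub):
                El = E[live]
                Pl = P[:, live]
                if n > 1:
                    Ebar = (El.sum() - El) / (n - 1)
                    M = (Pl.sum(axis=1, keepdims=True) - Pl) / (n - 1)
                else:
                    Ebar = np.zeros(n)
                    M = np.zeros_like(Pl)
                newE = El + h * (l - total * El + d * El**2 + t * El * Ebar)
                prod_same = Pl[prep.I1] * Pl[prep.I2]
                S_same = _scatter(C, n, prep.OUT,
                                  prep.W[:, None] * prod_same, prep.out_unique)
                newP = Pl * (1.0 - h * total) \
                    + h * d * (S_same + 2.0 * El[None, :] * Pl)
                if t > 0 and n > 1:
                    prod_mix = Pl[prep.I1] * M[prep.I2] + Pl[prep.I2] * M[prep.I1]
                    S_mix = _scatter(C, n, prep.OUT,
                                     prep.W[:, None] * prod_mix,
                                     prep.out_unique)
                    newP += h * t * (S_mix + El[None, :] * M
                                     + Ebar[None, :] * Pl)
                E[live] = newE
                P[:, live] = newP

            if self.origination == "uniform_branch":
                w = (h_full / T_tot) * P[prep.root_clade, live]
                orig_sum += float(w.sum())
                unobs_sum += float((h_full / T_tot) * E[live].sum())
                self.orig_weights.append(w)

            if self.store:
                self.pre_states.append((E.copy(), P.copy()))

            # speciation merges at the top boundary of this segment
            for v in sl.nodes_at.get(g + 1, []):
                self._merge(E, P, v)

            if self.store:
                self.bottom_states.append((E.copy(), P.copy()))
            elif not self.store:
                m = P[:, live].max() if n else 1.0
                if 0 < m < 1e-100:
                    P *= 1.0 / m
                    orig_sum /= m
                    self.log_scale += math.log(m)

        # root merge
        root = tree.root
        rl, rr = tree.children(root)
        prod = self.prep.W * (P[prep.I1, rl] * P[prep.I2, rr]
                              + P[prep.I1, rr] * P[prep.I2, rl])
        S = np.zeros(C)
        np.add.at(S, prep.OUT, prod)
        self.P_root = S + P[:, rl] * E[rr] + P[:, rr] * E[rl]
        self.E_root = E[rl] * E[rr]

        if self.origination == "root":
            raw = self.P_root[prep.root_clade]
            unobs = self.E_root
        elif self.origination == "uniform_branch":
            raw = orig_sum
            unobs = unobs_sum
        else:
            raise ValueError(f"unknown origination {self.origination!r}")
        if not np.isfinite(raw) or raw < 0:
            raise FloatingPointError(
                f"family {prep.family_id}: invalid likelihood {raw!r}")
        self.raw = raw
        self.p_unobserved = min(float(unobs), 1.0 - 1e-300)

    def _merge(self, E, P, v):
        tree = self.sliced.tree
        prep = self.prep
        lc, rc = tree.children(v)
        prod = prep.W * (P[prep.I1, lc] * P[prep.I2, rc]
                         + P[prep.I1, rc] * P[prep.I2, lc])
        S = np.zeros(prep.C)
        np.add.at(S, prep.OUT, prod)
        P[:, v] = S + P[:, lc] * E[rc] + P[:, rc] * E[lc]
        E[v] = E[lc] * E[rc]

    def loglik(self, condition: bool) -> float:
        if self.raw == 0.0:
            return -np.inf
        ll = math.log(self.raw) + self.log_scale
        if condition:
            ll -= math.log1p(-self.p_unobserved)
        return ll


def family_loglik(
    family: GeneFamily,
    sliced: TimeSlicedTree,
    rates: DTLRates,
    origination: str = "uniform_branch",
    condition_on_survival: bool = True,
) -> float:
    """Log-probability of a family's gene-tree evidence under the DTL model.

    Sums over reconciliations (and, for a tree sample, amalgamates over gene
    tree topologies weighted by their conditional clade probabilities).  With
    ``condition_on_survival`` the result is conditioned on the family being
    observed in at least one sampled genome, reflecting how gene-family
    clusters are ascertained.
    """
    prep = _PreparedFamily(family, sliced.tree)
    dp = _DP(prep, sliced, rates, origination, store=False)
    return dp.loglik(condition_on_survival)


# --------------------------------------------------------------------------
# rate fitting
# --------------------------------------------------------------------------

@dataclass
class RateFit:
    rates: DTLRates
    loglik: float
    converged: bool
    n_evaluations: int
    per_family: dict[str, DTLRates] | None = None


def fit_rates(
    families,
    sliced: TimeSlicedTree,
    init: tuple[float, float, float] = (0.005, 0.005, 0.005),
    bounds: tuple = ((1e-6, 1.0), (1e-6, 1.0), (1e-6, 1.0)),
    mode: str = "pooled",
    origination: str = "uniform_branch",
    condition_on_survival: bool = True,
    maxiter: int = 300,
) -> RateFit:
    """Maximize the summed family log-likelihood over (delta, tau, lambda).

    ``mode="pooled"`` fits one global rate triple to all families (the
    spec for datasets simulated under shared rates); ``mode="per_family"``
    fits each family separately, as ALEml does by default.
    """
    if isinstance(families, GeneFamily):
        families = [families]
    for (lo, hi) in bounds:
        if lo < 0 or hi <= lo:
            raise ValueError("bounds must satisfy 0 <= lo < hi")
    if not all(lo <= v <= hi for v, (lo, hi) in zip(init, bounds)):
        raise ValueError("init must lie within bounds")

    if mode == "per_family":
        per = {}
        total = 0.0
        ok = True
        nev = 0
        for fam in families:
            fit = fit_rates([fam], sliced, init, bounds, mode="pooled",
                            origination=origination,
                            condition_on_survival=condition_on_survival,
                            maxiter=maxiter)
            per[fam.family_id] = fit.rates
            total += fit.loglik
            ok = ok and fit.converged
            nev += fit.n_evaluations
        return RateFit(rates=next(iter(per.values())), loglik=total,
                       converged=ok,
                       n_evaluations=nev, per_family=per)
    if mode != "pooled":
        raise ValueError(f"unknown mode {mode!r}")

    preps = [_PreparedFamily(f, sliced.tree) for f in families]
    lo = np.log([b[0] for b in bounds])
    hi = np.log([b[1] for b in bounds])

    def nll(x):
        if np.any(x < lo - 1e-12) or np.any(x > hi + 1e-12):
            return np.inf
        r = DTLRates(*np.exp(x))
        tot = 0.0
        for p in preps:
            dp = _DP(p, sliced, r, origination, store=False)
            ll = dp.loglik(condition_on_survival)
            if not np.isfinite(ll):
                return np.inf
            tot += ll
        return -tot

    x0 = np.log(np.asarray(init, dtype=float))
    res = minimize(nll, x0, method="Nelder-Mead",
                   options={"maxiter": maxiter, "xatol": 1e-3, "fatol": 1e-4})
    x = np.clip(res.x, lo, hi)
    rates = DTLRates(*np.exp(x))
    ll = -nll(x)
    # monotone-improvement guarantee: never return worse than the start
    ll0 = -nll(x0)
    if ll0 > ll:
        rates, ll = DTLRates(*init), ll0
    return RateFit(rates=rates, loglik=float(ll), converged=bool(res.success),
                   n_evaluations=int(res.nfev))


# --------------------------------------------------------------------------
# stochastic backtracking
# --------------------------------------------------------------------------

@dataclass
class SampledReconciliation:
    events: list[Event]
    node_copies: dict[str, int]


@dataclass
class ReconciliationResult:
    """Likelihood, rates and event reconstruction for one family."""

    family_id: str
    loglik: float
    rates: DTLRates
    expected_events: pd.DataFrame     # per branch: dup, trans_in, trans_out, loss, orig
    expected_copies: pd.Series        # per node label
    samples: list[SampledReconciliation] | None = None


class _Backtracker:
    def __init__(self, dp: _DP, rng: np.random.Generator):
        self.dp = dp
        self.rng = rng
        self.tree = dp.sliced.tree
        self.times = dp.sliced.times
        self.rates = dp.rates.as_tuple()
        self.events: list[Event] = []
        self.copies = np.zeros(self.tree.n_nodes, dtype=int)

    def _choose(self, weights):
        w = np.asarray(weights, dtype=float)
        tot = w.sum()
        if tot <= 0:
            raise FloatingPointError("degenerate backtracking weights")
        return int(self.rng.choice(len(w), p=w / tot))

    def run(self) -> SampledReconciliation:
        dp, tree = self.dp, self.tree
        prep = dp.prep
        if dp.origination == "root":
            self._orig_root()
        else:
            segs = []
            for g, w in enumerate(dp.orig_weights):
                for k, e in enumerate(dp.sliced.live[g]):
                    segs.append((g, int(e), w[k]))
            i = self._choose([s[2] for s in segs])
            g, e, _ = segs[i]
            t_orig = 0.5 * (self.times[g] + self.times[g + 1])
            self.events.append(Event("origination", tree.labels[e], t_orig))
            self.lineage(prep.root_clade, e, g + 1)
        return SampledReconciliation(
            events=list(self.events),
            node_copies={tree.labels[i]: int(self.copies[i])
                         for i in range(tree.n_nodes)},
        )

    def _orig_root(self):
        dp, tree = self.dp, self.tree
        prep = dp.prep
        root = tree.root
        G = len(self.times) - 1
        self.events.append(
            Event("origination", tree.labels[root], tree.root_age))
        self.copies[root] += 1
        E, P = dp.bottom_states[G] if dp.store else (None, None)
        lc, rc = tree.children(root)
        gamma = prep.root_clade
        terms, actions = self._speciation_terms(gamma, lc, rc, E, P, G)
        i = self._choose(terms)
        actions[i]()

    def _speciation_terms(self, gamma, lc, rc, E, P, j):
        prep = self.dp.prep
        terms, actions = [], []
        for (a, b, w) in prep.ccp.splits[gamma]:
            for (g1, g2) in ((a, b), (b, a)):
                terms.append(w * P[g1, lc] * P[g2, rc])
                actions.append(lambda g1=g1, g2=g2: (
                    self.lineage(g1, lc, j), self.lineage(g2, rc, j)))
        terms.append(P[gamma, lc] * E[rc])
        actions.append(lambda: (self.lineage(gamma, lc, j), self.ghost(rc, j)))
        terms.append(P[gamma, rc] * E[lc])
        actions.append(lambda: (self.lineage(gamma, rc, j), self.ghost(lc, j)))
        return terms, actions

    # ---------------------------------------------------------------- observed
    def lineage(self, gamma: int, e: int, j: int):
        """Observed lineage realizing clade ``gamma`` on branch ``e`` at
        grid time index ``j`` (value taken from the pre-merge state)."""
        tree, dp = self.tree, self.dp
        prep = dp.prep
        if j == 0:
            self.copies[e] += 1
            return
        if abs(tree.ages[e] - self.times[j]) < 1e-9 * max(tree.root_age, 1.0) \
                and tree.left[e] != -1:
            # lineage sits at internal node e: speciation
            self.copies[e] += 1
            E, P = dp.pre_states[j]
            lc, rc = tree.children(e)
            terms, actions = self._speciation_terms(gamma, lc, rc, E, P, j)
            i = self._choose(terms)
            actions[i]()
            return
        # within segment j-1
        d, t, l = self.rates
        g = j - 1
        h = self.times[j] - self.times[g]
        live = dp.sliced.live[g]
        n = len(live)
        E, P = dp.bottom_states[g]
        tmid = 0.5 * (self.times[g] + self.times[j])
        total = d + t + l
        others = live[live != e]

        terms = [(1.0 - h * total) * P[gamma, e]]
        actions = [lambda: self.lineage(gamma, e, g)]
        for (a, b, w) in prep.ccp.splits[gamma]:
            terms.append(h * d * w * P[a, e] * P[b, e])
            actions.append(lambda a=a, b=b: (
                self.events.append(Event("duplication", tree.labels[e], tmid)),
                self.lineage(a, e, g), self.lineage(b, e, g)))
        terms.append(h * d * 2.0 * E[e] * P[gamma, e])
        actions.append(lambda: (
            self.events.append(Event("duplication", tree.labels[e], tmid)),
            self.ghost(e, g), self.lineage(gamma, e, g)))
        if t > 0 and n > 1:
            for (a, b, w) in prep.ccp.splits[gamma]:
                for (stay, move) in ((a, b), (b, a)):
                    for f in others:
                        terms.append(h * t * w * P[stay, e] * P[move, f]
                                     / (n - 1))
                        actions.append(lambda stay=stay, move=move, f=int(f): (
                            self.events.append(Event(
                                "transfer", tree.labels[e], tmid,
                                recipient=tree.labels[f])),
                            self.lineage(stay, e, g),
                            self.lineage(move, f, g)))
            for f in others:
                # transferred copy goes extinct on f
                terms.append(h * t * E[f] * P[gamma, e] / (n - 1))
                actions.append(lambda f=int(f): (
                    self.events.append(Event("transfer", tree.labels[e], tmid,
                                             recipient=tree.labels[f])),
                    self.ghost(f, g), self.lineage(gamma, e, g)))
                # donor copy goes extinct, moved copy realizes gamma
                terms.append(h * t * E[e] * P[gamma, f] / (n - 1))
                actions.append(lambda f=int(f): (
                    self.events.append(Event("transfer", tree.labels[e], tmid,
                                             recipient=tree.labels[f])),
                    self.ghost(e, g), self.lineage(gamma, f, g)))
        i = self._choose(terms)
        actions[i]()

    # ------------------------------------------------------------------ ghost
    def ghost(self, e: int, j: int):
        """Lineage on branch ``e`` at grid index ``j`` destined to leave no
        sampled descendants; realizes explicit loss events."""
        tree, dp = self.tree, self.dp
        if j == 0:
            raise FloatingPointError("ghost lineage reached the present")
        if abs(tree.ages[e] - self.times[j]) < 1e-9 * max(tree.root_age, 1.0) \
                and tree.left[e] != -1:
            self.copies[e] += 1
            lc, rc = tree.children(e)
            self.ghost(lc, j)
            self.ghost(rc, j)
            return
        d, t, l = self.rates
        g = j - 1
        h = self.times[j] - self.times[g]
        live = dp.sliced.live[g]
        n = len(live)
        E, _ = dp.bottom_states[g]
        tmid = 0.5 * (self.times[g] + self.times[j])
        total = d + t + l
        others = live[live != e]

        terms = [h * l, (1.0 - h * total) * E[e], h * d * E[e] ** 2]
        actions = [
            lambda: self.events.append(Event("loss", tree.labels[e], tmid)),
            lambda: self.ghost(e, g),
            lambda: (self.events.append(
                Event("duplication", tree.labels[e], tmid)),
                self.ghost(e, g), self.ghost(e, g)),
        ]
        if t > 0 and n > 1:
            for f in others:
                terms.append(h * t * E[e] * E[f] / (n - 1))
                actions.append(lambda f=int(f): (
                    self.events.append(Event("transfer", tree.labels[e], tmid,
                                             recipient=tree.labels[f])),
                    self.ghost(e, g), self.ghost(f, g)))
        i = self._choose(terms)
        actions[i]()


def _aggregate_samples(tree: DatedSpeciesTree, samples):
    labels = tree.labels
    idx = {lab: i for i, lab in enumerate(labels)}
    cols = ["dup", "trans_in", "trans_out", "loss", "orig"]
    acc = np.zeros((len(labels), len(cols)))
    copies = np.zeros(len(labels))
    for s in samples:
        for ev in s.events:
            i = idx[ev.donor]
            if ev.kind == "duplication":
                acc[i, 0] += 1
            elif ev.kind == "transfer":
                acc[idx[ev.recipient], 1] += 1
                acc[i, 2] += 1
            elif ev.kind == "loss":
                acc[i, 3] += 1
            elif ev.kind == "origination":
                acc[i, 4] += 1
        for lab, c in s.node_copies.items():
            copies[idx[lab]] += c
    acc /= len(samples)
    copies /= len(samples)
    expected = pd.DataFrame(acc, index=labels, columns=cols)
    return expected, pd.Series(copies, index=labels)


def sample_events(
    family: GeneFamily,
    sliced: TimeSlicedTree,
    rates: DTLRates,
    n_samples: int = 100,
    seed: int = 0,
    origination: str = "uniform_branch",
    condition_on_survival: bool = True,
    keep_samples: bool = True,
) -> ReconciliationResult:
    """Draw reconciliations by stochastic backtracking of the DP.

    Expected per-branch event counts and per-node copy numbers are means over
    the sampled reconciliations.  Copy numbers include lineages that later go
    extinct, so for every sample the bookkeeping identity

        copies(child) = copies(parent) + gains(branch) - losses(branch)

    holds exactly, with gains = duplications + incoming transfers +
    originations on the branch.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    prep = _PreparedFamily(family, sliced.tree)
    dp = _DP(prep, sliced, rates, origination, store=True)
    if dp.raw == 0.0:
        raise FloatingPointError(
            f"family {family.family_id} has zero likelihood; cannot sample")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0x5A)))
    samples = [_Backtracker(dp, rng).run() for _ in range(n_samples)]
    expected, copies = _aggregate_samples(sliced.tree, samples)
    return ReconciliationResult(
        family_id=family.family_id,
        loglik=dp.loglik(condition_on_survival),
        rates=rates,
        expected_events=expected,
        expected_copies=copies,
        samples=samples if keep_samples else None,
    )


# --------------------------------------------------------------------------
# copy-number profile likelihood (no gene tree)
# --------------------------------------------------------------------------

def profile_loglik(
    family: GeneFamily,
    sliced: TimeSlicedTree,
    rates: DTLRates,
    max_copies: int = 10,
    origination: str = "uniform_branch",
    condition_on_survival: bool = True,
) -> float:
    """Likelihood of tip copy numbers alone under a birth--death gene process.

    Copies duplicate at rate ``delta`` and are lost at rate ``lambda`` along
    each branch (a linear birth--death process on the copy count, truncated at
    ``max_copies``); at speciations the count is inherited by both children.
    Transfers are not modelled in profile mode.
    """
    from scipy.linalg import expm

    if family.tip_copy_numbers is None:
        raise ValueError("profile_loglik needs tip copy numbers")
    tree = sliced.tree
    d, _t, l = rates.as_tuple()
    K = max_copies
    Q = np.zeros((K + 1, K + 1))
    for k in range(K + 1):
        if k < K:
            Q[k, k + 1] = d * k
        if k > 0:
            Q[k, k - 1] = l * k
        Q[k, k] = -Q[k].sum()

    counts = family.tip_copy_numbers
    for sp, c in counts.items():
        if c > K:
            raise ValueError(f"tip count {c} exceeds max_copies={K}")

    # g[v][k] = P(data below node v | k copies at node v)
    g: dict[int, np.ndarray] = {}
    # f[e][k] = P(data below branch e | k copies at the top of branch e)
    f: dict[int, np.ndarray] = {}
    for v in tree.postorder():
        if tree.left[v] == -1:
            vec = np.zeros(K + 1)
            vec[counts.get(tree.labels[v], 0)] = 1.0
            g[v] = vec
        else:
            lc, rc = tree.children(v)
            g[v] = f[lc] * f[rc]
        if tree.parent[v] != -1:
            M = expm(Q * tree.branch_duration(v))
            f[v] = M @ g[v]

    zero = {sp: 0 for sp in tree.tip_labels}
    all_zero = all(counts.get(sp, 0) == 0 for sp in tree.tip_labels)

    def orig_like(gtab, tip_counts):
        # origination on branch e also requires zero observed copies in
        # every tip outside e's subtree
        def outside_zero(e):
            below = tree.clade(e)
            return all(tip_counts.get(sp, 0) == 0
                       for sp in tree.tip_labels if sp not in below)

        if origination == "root":
            root = tree.root
            return float(gtab[root][1])
        T_tot = tree.total_branch_duration
        tot = 0.0
        for e in tree.branch_nodes:
            if not outside_zero(int(e)):
                continue
            dur = tree.branch_duration(e)
            # integrate origin time uniformly over the branch at slice scale
            npts = max(2, sliced.n_slices_per_interval + 1)
            ts = np.linspace(0, dur, npts)
            vals = [float((expm(Q * s) @ gtab[e])[1]) for s in ts]
            tot += np.trapezoid(vals, ts) / T_tot
        return tot

    # g at branch-child nodes is what origination on the branch sees
    gtab = {int(e): g[int(e)] for e in tree.branch_nodes}
    gtab[tree.root] = g[tree.root]
    L = orig_like(gtab, counts)
    if condition_on_survival and not all_zero:
        gz: dict[int, np.ndarray] = {}
        fz: dict[int, np.ndarray] = {}
        for v in tree.postorder():
            if tree.left[v] == -1:
                vec = np.zeros(K + 1)
                vec[0] = 1.0
                gz[v] = vec
            else:
                lc, rc = tree.children(v)
                gz[v] = fz[lc] * fz[rc]
            if tree.parent[v] != -1:
                M = expm(Q * tree.branch_duration(v))
                fz[v] = M @ gz[v]
        gztab = {int(e): gz[int(e)] for e in tree.branch_nodes}
        gztab[tree.root] = gz[tree.root]
        p0 = orig_like(gztab, {})
        L = L / max(1.0 - p0, 1e-300)
    if L <= 0:
        return -np.inf
    return math.log(L)
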