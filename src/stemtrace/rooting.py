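"""Root inference for species trees from summed reconciliation likelihoods.

Candidate roots are branches of an unrooted species tree.  Each candidate
induces a rooted topology, which is scaled to geological time and used to
reconcile every gene family; candidates are then compared by their summed
per-family log-likelihoods, and an approximately unbiased (AU) test over the
per-family likelihood contributions defines the credible root set.  A
family-filtering scan checks that the root ranking is robust to removing the
families with the highest fitted DTL rates, whose evolution the model may
describe poorly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy.stats import norm

from .reconciliation import (
    DTLRates,
    GeneFamily,
    discretize,
    family_loglik,
    fit_rates,
)
from .trees import DatedSpeciesTree, TreeError

__all__ = [
    "RootCandidate",
    "LikelihoodMatrix",
    "AUTestResult",
    "enumerate_roots",
    "scale_to_ages",
    "assign_ages_from_reference",
    "root_scan",
    "au_test",
    "dtl_filter_scan",
]

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# unrooted trees and candidate roots
# --------------------------------------------------------------------------

class _UnrootedTree:
    """Adjacency representation of an unrooted binary tree."""

    def __init__(self, newick: str):
        tree = dendropy.Tree.get(data=newick, schema="newick",
                                 preserve_underscores=True)
        tree.deroot()  # force the basal trifurcation form
        self.adj: dict[int, list[int]] = {}
        self.label: dict[int, str] = {}
        nodes = list(tree.preorder_node_iter())
        idx = {id(nd): i for i, nd in enumerate(nodes)}
        for nd in nodes:
            i = idx[id(nd)]
            self.adj.setdefault(i, [])
            if nd.taxon is not None:
                self.label[i] = nd.taxon.label
            for ch in nd.child_nodes():
                j = idx[id(ch)]
                self.adj[i].append(j)
                self.adj.setdefault(j, []).append(i)
        self.tips = sorted(self.label.values())
        if len(self.tips) < 3:
            raise TreeError("unrooted tree needs at least 3 tips")

    def edges(self) -> list[tuple[int, int]]:
        out = []
        for i, nbrs in self.adj.items():
            for j in nbrs:
                if i < j:
                    out.append((i, j))
        return out

    def side_tips(self, u: int, away_from: int) -> frozenset:
        """Tip labels reachable from ``u`` without crossing ``away_from``."""
        seen, stack, tips = {away_from, u}, [u], []
        if u in self.label:
            tips.append(self.label[u])
        while stack:
            v = stack.pop()
            for w in self.adj[v]:
                if w not in seen:
                    seen.add(w)
                    stack.append(w)
                    if w in self.label:
                        tips.append(self.label[w])
        return frozenset(tips)


def _bipartition_id(side_a: frozenset, side_b: frozenset) -> str:
    small = min(side_a, side_b, key=lambda s: (len(s), tuple(sorted(s))))
    return ",".join(sorted(small))


@dataclass
class RootCandidate:
    """One candidate root: a branch of the unrooted tree.

    ``candidate_id`` is the smaller side of the branch's tip bipartition
    (comma-joined sorted tip names), which is stable across tree rewrites.
    """

    candidate_id: str
    bipartition: tuple[frozenset, frozenset]
    rooted_newick: str
    dated: DatedSpeciesTree | None = None


def enumerate_roots(unrooted_newick: str, candidate_branches=None
                    ) -> list[RootCandidate]:
    """One rooted topology per candidate branch of an unrooted binary tree.

    ``candidate_branches`` is either ``None`` (all 2n-3 branches) or a list
    of candidate ids as produced by :func:`_bipartition_id` (the sorted,
    comma-joined smaller bipartition side).
    """
    ut = _UnrootedTree(unrooted_newick)
    out = []
    for (u, v) in ut.edges():
        side_u = ut.side_tips(u, away_from=v)
        side_v = ut.side_tips(v, away_from=u)
        cid = _bipartition_id(side_u, side_v)
        newick = _root_on_edge(ut, u, v)
        out.append(RootCandidate(candidate_id=cid,
                                 bipartition=(side_u, side_v),
                                 rooted_newick=newick))
    out.sort(key=lambda c: c.candidate_id)
    if candidate_branches is not None:
        by_id = {c.candidate_id: c for c in out}
        missing = [b for b in candidate_branches if b not in by_id]
        if missing:
            raise TreeError(f"candidate branches not found: {missing}")
        out = [by_id[b] for b in candidate_branches]
    return out


def _root_on_edge(ut: _UnrootedTree, u: int, v: int) -> str:
    def render(node, parent) -> str:
        kids = [w for w in ut.adj[node] if w != parent]
        if not kids:
            return ut.label[node]
        return "(" + ",".join(render(w, node) for w in kids) + ")"

    return f"({render(u, v)},{render(v, u)});"


# --------------------------------------------------------------------------
# assigning ages to rooted topologies
# --------------------------------------------------------------------------

def scale_to_ages(rooted_newick: str, age_table: pd.DataFrame
                  ) -> DatedSpeciesTree:
    """Scale a rooted topology to geological time from a clade age table.

    ``age_table`` has columns ``clade_tips`` (comma-joined tip names, order
    irrelevant) and ``age_Ma``.  Every internal node must be matched by clade
    membership; a child assigned an age older than its parent is a hard
    error naming the offending clades.
    """
    tree = _topology_arrays(rooted_newick)
    ages_by_clade = {
        frozenset(str(r.clade_tips).split(",")): float(r.age_Ma)
        for r in age_table.itertuples()
    }
    offenders = []
    for v in tree.internal_nodes:
        cl = tree.clade(v)
        if cl not in ages_by_clade:
            raise TreeError(f"no age for clade {sorted(cl)}")
        tree.ages[v] = ages_by_clade[cl]
    for v in tree.branch_nodes:
        if tree.left[v] != -1 and tree.ages[tree.parent[v]] <= tree.ages[v]:
            offenders.append((sorted(tree.clade(v)),
                              sorted(tree.clade(tree.parent[v]))))
    if offenders:
        raise TreeError(f"age table inconsistent with topology: child clades "
                        f"older than parents: {offenders}")
    tree.validate()
    return tree


def assign_ages_from_reference(rooted_newick: str,
                               reference: DatedSpeciesTree
                               ) -> DatedSpeciesTree:
    """Date an alternatively rooted topology from a reference dated tree.

    Clades shared with the reference inherit its node ages; clades that exist
    only under the alternative root are assigned midpoint ages between the
    nearest dated ancestor and their oldest dated descendant (or 0 when all
    descendants are tips).  The candidate root inherits the reference root
    age, as both span the full tip set.
    """
    tree = _topology_arrays(rooted_newick)
    ref_ages = {reference.clade(v): float(reference.ages[v])
                for v in reference.internal_nodes}
    if frozenset(tree.tip_labels) != frozenset(reference.tip_labels):
        raise TreeError("tip sets differ between topology and reference")

    known = np.full(tree.n_nodes, np.nan)
    for v in tree.internal_nodes:
        cl = tree.clade(v)
        if cl in ref_ages:
            known[v] = ref_ages[cl]
    root = tree.root
    if np.isnan(known[root]):
        # the root clade is the full tip set; always present in the reference
        known[root] = reference.root_age
    # oldest dated clade below each node
    max_below = np.zeros(tree.n_nodes)
    for v in tree.postorder():
        if tree.left[v] == -1:
            continue
        m = 0.0
        for c in tree.children(v):
            m = max(m, max_below[c],
                    known[c] if not np.isnan(known[c]) else 0.0)
        max_below[v] = m
    # top-down midpoint interpolation for novel clades
    order = [v for v in reversed(tree.postorder()) if tree.left[v] != -1]
    for v in order:
        if not np.isnan(known[v]):
            tree.ages[v] = known[v]
        else:
            pa = tree.ages[tree.parent[v]]
            tree.ages[v] = 0.5 * (pa + max_below[v])
    tree.validate()
    return tree


def _topology_arrays(rooted_newick: str) -> DatedSpeciesTree:
    """Parse a rooted topology into arrays with placeholder ages."""
    t = dendropy.Tree.get(data=rooted_newick, schema="newick",
                          preserve_underscores=True)
    nodes = list(t.preorder_node_iter())
    idx = {id(nd): i for i, nd in enumerate(nodes)}
    n = len(nodes)
    parent = np.full(n, -1, int)
    left = np.full(n, -1, int)
    right = np.full(n, -1, int)
    labels = []
    k = 0
    for i, nd in enumerate(nodes):
        if nd.parent_node is not None:
            parent[i] = idx[id(nd.parent_node)]
        kids = nd.child_nodes()
        if kids:
            if len(kids) != 2:
                raise TreeError("rooted topology must be binary")
            left[i], right[i] = idx[id(kids[0])], idx[id(kids[1])]
            k += 1
            labels.append(f"n{k}")
        else:
            labels.append(nd.taxon.label)
    depth = np.zeros(n)
    for i in range(n):
        if parent[i] != -1:
            depth[i] = depth[parent[i]] + 1
    ages = (depth.max() - depth)  # placeholder, strictly decreasing tipward
    ages[left == -1] = 0.0
    return DatedSpeciesTree(parent=parent, left=left, right=right,
                            ages=ages, labels=labels)


# --------------------------------------------------------------------------
# root scan
# --------------------------------------------------------------------------

@dataclass
class LikelihoodMatrix:
    """Per-family x per-candidate log-likelihoods."""

    table: pd.DataFrame        # index family ids, columns candidate ids

    @property
    def summed(self) -> pd.Series:
        return self.table.sum(axis=0)

    @property
    def best_candidate(self) -> str:
        return self.summed.idxmax()

    def validate(self) -> None:
        if not np.all(np.isfinite(self.table.values)):
            raise ValueError("likelihood matrix has non-finite entries")


def root_scan(
    families: list[GeneFamily],
    candidates: list[RootCandidate],
    rate_mode: str = "fixed",
    rates: DTLRates | None = None,
    n_slices_per_interval: int = 3,
    origination: str = "uniform_branch",
) -> LikelihoodMatrix:
    """Reconcile every family under every dated candidate root.

    ``rate_mode``:

    * ``"fixed"`` -- use ``rates`` for all families and candidates;
    * ``"global"`` -- fit one pooled rate triple per candidate;
    * ``"per_family"`` -- refit rates for each family under each candidate.

    Families that fail reconciliation under any candidate are dropped from
    all columns (the comparison stays paired) and logged.
    """
    for c in candidates:
        if c.dated is None:
            raise TreeError(f"candidate {c.candidate_id} has no dated tree; "
                            "call assign_ages_from_reference/scale_to_ages")
    if rate_mode == "fixed" and rates is None:
        raise ValueError("rate_mode='fixed' requires rates")

    cols = {}
    failed: set[str] = set()
    for c in candidates:
        sliced = discretize(c.dated, n_slices_per_interval)
        if rate_mode == "global":
            fit = fit_rates(families, sliced, origination=origination)
            use = fit.rates
        col = {}
        for fam in families:
            try:
                if rate_mode == "per_family":
                    fit = fit_rates([fam], sliced, origination=origination)
                    ll = fit.loglik
                elif rate_mode == "global":
                    ll = family_loglik(fam, sliced, use, origination)
                else:
                    ll = family_loglik(fam, sliced, rates, origination)
                if not np.isfinite(ll):
                    raise FloatingPointError("non-finite log-likelihood")
                col[fam.family_id] = ll
            except Exception as exc:  # noqa: BLE001 - paired exclusion
                failed.add(fam.family_id)
                logger.warning("family %s failed under candidate %s: %s",
                               fam.family_id, c.candidate_id, exc)
        cols[c.candidate_id] = col
    table = pd.DataFrame(cols)
    if failed:
        table = table.drop(index=[f for f in failed if f in table.index])
        logger.warning("excluded %d families from all candidates", len(failed))
    table = table.dropna()
    mat = LikelihoodMatrix(table=table)
    mat.validate()
    return mat


# --------------------------------------------------------------------------
# AU test (multiscale RELL bootstrap)
# --------------------------------------------------------------------------

@dataclass
class AUTestResult:
    pvalues: pd.Series
    summed: pd.Series
    alpha: float
    n_boot: int
    scales: tuple
    seed: int
    bootstrap_proportions: pd.DataFrame = field(repr=False, default=None)

    def credible_set(self, alpha: float | None = None) -> list[str]:
        a = self.alpha if alpha is None else alpha
        return sorted(self.pvalues.index[self.pvalues >= a])


def au_test(
    matrix: LikelihoodMatrix,
    n_boot: int = 1000,
    scales: tuple = (0.5, 0.6, 0.7, 0.8, 0.9, 1.0, 1.1, 1.2, 1.3, 1.4),
    seed: int = 0,
    alpha: float = 0.05,
) -> AUTestResult:
    """Approximately unbiased test over per-family log-likelihoods.

    Multiscale RELL bootstrap: family rows are resampled with replacement at
    relative sample sizes ``scales``; for each scale the bootstrap proportion
    of replicates in which each candidate attains the maximum summed score is
    recorded (candidates tied at the maximum share the win equally, so
    duplicated columns receive identical p-values).  The signed
    distance ``d`` and curvature ``c`` are fitted per candidate by weighted
    least squares of the probit-transformed proportions on ``(sqrt(r),
    1/sqrt(r))``, and ``p_AU = 1 - Phi(d - c)``.

    Bootstrap proportions of exactly 0 or 1 are continuity-corrected to
    ``0.5/n_boot`` from the boundary before the probit transform.
    """
    X = matrix.table.values
    F, K = X.shape
    if K < 2 or F < 2:
        raise ValueError("need at least 2 candidates and 2 families")
    cand = list(matrix.table.columns)
    summed = matrix.summed

    if np.allclose(X, X[:, [0]]):
        warnings.warn("all candidate columns identical; AU p-values are 1")
        p = pd.Series(1.0, index=cand)
        return AUTestResult(p, summed, alpha, n_boot, tuple(scales), seed)

    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xA0)))
    bp = np.zeros((K, len(scales)))
    for si, r in enumerate(scales):
        m = max(1, int(round(r * F)))
        idx = rng.integers(F, size=(n_boot, m))
        sums = X[idx].sum(axis=1)                    # n_boot x K
        mx = sums.max(axis=1, keepdims=True)
        tied = sums == mx
        shares = tied / tied.sum(axis=1, keepdims=True)
        bp[:, si] = shares.mean(axis=0)

    eps = 0.5 / n_boot
    pvals = np.empty(K)
    rr = np.asarray([max(1, int(round(r * F))) / F for r in scales])
    for k in range(K):
        b = bp[k]
        if np.all(b <= 0):
            pvals[k] = 0.0
            continue
        if np.all(b >= 1):
            pvals[k] = 1.0
            continue
        bc = np.clip(b, eps, 1 - eps)
        z = norm.ppf(1 - bc)                         # signed distance at scale
        # WLS of z on (sqrt(r), 1/sqrt(r)); weights from binomial delta method
        w = n_boot * norm.pdf(z) ** 2 / (bc * (1 - bc))
        A = np.column_stack([np.sqrt(rr), 1 / np.sqrt(rr)])
        Aw = A * w[:, None]
        try:
            beta = np.linalg.solve(A.T @ Aw, Aw.T @ z)
        except np.linalg.LinAlgError:  # pragma: no cover
            beta = np.linalg.lstsq(Aw, z * w, rcond=None)[0]
        d, c = beta
        pvals[k] = 1 - norm.cdf(d - c)
    p = pd.Series(pvals, index=cand)
    return AUTestResult(
        pvalues=p, summed=summed, alpha=alpha, n_boot=n_boot,
        scales=tuple(scales), seed=seed,
        bootstrap_proportions=pd.DataFrame(bp, index=cand, columns=scales),
    )


# --------------------------------------------------------------------------
# high-DTL family filtering scan
# --------------------------------------------------------------------------

def dtl_filter_scan(
    matrix: LikelihoodMatrix,
    family_total_rates: pd.Series,
    removal_fractions=(0.0, 0.05, 0.1, 0.2),
) -> pd.DataFrame:
    """Re-rank candidate roots after removing high-DTL-rate families.

    Families are ranked by their total fitted DTL rate (duplication +
    transfer + loss); for each removal fraction the top families are dropped
    and the candidate ranking recomputed from the remaining likelihood rows.
    The report states, per fraction, the ranking and whether it equals the
    full-data ranking.
    """
    for f in removal_fractions:
        if not 0 <= f < 1:
            raise ValueError("removal fractions must lie in [0, 1)")
    totals = family_total_rates.reindex(matrix.table.index)
    if totals.isna().any():
        raise ValueError("missing fitted rates for some families")
    order = totals.sort_values(ascending=False).index
    base_rank = tuple(matrix.summed.sort_values(ascending=False).index)
    rows = []
    for f in sorted(removal_fractions):
        n_remove = int(round(f * len(order)))
        keep = matrix.table.drop(index=order[:n_remove])
        sums = keep.sum(axis=0)
        rank = tuple(sums.sort_values(ascending=False).index)
        rows.append({
            "fraction_removed": f,
            "n_families": len(keep),
            "ranking": ">".join(rank),
            "top_candidate": rank[0],
            "ranking_unchanged": rank == base_rank,
        })
    return pd.DataFrame(rows)
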