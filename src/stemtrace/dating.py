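"""Bayesian divergence-time estimation on a fixed rooted topology.

The model follows the relative-node-dating approach: the phylogenetic
likelihood is approximated by a multivariate normal distribution over branch
lengths (mean and covariance estimated from a posterior sample of branch
lengths, e.g. from a Bayesian sequence analysis); branch rates are iid
lognormal with mean ``mu`` and log-scale spread ``sigma``; node ages carry a
conditional-on-root uniform kernel prior; fossil calibrations are soft-bounded
uniforms with fixed tail probabilities; and horizontal gene transfers
contribute hard relative node-order constraints (donor-side node strictly
older than the recipient node).  Sampling is by random-walk Metropolis within
Metropolis-coupled MCMC (MC3) with a tailored set of proposals executed in
random order per iteration.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, cho_solve

from .trees import DatedSpeciesTree, TreeError

__all__ = [
    "CalibrationConstraint",
    "RelativeConstraint",
    "ClockModel",
    "BranchLengthPosterior",
    "PosteriorTrace",
    "estimate_blp",
    "calibration_logprior",
    "relative_constraint_check",
    "approx_loglik",
    "run_dating_mcmc",
    "posterior_to_prior",
    "diagnostics",
]


# --------------------------------------------------------------------------
# constraints and priors
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CalibrationConstraint:
    """Soft-bounded uniform age calibration on the MRCA of ``tips``.

    The density is flat on ``[min_age, max_age]`` carrying mass
    ``1 - 2 * tail_prob``; each side carries ``tail_prob`` -- a power tail
    decaying towards 0 below the minimum and an exponential tail above the
    maximum, both continuous with the plateau.  With no maximum, the density
    above ``min_age`` decays exponentially with scale ``min_age`` and the
    lower tail keeps mass ``tail_prob``.
    """

    tips: tuple
    min_age: float
    max_age: float | None = None
    tail_prob: float = 0.01

    def __post_init__(self):
        if not 0 < self.tail_prob < 0.5:
            raise ValueError("tail_prob must lie in (0, 0.5)")
        if self.min_age <= 0:
            raise ValueError("min_age must be positive")
        if self.max_age is not None and self.min_age >= self.max_age:
            raise ValueError("min_age must be smaller than max_age")


@dataclass(frozen=True)
class RelativeConstraint:
    """Hard order constraint: MRCA(older_tips) strictly predates
    MRCA(younger_tips); e.g. an HGT donor lineage and its recipient."""

    older_tips: tuple
    younger_tips: tuple
    note: str = ""

    def __post_init__(self):
        if frozenset(self.older_tips) == frozenset(self.younger_tips):
            raise ValueError("constraint nodes must be distinct")


def calibration_logprior(age: float, c: CalibrationConstraint) -> float:
    """Log-density of the soft-bounded calibration at ``age``; proper."""
    if age <= 0:
        return -np.inf
    p = c.tail_prob
    lo = c.min_age
    if c.max_age is None:
        # exponential body above the minimum, power tail below
        scale = lo
        h = (1 - p) / scale
        if age >= lo:
            return math.log(h) - (age - lo) / scale
        return _lower_tail_logpdf(age, lo, h, p)
    hi = c.max_age
    h = (1 - 2 * p) / (hi - lo)
    if lo <= age <= hi:
        return math.log(h)
    if age > hi:
        s = p / h
        return math.log(h) - (age - hi) / s
    return _lower_tail_logpdf(age, lo, h, p)


def _lower_tail_logpdf(age: float, lo: float, h: float, p: float) -> float:
    """Lower tail on (0, lo) with total mass ``p``.

    Power tail ``h * (x/lo)**c`` continuous with the plateau when
    ``h * lo >= p``; otherwise (a plateau too low to feed a decreasing tail)
    a uniform tail of height ``p / lo`` is used instead.
    """
    if h * lo >= p:
        cexp = h * lo / p - 1.0
        return math.log(h) + cexp * (math.log(age) - math.log(lo))
    return math.log(p / lo)


def relative_constraint_check(
    ages: dict[str, float],
    constraints: list[RelativeConstraint],
    tree: DatedSpeciesTree,
) -> tuple[bool, list[RelativeConstraint]]:
    """True iff every older-node age strictly exceeds its younger-node age.

    ``ages`` maps node labels to ages; constraint tip sets are resolved to
    MRCA labels on ``tree``.  A cyclic constraint set is a hard error.
    """
    pairs = [(tree.labels[tree.mrca(c.older_tips)],
              tree.labels[tree.mrca(c.younger_tips)], c) for c in constraints]
    _check_acyclic([(a, b) for a, b, _ in pairs])
    offending = [c for a, b, c in pairs if not ages[a] > ages[b]]
    return (len(offending) == 0, offending)


def _check_acyclic(edges: list[tuple[str, str]]) -> None:
    graph: dict[str, list[str]] = {}
    for a, b in edges:
        graph.setdefault(a, []).append(b)
        graph.setdefault(b, [])
    state: dict[str, int] = {}

    def visit(v):
        state[v] = 1
        for w in graph[v]:
            if state.get(w) == 1:
                raise ValueError("relative constraint set is cyclic")
            if w not in state:
                visit(w)
        state[v] = 2

    for v in graph:
        if v not in state:
            visit(v)


# --------------------------------------------------------------------------
# clock model
# --------------------------------------------------------------------------

@dataclass
class ClockModel:
    """iid lognormal branch rates with hyperpriors on mean and spread.

    ``mu`` is the expected branch rate (substitutions/site/Myr) and ``sigma``
    the standard deviation of log rate among branches.  Hyperpriors are
    either gamma (``("gamma", shape, scale)``) or exponential
    (``("exponential", mean)``); the node-age prior kernel is uniform
    conditional on the root age by default, with a birth--death kernel
    available.
    """

    mu_prior: tuple = ("gamma", 2.0, 10.0)
    sigma_prior: tuple = ("gamma", 1.0, 10.0)
    birth: float = 1.0
    death: float = 1.0
    kernel: str = "uniform"

    @classmethod
    def mcmctree_profile(cls) -> "ClockModel":
        """Gamma hyperpriors as printed: shape 2 scale 10 on the mean rate,
        shape 1 scale 10 on the rate spread; uniform node-age kernel."""
        return cls(mu_prior=("gamma", 2.0, 10.0),
                   sigma_prior=("gamma", 1.0, 10.0))

    @classmethod
    def mcmcdate_profile(cls) -> "ClockModel":
        """Exponential hyperpriors with mean 1.0 on the rate mean and spread
        (and on birth/death when the birth--death kernel is used)."""
        return cls(mu_prior=("exponential", 1.0),
                   sigma_prior=("exponential", 1.0))

    @staticmethod
    def _hyper_logpdf(value: float, spec: tuple) -> float:
        if value <= 0:
            return -np.inf
        if spec[0] == "gamma":
            _, shape, scale = spec
            return float(stats.gamma.logpdf(value, shape, scale=scale))
        if spec[0] == "gamma_rate":
            _, shape, rate = spec
            return float(stats.gamma.logpdf(value, shape, scale=1.0 / rate))
        if spec[0] == "exponential":
            _, mean = spec
            return -value / mean - math.log(mean)
        raise ValueError(f"unknown hyperprior {spec!r}")


# --------------------------------------------------------------------------
# branch-length pseudo-likelihood
# --------------------------------------------------------------------------

@dataclass
class BranchLengthPosterior:
    """MVN summary (mean, covariance) of branch-length posterior samples."""

    mean: pd.Series
    cov: pd.DataFrame
    ridge: float = 0.0
    _chol: tuple = field(default=None, repr=False)

    @property
    def branches(self) -> list[str]:
        return list(self.mean.index)

    def _factor(self):
        if self._chol is None:
            C = self.cov.values
            fac = cho_factor(C, lower=True)
            logdet = 2.0 * np.sum(np.log(np.diag(fac[0])))
            object.__setattr__(self, "_chol", (fac, logdet))
        return self._chol

    def logpdf(self, lengths: np.ndarray) -> float:
        fac, logdet = self._factor()
        d = lengths - self.mean.values
        q = float(d @ cho_solve(fac, d))
        k = len(d)
        return -0.5 * (k * math.log(2 * math.pi) + logdet + q)


def estimate_blp(samples: pd.DataFrame) -> BranchLengthPosterior:
    """Mean and covariance of a branch-length sample matrix.

    Positive definiteness is enforced by the smallest diagonal ridge that
    lifts all eigenvalues above ``1e-10 * mean(diag)``; the ridge used is
    reported on the result and a warning is emitted when the sample is too
    small for a full-rank covariance.
    """
    if samples.shape[0] < 2 or samples.shape[1] < 1:
        raise ValueError("need >= 2 samples of >= 1 branch")
    mean = samples.mean(axis=0)
    cov = np.cov(samples.values, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    k = cov.shape[0]
    if samples.shape[0] <= k:
        warnings.warn("fewer samples than branches; covariance is rank "
                      "deficient and will be ridged")
    scale = max(float(np.trace(cov)) / k, 1e-300)
    w = np.linalg.eigvalsh(cov)
    floor = 1e-10 * scale
    ridge = max(0.0, floor - float(w.min()))
    if ridge > 0:
        cov = cov + np.eye(k) * ridge
    return BranchLengthPosterior(
        mean=mean,
        cov=pd.DataFrame(cov, index=samples.columns, columns=samples.columns),
        ridge=ridge,
    )


def approx_loglik(
    ages: dict[str, float],
    rates: dict[str, float],
    blp: BranchLengthPosterior,
    tree: DatedSpeciesTree,
) -> float:
    """MVN log-density of the implied branch lengths rate x duration."""
    lengths = []
    for lab in blp.branches:
        i = tree.index_of(lab)
        dur = ages[tree.labels[tree.parent[i]]] - \
            (ages[lab] if tree.left[i] != -1 else 0.0)
        if dur <= 0:
            raise ValueError(f"non-positive duration on branch {lab}")
        lengths.append(rates[lab] * dur)
    return blp.logpdf(np.asarray(lengths))


# --------------------------------------------------------------------------
# MCMC
# --------------------------------------------------------------------------

@dataclass
class PosteriorTrace:
    """Cold-chain samples of node ages, branch rates and hyperparameters."""

    df: pd.DataFrame
    tree: DatedSpeciesTree
    seed: int
    n_chains: int
    burn_in: int
    acceptance: dict[str, float] = field(default_factory=dict)

    def ages(self) -> pd.DataFrame:
        cols = [c for c in self.df.columns if c.startswith("age_")]
        return self.df[cols].rename(columns=lambda c: c[4:])


class _DatingModel:
    """Unnormalized log-posterior over (ages, rates, mu, sigma)."""

    def __init__(self, tree, blp, calibrations, rel_constraints, clock,
                 use_likelihood, fix_root_age, node_log_priors, root_prior):
        self.tree = tree
        self.blp = blp
        self.clock = clock
        self.use_likelihood = use_likelihood and blp is not None
        self.fix_root_age = fix_root_age
        self.root = tree.root
        self.internal = [int(v) for v in tree.internal_nodes]
        self.nonroot_internal = [v for v in self.internal if v != self.root]
        self.branch_nodes = [int(v) for v in tree.branch_nodes]
        self.labels = tree.labels
        # resolve calibrations / constraints to node indices
        self.cals: list[tuple[int, CalibrationConstraint]] = []
        root_calibrated = False
        for c in calibrations:
            v = tree.mrca(c.tips)
            if tree.left[v] == -1:
                raise TreeError("calibrations must target internal nodes")
            self.cals.append((int(v), c))
            root_calibrated = root_calibrated or v == self.root
        pairs = [(tree.mrca(c.older_tips), tree.mrca(c.younger_tips))
                 for c in rel_constraints]
        _check_acyclic([(self.labels[a], self.labels[b]) for a, b in pairs])
        self.rel_pairs = [(int(a), int(b)) for a, b in pairs]
        self.node_log_priors = {tree.index_of(k): f
                                for k, f in (node_log_priors or {}).items()}
        self.root_prior = root_prior
        self.needs_root_prior = (not root_calibrated
                                 and fix_root_age is None
                                 and self.root not in self.node_log_priors)
        if self.needs_root_prior and root_prior is None:
            raise ValueError(
                "the root age must be calibrated, fixed, or given an "
                "explicit root_prior=('exponential', mean)")
        if blp is not None:
            known = set(self.labels[v] for v in self.branch_nodes)
            if set(blp.branches) != known:
                raise TreeError("branch-length posterior branches do not "
                                "match the topology")
            self.blp_rows = [tree.index_of(lab) for lab in blp.branches]

    # ---- posterior pieces -------------------------------------------------
    def log_posterior(self, ages, rates, mu, sigma):
        """ages/rates are arrays indexed by node id."""
        lp = self.log_prior(ages, rates, mu, sigma)
        if not np.isfinite(lp):
            return -np.inf, -np.inf
        ll = self.loglik(ages, rates) if self.use_likelihood else 0.0
        return lp + ll, ll

    def loglik(self, ages, rates):
        rows = self.blp_rows
        par = self.tree.parent
        durs = ages[par[rows]] - ages[rows]
        lengths = rates[rows] * durs
        return self.blp.logpdf(lengths)

    def log_prior(self, ages, rates, mu, sigma):
        tree = self.tree
        root_age = ages[self.root]
        if root_age <= 0:
            return -np.inf
        for v in self.branch_nodes:
            if ages[tree.parent[v]] <= ages[v]:
                return -np.inf
        for (a, b) in self.rel_pairs:
            if not ages[a] > ages[b]:
                return -np.inf
        lp = 0.0
        # node-age kernel conditional on the root age
        if self.clock.kernel == "uniform":
            lp += -len(self.nonroot_internal) * math.log(root_age)
        elif self.clock.kernel == "birth_death":
            lp += self._bd_kernel(ages, root_age)
        else:
            raise ValueError(f"unknown kernel {self.clock.kernel!r}")
        for v, c in self.cals:
            lp += calibration_logprior(float(ages[v]), c)
        for v, f in self.node_log_priors.items():
            lp += f(float(ages[v]))
        if self.needs_root_prior:
            kind, mean = self.root_prior
            if kind != "exponential":
                raise ValueError("root_prior must be ('exponential', mean)")
            lp += -root_age / mean - math.log(mean)
        # rates: iid lognormal with mean mu, log-sd sigma
        if mu <= 0 or sigma <= 0:
            return -np.inf
        mlog = math.log(mu) - 0.5 * sigma**2
        r = rates[self.branch_nodes]
        if np.any(r <= 0):
            return -np.inf
        logr = np.log(r)
        lp += float(np.sum(-logr - math.log(sigma) - 0.5 * math.log(2 * math.pi)
                           - 0.5 * ((logr - mlog) / sigma) ** 2))
        lp += ClockModel._hyper_logpdf(mu, self.clock.mu_prior)
        lp += ClockModel._hyper_logpdf(sigma, self.clock.sigma_prior)
        return lp

    def _bd_kernel(self, ages, root_age):
        """Conditional birth--death node-age kernel (complete sampling)."""
        lam, mu_ = self.clock.birth, self.clock.death
        lp = 0.0
        for v in self.nonroot_internal:
            t = ages[v]
            if abs(lam - mu_) < 1e-12:
                g = (1 + lam * root_age) / (root_age * (1 + lam * t) ** 2)
            else:
                r = lam - mu_
                def p1(s):
                    e = math.exp(-r * s)
                    return r**2 * e / (lam - mu_ * e) ** 2
                e1 = math.exp(-r * root_age)
                vt1 = 1 - e1 / (1 - mu_ / lam * e1) if lam > 0 else 1.0
                g = lam * p1(t) / max(vt1, 1e-300)
            lp += math.log(max(g, 1e-300))
        return lp


def _initial_state(model: _DatingModel, rng) -> tuple[np.ndarray, np.ndarray,
                                                      float, float]:
    """Deterministic-ish feasible starting point; error when none found."""
    tree = model.tree
    ages = np.zeros(tree.n_nodes)
    # root init: fixed, calibrated midpoint, or from the input tree's ages
    cal_by_node = dict(model.cals)
    if model.fix_root_age is not None:
        root_age = float(model.fix_root_age)
    elif model.root in cal_by_node:
        c = cal_by_node[model.root]
        root_age = c.min_age * 1.05 if c.max_age is None else \
            0.5 * (c.min_age + c.max_age)
    else:
        root_age = float(tree.ages[model.root])
        if root_age <= 0:
            root_age = 2.0 * max((c.min_age for _, c in model.cals),
                                 default=1.0)
    for attempt in range(200):
        ages[:] = 0.0
        ages[model.root] = root_age
        # top-down: calibrated nodes to their plateau midpoint when feasible,
        # otherwise midpoint between parent age and oldest lower bound below
        order = [v for v in reversed(tree.postorder())
                 if tree.left[v] != -1 and v != model.root]
        for v in order:
            pa = ages[tree.parent[v]]
            target = None
            if v in cal_by_node:
                c = cal_by_node[v]
                target = c.min_age * 1.05 if c.max_age is None else \
                    0.5 * (c.min_age + c.max_age)
            if target is None or not 0 < target < pa:
                target = 0.5 * pa
            ages[v] = target * (1.0 + 0.02 * rng.standard_normal()) \
                if attempt else target
            ages[v] = min(max(ages[v], 1e-6), pa * 0.999)
        # nudge relative-constraint violations
        for _ in range(20):
            ok = True
            for (a, b) in model.rel_pairs:
                if not ages[a] > ages[b]:
                    ok = False
                    ages[b] = max(ages[a] * 0.9, 1e-6)
                    for w in tree.postorder():
                        if tree.left[w] != -1:
                            lo = max(ages[tree.left[w]], ages[tree.right[w]])
                            if w != model.root and ages[w] <= lo:
                                ages[w] = lo * 1.01
            if ok:
                break
        mu0, s0 = 1e-3, 0.3
        if model.use_likelihood:
            rows = model.blp_rows
            durs = ages[tree.parent[rows]] - ages[rows]
            if np.all(durs > 0):
                implied = np.maximum(model.blp.mean.values, 1e-12) / durs
                mu0 = float(np.exp(np.mean(np.log(implied))))
        rates = np.zeros(tree.n_nodes)
        rates[model.branch_nodes] = mu0
        lp = model.log_prior(ages, rates, mu0, s0)
        if np.isfinite(lp):
            return ages.copy(), rates, mu0, s0
        root_age *= 1.1
    raise RuntimeError("no feasible starting point satisfies the "
                       "calibrations and relative constraints")


def run_dating_mcmc(
    tree: DatedSpeciesTree,
    blp: BranchLengthPosterior | None,
    calibrations: list[CalibrationConstraint],
    relative_constraints: list[RelativeConstraint] = (),
    clock: ClockModel | None = None,
    n_iter: int = 10000,
    n_chains: int = 1,
    seed: int = 0,
    burn_in_fraction: float = 0.25,
    use_likelihood: bool = True,
    fix_root_age: float | None = None,
    node_log_priors: dict | None = None,
    root_prior: tuple | None = None,
    heat_increment: float = 0.1,
    step_age: float = 0.25,
    step_scale: float = 0.2,
) -> PosteriorTrace:
    """Sample node ages and branch rates from the dating posterior.

    Proposals (executed in random order each iteration): per-node age slides
    uniform within the (parent, oldest-child) bracket, a root-age multiplier,
    per-branch rate multipliers, and hyperparameter multipliers.  With
    ``n_chains > 1``, Metropolis coupling runs heated chains at inverse
    temperatures ``1/(1 + heat_increment * k)`` with one adjacent-pair swap
    proposal per iteration; only cold-chain samples are returned.  With one
    chain the sampler reduces exactly to Metropolis--Hastings.

    ``use_likelihood=False`` samples the prior (calibrations, node-age
    kernel, rate priors) only, which is how the realized calibration tail
    probabilities can be audited.
    """
    clock = clock or ClockModel.mcmcdate_profile()
    model = _DatingModel(tree, blp, calibrations, list(relative_constraints),
                         clock, use_likelihood, fix_root_age,
                         node_log_priors, root_prior)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xDA7E)))
    heats = np.array([1.0 / (1.0 + heat_increment * k)
                      for k in range(n_chains)])

    states = []
    for _ in range(n_chains):
        ages, rates, mu0, s0 = _initial_state(model, rng)
        lp, ll = model.log_posterior(ages, rates, mu0, s0)
        states.append({"ages": ages, "rates": rates, "mu": mu0, "sigma": s0,
                       "lp": lp, "ll": ll})

    tree_par = tree.parent
    children_of = {v: tree.children(v) for v in model.internal}
    n_prop = {"age": 0, "root": 0, "rate": 0, "hyper": 0}
    n_acc = {k: 0 for k in n_prop}

    moves = []
    for v in model.nonroot_internal:
        moves.append(("age", v))
    if fix_root_age is None:
        moves.append(("root", model.root))
    if use_likelihood and blp is not None:
        for v in model.branch_nodes:
            moves.append(("rate", v))
    moves.append(("hyper", "mu"))
    moves.append(("hyper", "sigma"))

    burn = int(burn_in_fraction * n_iter)
    records = []

    compensate = use_likelihood and blp is not None

    def _affected(v):
        out = [c for c in children_of.get(v, ())]
        if tree_par[v] != -1:
            out.append(v)
        return out

    def _compensate(ages_old, ages, rates, branches):
        """Rescale rates on ``branches`` so lengths are preserved; returns
        the log Jacobian of the joint (age, rates) transformation."""
        logj = 0.0
        for e in branches:
            dur_o = ages_old[tree_par[e]] - ages_old[e]   # tip ages are 0
            dur_n = ages[tree_par[e]] - ages[e]
            rates[e] *= dur_o / dur_n
            logj += math.log(dur_o / dur_n)
        return logj

    def propose(state, heat, kind, target):
        ages, rates = state["ages"], state["rates"]
        log_hastings = 0.0
        if kind == "age":
            v = target
            pa = ages[tree_par[v]]
            lo = max(ages[c] for c in children_of[v])
            old = ages[v]
            old_rates = None
            # reflected window slide within the (children, parent) bracket;
            # symmetric, so no Hastings correction for the age itself
            width = step_age * (pa - lo)
            new = old + width * (rng.random() - 0.5) * 2
            while new < lo or new > pa:
                if new < lo:
                    new = 2 * lo - new
                if new > pa:
                    new = 2 * pa - new
            if compensate:
                aff = _affected(v)
                old_rates = rates[aff].copy()
                ages_old = ages.copy()
                ages[v] = new
                log_hastings += _compensate(ages_old, ages, rates, aff)
            else:
                ages[v] = new
        elif kind == "root":
            v = target
            old = ages[v]
            old_rates = None
            fac = math.exp(step_scale * (rng.random() - 0.5) * 2)
            if old * fac <= max(ages[c] for c in children_of[v]):
                return False
            if compensate:
                aff = _affected(v)
                old_rates = rates[aff].copy()
                ages_old = ages.copy()
                ages[v] = old * fac
                log_hastings = math.log(fac) + \
                    _compensate(ages_old, ages, rates, aff)
            else:
                ages[v] = old * fac
                log_hastings = math.log(fac)
        elif kind == "rate":
            v = target
            old = rates[v]
            fac = math.exp(step_scale * (rng.random() - 0.5) * 2)
            rates[v] = old * fac
            log_hastings = math.log(fac)
        else:
            old = state[target]
            fac = math.exp(step_scale * (rng.random() - 0.5) * 2)
            state[target] = old * fac
            log_hastings = math.log(fac)
        lp, ll = model.log_posterior(ages, rates, state["mu"], state["sigma"])
        accept = (np.isfinite(lp) and
                  math.log(rng.random() + 1e-300) <
                  heat * (lp - state["lp"]) + log_hastings)
        if accept:
            state["lp"], state["ll"] = lp, ll
        else:
            if kind == "age" or kind == "root":
                ages[target] = old
                if compensate and old_rates is not None:
                    rates[_affected(target)] = old_rates
            elif kind == "rate":
                rates[target] = old
            else:
                state[target] = old
        return accept

    for it in range(n_iter):
        order = rng.permutation(len(moves))
        for ci, state in enumerate(states):
            for mi in order:
                kind, target = moves[mi]
                n_prop[kind] += 1 if ci == 0 else 0
                acc = propose(state, heats[ci], kind, target)
                if ci == 0 and acc:
                    n_acc[kind] += 1
        if n_chains > 1:
            j = int(rng.integers(n_chains - 1))
            si, sj = states[j], states[j + 1]
            dlog = (heats[j] - heats[j + 1]) * (sj["lp"] - si["lp"])
            if math.log(rng.random() + 1e-300) < dlog:
                states[j], states[j + 1] = sj, si
        if it >= burn:
            cold = states[0]
            rec = {"iteration": it,
                   "mu": cold["mu"], "sigma": cold["sigma"],
                   "loglik": cold["ll"], "logpost": cold["lp"]}
            for v in model.internal:
                rec[f"age_{tree.labels[v]}"] = cold["ages"][v]
            if use_likelihood and blp is not None:
                for v in model.branch_nodes:
                    rec[f"rate_{tree.labels[v]}"] = cold["rates"][v]
            records.append(rec)

    df = pd.DataFrame(records)
    acc_rates = {k: (n_acc[k] / n_prop[k] if n_prop[k] else np.nan)
                 for k in n_prop}
    return PosteriorTrace(df=df, tree=tree, seed=seed, n_chains=n_chains,
                          burn_in=burn, acceptance=acc_rates)


# --------------------------------------------------------------------------
# posterior-as-prior and diagnostics
# --------------------------------------------------------------------------

@dataclass
class FittedAgePrior:
    """Gamma density fitted by moments to a marginal age posterior."""

    shape: float
    scale: float

    @property
    def mean(self) -> float:
        return self.shape * self.scale

    def logpdf(self, age: float) -> float:
        return float(stats.gamma.logpdf(age, self.shape, scale=self.scale))

    def __call__(self, age: float) -> float:
        return self.logpdf(age)


def posterior_to_prior(trace: PosteriorTrace, nodes: list[str]
                       ) -> dict[str, FittedAgePrior]:
    """Fit per-node gamma age priors to posterior marginals by moments.

    The fitted priors plug into a second-stage run through
    ``node_log_priors`` -- the posterior-as-prior combination of a relative
    node dating stage with a subsequent partitioned analysis.
    """
    out = {}
    ages = trace.ages()
    for node in nodes:
        if node not in ages.columns:
            raise KeyError(f"node {node!r} not in trace")
        x = ages[node].values
        if len(x) < 100:
            raise ValueError("too few samples (<100) to fit a prior")
        m, v = float(np.mean(x)), float(np.var(x, ddof=1))
        if v <= 0 or not np.isfinite(v):
            raise ValueError(f"degenerate posterior for node {node!r}")
        out[node] = FittedAgePrior(shape=m * m / v, scale=v / m)
    return out


def diagnostics(traces, ess_floor: float = 200.0) -> pd.DataFrame:
    """Effective sample sizes and (for >=2 runs) rank-normalized R-hat.

    ``traces`` is one PosteriorTrace or a list of independent runs with
    identical columns.  Returns a per-parameter table with ``ess``,
    ``rhat`` (NaN for a single run) and ``ess_ok`` against ``ess_floor``.
    """
    import arviz as az

    if isinstance(traces, PosteriorTrace):
        traces = [traces]
    dfs = [t.df for t in traces]
    if min(len(d) for d in dfs) < 10:
        raise ValueError("trace too short for diagnostics (<10 samples)")
    cols = [c for c in dfs[0].columns
            if c.startswith(("age_", "rate_")) or c in ("mu", "sigma")]
    n = min(len(d) for d in dfs)
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for c in cols:
            arr = np.stack([d[c].values[:n] for d in dfs])
            if np.allclose(arr, arr.flat[0]):
                ess, rhat = 1.0, np.nan
            else:
                ess = float(az.ess(arr))
                rhat = float(az.rhat(arr)) if len(dfs) > 1 else np.nan
            rows.append({"parameter": c, "ess": ess, "rhat": rhat,
                         "ess_ok": ess >= ess_floor})
    return pd.DataFrame(rows).set_index("parameter")
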