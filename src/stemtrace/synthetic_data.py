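"""Ground-truthed synthetic inputs for every downstream analysis stage.

This module generates

* dated species trees (forward birth--death simulation conditioned on a fixed
  number of extant tips),
* gene families evolving down a dated tree under a duplication--transfer--loss
  (DTL) process with time-consistent transfers, together with the full event
  ledger and the true gene tree, and
* pseudo-posterior samples of branch lengths under an iid lognormal
  relaxed clock, the input consumed by the dating stage.

Every simulator takes an explicit seed and is bit-reproducible.  Per-family
random streams are derived from ``(seed, family_index)`` so datasets can be
generated family-by-family in any order.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .trees import DatedSpeciesTree

__all__ = [
    "Event",
    "SimulatedFamily",
    "SimulationConfig",
    "ClockParams",
    "simulate_dated_tree",
    "simulate_family",
    "simulate_dataset",
    "simulate_length_posterior",
    "replay_ledger",
    "truth_table",
]


# --------------------------------------------------------------------------
# species tree simulation
# --------------------------------------------------------------------------

def simulate_dated_tree(
    n_tips: int,
    birth_rate: float,
    death_rate: float = 0.0,
    seed: int = 0,
    *,
    max_tries: int = 1000,
) -> DatedSpeciesTree:
    """Simulate an ultrametric dated species tree with ``n_tips`` extant tips.

    Forward birth--death simulation from a single lineage.  The process runs
    until the standing lineage count first reaches ``n_tips``; the present is
    then placed at an additional exponential waiting time (the time to the
    next would-be event), so the youngest divergence has strictly positive
    age.  Replicates that go extinct before reaching ``n_tips`` are discarded
    and re-drawn, which conditions the simulation on survival.

    Ages are in Myr with tips at 0.  Tips are labelled ``s1..sN``.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be positive")
    if not 0 <= death_rate < birth_rate:
        raise ValueError("need 0 <= death_rate < birth_rate")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xD7EE)))

    for _ in range(max_tries):
        # each live lineage: (node_id); store split times going forward
        parent: list[int] = [-1]
        children: list[list[int]] = [[]]
        birth_time: list[float] = [0.0]
        death_time: list[float] = [np.inf]
        live = [0]
        t = 0.0
        ok = False
        while live:
            total = len(live) * (birth_rate + death_rate)
            t += rng.exponential(1.0 / total)
            if len(live) == n_tips:
                # stop: present = time of the next (unrealized) event
                ok = True
                break
            i = live[rng.integers(len(live))]
            if rng.random() < birth_rate / (birth_rate + death_rate):
                for _k in range(2):
                    parent.append(i)
                    children.append([])
                    birth_time.append(t)
                    death_time.append(np.inf)
                children[i].extend([len(parent) - 2, len(parent) - 1])
                live.remove(i)
                live.extend([len(parent) - 2, len(parent) - 1])
                death_time[i] = t
            else:
                live.remove(i)
                death_time[i] = t
            if len(live) > n_tips:  # pragma: no cover - cannot happen
                break
        if not ok:
            continue
        return _assemble_tree(parent, children, birth_time, live, present=t)
    raise RuntimeError(
        f"no surviving replicate with {n_tips} tips in {max_tries} tries"
    )


def _assemble_tree(parent, children, birth_time, live, present) -> DatedSpeciesTree:
    """Prune extinct lineages and convert to a DatedSpeciesTree."""
    alive = set(live)

    # survives[i]: subtree of i contains an extant lineage
    n = len(parent)
    survives = [False] * n
    for i in sorted(range(n), key=lambda j: -birth_time[j]):
        if i in alive:
            survives[i] = True
        for c in children[i]:
            survives[i] = survives[i] or survives[c]

    # build pruned binary tree, suppressing unifurcations
    def prune(i):
        """Return (structure, divergence_time) of the surviving subtree."""
        while True:
            if i in alive:
                return ("tip", i), present
            kids = [c for c in children[i] if survives[c]]
            if len(kids) == 2:
                lt, la = prune(kids[0])
                rt, ra = prune(kids[1])
                return ("int", lt, rt, la, ra), birth_time[children[i][0]]
            i = kids[0]

    root_struct, root_div = prune(0)

    parent_a: list[int] = []
    left_a: list[int] = []
    right_a: list[int] = []
    ages: list[float] = []
    labels: list[str] = []
    tip_counter = [0]
    int_counter = [0]

    def emit(struct, div_time, par) -> int:
        idx = len(parent_a)
        parent_a.append(par)
        left_a.append(-1)
        right_a.append(-1)
        if struct[0] == "tip":
            tip_counter[0] += 1
            labels.append(f"s{tip_counter[0]}")
            ages.append(0.0)
        else:
            int_counter[0] += 1
            labels.append(f"n{int_counter[0]}")
            ages.append(present - div_time)
            _, lt, rt, la, ra = struct
            left_a[idx] = emit(lt, la, idx)
            right_a[idx] = emit(rt, ra, idx)
        return idx

    emit(root_struct, root_div, -1)
    tree = DatedSpeciesTree(
        parent=np.asarray(parent_a),
        left=np.asarray(left_a),
        right=np.asarray(right_a),
        ages=np.asarray(ages),
        labels=labels,
    )
    tree.validate()
    return tree


# --------------------------------------------------------------------------
# gene family simulation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Event:
    """One DTL event: kind in {duplication, transfer, loss, origination}.

    ``donor`` / ``recipient`` are species-tree branch labels (the label of the
    branch's child node); ``recipient`` is set for transfers only.  ``time``
    is the event age in Ma.
    """

    kind: str
    donor: str
    time: float
    recipient: str | None = None


@dataclass
class SimulatedFamily:
    """A simulated gene family with its complete ground truth."""

    family_id: str
    origin_branch: str       # branch label, or the root label for root origin
    origin_time: float
    events: list[Event]
    tip_copy_numbers: dict[str, int]
    true_gene_tree: str | None   # Newick; None if the family went extinct
    leaf_to_species: dict[str, str] = field(default_factory=dict)

    @property
    def surviving(self) -> bool:
        return self.true_gene_tree is not None


class _GeneNode:
    __slots__ = ("age", "children", "label")

    def __init__(self, age, label=None):
        self.age = age
        self.children: list[_GeneNode] = []
        self.label = label


def simulate_family(
    tree: DatedSpeciesTree,
    rates,
    origination_policy: str = "uniform_branch",
    seed: int = 0,
    family_id: str = "fam0",
    rng: np.random.Generator | None = None,
) -> SimulatedFamily:
    """Forward-simulate one gene family down a dated species tree.

    ``rates`` is ``(duplication, transfer, loss)`` per gene lineage per Myr.
    Transfers pick a recipient uniformly among the species-tree branches alive
    at the event time, excluding the donor, so every transfer is
    time-consistent by construction.

    ``origination_policy``:

    * ``"uniform_branch"`` -- the family originates on a branch drawn with
      probability proportional to branch duration, at a uniform time on it;
    * ``"root"`` -- a single ancestral copy sits at the root node and
      speciates immediately into both root children.
    """
    delta, tau, lam = (float(r) for r in rates)
    if min(delta, tau, lam) < 0:
        raise ValueError("rates must be non-negative")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence((seed, 0xFA1)))
    tree.validate()

    branch_nodes = tree.branch_nodes
    top_ages = tree.ages[tree.parent[branch_nodes]]
    bot_ages = tree.ages[branch_nodes]
    durations = top_ages - bot_ages

    events: list[Event] = []
    tip_counts: dict[str, int] = {lab: 0 for lab in tree.tip_labels}
    total_rate = delta + tau + lam

    def live_branches(t: float) -> np.ndarray:
        return branch_nodes[(bot_ages < t) & (t < top_ages)]

    def evolve(branch: int, t: float) -> _GeneNode | None:
        """Lineage on ``branch`` at age ``t``; returns surviving gene subtree."""
        while True:
            wait = rng.exponential(1.0 / total_rate) if total_rate > 0 else np.inf
            t_event = t - wait
            bottom = tree.ages[branch]
            if t_event <= bottom:
                if tree.left[branch] == -1:  # tip reached
                    sp = tree.labels[branch]
                    tip_counts[sp] += 1
                    return _GeneNode(0.0, label=sp)
                node = _GeneNode(bottom)
                for c in tree.children(branch):
                    sub = evolve(c, bottom)
                    if sub is not None:
                        node.children.append(sub)
                return _collapse(node)
            u = rng.random() * total_rate
            if u < delta:
                events.append(Event("duplication", tree.labels[branch], t_event))
                node = _GeneNode(t_event)
                for _ in range(2):
                    sub = evolve(branch, t_event)
                    if sub is not None:
                        node.children.append(sub)
                return _collapse(node)
            elif u < delta + tau:
                others = live_branches(t_event)
                others = others[others != branch]
                if len(others) == 0:
                    t = t_event  # no contemporaneous recipient; no event
                    continue
                rec = int(others[rng.integers(len(others))])
                events.append(
                    Event("transfer", tree.labels[branch], t_event,
                          recipient=tree.labels[rec])
                )
                node = _GeneNode(t_event)
                stay = evolve(branch, t_event)
                moved = evolve(rec, t_event)
                for sub in (stay, moved):
                    if sub is not None:
                        node.children.append(sub)
                return _collapse(node)
            else:
                events.append(Event("loss", tree.labels[branch], t_event))
                return None

    if origination_policy == "root":
        origin_branch = tree.labels[tree.root]
        origin_time = tree.root_age
        root_node = _GeneNode(origin_time)
        for c in tree.children(tree.root):
            sub = evolve(c, origin_time)
            if sub is not None:
                root_node.children.append(sub)
        gene_root = _collapse(root_node)
    elif origination_policy == "uniform_branch":
        probs = durations / durations.sum()
        b = int(branch_nodes[rng.choice(len(branch_nodes), p=probs)])
        origin_branch = tree.labels[b]
        origin_time = float(
            tree.ages[b] + rng.random() * (tree.ages[tree.parent[b]] - tree.ages[b])
        )
        gene_root = evolve(b, origin_time)
    else:
        raise ValueError(f"unknown origination_policy {origination_policy!r}")
    events.append(Event("origination", origin_branch, origin_time))

    # assign per-species gene indices and render the gene tree
    leaf_to_species: dict[str, str] = {}
    newick = None
    if gene_root is not None and _has_leaf(gene_root):
        counters: dict[str, int] = {}
        _name_leaves(gene_root, counters, leaf_to_species)
        newick = _to_newick(gene_root) + ";"

    return SimulatedFamily(
        family_id=family_id,
        origin_branch=origin_branch,
        origin_time=origin_time,
        events=events,
        tip_copy_numbers=tip_counts,
        true_gene_tree=newick,
        leaf_to_species=leaf_to_species,
    )


def _collapse(node: _GeneNode) -> _GeneNode | None:
    """Drop extinct children / suppress unifurcations."""
    if node.label is not None:
        return node
    if not node.children:
        return None
    if len(node.children) == 1:
        return node.children[0]
    return node


def _has_leaf(node: _GeneNode) -> bool:
    if node.label is not None:
        return True
    return any(_has_leaf(c) for c in node.children)


def _name_leaves(node, counters, leaf_to_species):
    if node.label is not None:
        sp = node.label
        counters[sp] = counters.get(sp, 0) + 1
        node.label = f"{sp}_{counters[sp]}"
        leaf_to_species[node.label] = sp
        return
    for c in node.children:
        _name_leaves(c, counters, leaf_to_species)


def _to_newick(node: _GeneNode, parent_age: float | None = None) -> str:
    if node.label is not None:
        s = node.label
    else:
        s = "(" + ",".join(_to_newick(c, node.age) for c in node.children) + ")"
    if parent_age is not None:
        s += f":{parent_age - node.age:.6g}"
    return s


def replay_ledger(tree: DatedSpeciesTree, family: SimulatedFamily) -> dict[str, int]:
    """Recompute tip copy numbers by replaying the event ledger.

    Copy counts per branch are propagated through speciations and updated at
    each ledger event; the result must equal ``family.tip_copy_numbers``.
    """
    label_to_idx = {lab: i for i, lab in enumerate(tree.labels)}
    counts = np.zeros(tree.n_nodes, dtype=int)

    # timeline of (age, action); process in decreasing age
    items: list[tuple[float, int, tuple]] = []
    for ev in family.events:
        if ev.kind == "origination":
            items.append((ev.time, 0, ("orig", label_to_idx[ev.donor])))
        elif ev.kind == "duplication":
            items.append((ev.time, 2, ("dup", label_to_idx[ev.donor])))
        elif ev.kind == "transfer":
            items.append((ev.time, 2, ("tra", label_to_idx[ev.recipient])))
        elif ev.kind == "loss":
            items.append((ev.time, 2, ("loss", label_to_idx[ev.donor])))
    for v in tree.internal_nodes:
        items.append((float(tree.ages[v]), 1, ("spec", int(v))))
    # at equal ages: origination first, then speciation, then events
    items.sort(key=lambda x: (-x[0], x[1]))

    for _age, _prio, (kind, i) in items:
        if kind == "orig":
            counts[i] += 1
        elif kind == "spec":
            if counts[i]:
                counts[tree.left[i]] += counts[i]
                counts[tree.right[i]] += counts[i]
                counts[i] = 0
        elif kind in ("dup", "tra"):
            counts[i] += 1
        elif kind == "loss":
            counts[i] -= 1
    return {tree.labels[i]: int(counts[i]) for i in tree.tips}


# --------------------------------------------------------------------------
# dataset-level simulation
# --------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Configuration of a synthetic reconciliation dataset."""

    n_tips: int = 10
    birth_rate: float = 0.02          # per Myr
    death_rate: float = 0.0
    n_families: int = 100
    # either fixed rates ...
    dtl_rates: tuple[float, float, float] | None = (0.002, 0.001, 0.004)
    # ... or per-family gamma-distributed rates: kind -> (shape, mean)
    rate_gamma: dict[str, tuple[float, float]] | None = None
    origination_policy: str = "uniform_branch"
    seed: int = 0

    def validate(self) -> None:
        if self.n_tips < 2:
            raise ValueError("n_tips must be >= 2")
        if self.n_families < 0:
            raise ValueError("n_families must be >= 0")
        if self.dtl_rates is not None and min(self.dtl_rates) < 0:
            raise ValueError("rates must be non-negative")


@dataclass
class FamilySet:
    tree: DatedSpeciesTree
    families: list[SimulatedFamily]
    config: SimulationConfig
    family_rates: list[tuple[float, float, float]] = field(default_factory=list)

    @property
    def surviving(self) -> list[SimulatedFamily]:
        return [f for f in self.families if f.surviving]


def _family_rng(seed: int, index: int) -> np.random.Generator:
    """Stable per-family stream derived from (seed, family index)."""
    return np.random.default_rng(np.random.SeedSequence((seed, 0xFA2, index)))


def simulate_dataset(
    tree: DatedSpeciesTree, config: SimulationConfig
) -> FamilySet:
    """Simulate ``config.n_families`` families on ``tree``."""
    config.validate()
    rng0 = np.random.default_rng(np.random.SeedSequence((config.seed, 0xFA3)))
    families = []
    rates_used = []
    for i in range(config.n_families):
        if config.rate_gamma is not None:
            r = []
            for kind in ("duplication", "transfer", "loss"):
                shape, mean = config.rate_gamma.get(kind, (1.0, 0.0))
                r.append(rng0.gamma(shape, mean / shape) if mean > 0 else 0.0)
            rates = tuple(r)
        else:
            rates = tuple(config.dtl_rates)
        fam = simulate_family(
            tree,
            rates,
            origination_policy=config.origination_policy,
            family_id=f"fam{i}",
            rng=_family_rng(config.seed, i),
        )
        families.append(fam)
        rates_used.append(rates)
    return FamilySet(tree=tree, families=families, config=config,
                     family_rates=rates_used)


def truth_table(fs: FamilySet) -> pd.DataFrame:
    """Per-family, per-branch true event counts.

    Columns: family_id, branch_id, n_dup, n_trans, n_loss, n_orig.  Transfers
    are counted on the recipient branch (gains into the branch); every branch
    of the species tree appears for every family.
    """
    rows = []
    branch_labels = [fs.tree.labels[i] for i in fs.tree.branch_nodes]
    branch_labels.append(fs.tree.labels[fs.tree.root])
    for fam in fs.families:
        counts = {b: [0, 0, 0, 0] for b in branch_labels}
        for ev in fam.events:
            if ev.kind == "duplication":
                counts[ev.donor][0] += 1
            elif ev.kind == "transfer":
                counts[ev.recipient][1] += 1
            elif ev.kind == "loss":
                counts[ev.donor][2] += 1
            elif ev.kind == "origination":
                counts[ev.donor][3] += 1
        for b in branch_labels:
            rows.append([fam.family_id, b, *counts[b]])
    return pd.DataFrame(
        rows, columns=["family_id", "branch_id", "n_dup", "n_trans",
                       "n_loss", "n_orig"],
    )


def write_dataset(fs: FamilySet, outdir) -> None:
    """Write the dataset in the formats the reconciliation stage reads."""
    import os

    os.makedirs(outdir, exist_ok=True)
    fs.tree.write(os.path.join(outdir, "species_tree.nwk"))
    fs.tree.node_age_table().to_csv(
        os.path.join(outdir, "node_ages.tsv"), sep="\t", index=False
    )
    manifest = []
    map_rows = []
    with open(os.path.join(outdir, "gene_trees.nwk"), "w") as fh:
        for fam in fs.surviving:
            fh.write(fam.true_gene_tree + "\n")
            manifest.append(fam.family_id)
            for leaf, sp in fam.leaf_to_species.items():
                map_rows.append([leaf, sp])
    pd.DataFrame({"family_id": manifest}).to_csv(
        os.path.join(outdir, "family_manifest.tsv"), sep="\t", index=False
    )
    pd.DataFrame(map_rows, columns=["gene_id", "species"]).to_csv(
        os.path.join(outdir, "species_map.tsv"), sep="\t", index=False
    )
    counts = pd.DataFrame(
        {f.family_id: f.tip_copy_numbers for f in fs.families}
    ).T
    counts.index.name = "family_id"
    counts.to_csv(os.path.join(outdir, "tip_copy_numbers.tsv"), sep="\t")
    truth_table(fs).to_csv(
        os.path.join(outdir, "truth_events.tsv"), sep="\t", index=False
    )
    with open(os.path.join(outdir, "config.yaml"), "w") as fh:
        yaml.safe_dump(dataclasses.asdict(fs.config), fh)


# --------------------------------------------------------------------------
# pseudo-posterior branch lengths (relaxed clock)
# --------------------------------------------------------------------------

@dataclass
class ClockParams:
    """iid lognormal relaxed clock used to fabricate branch-length posteriors.

    ``mean_rate`` is the expected substitution rate (subst/site/Myr);
    ``sd_log`` the standard deviation of log rate across branches; and
    ``noise_sd`` the lognormal sampling noise applied per posterior draw.
    """

    mean_rate: float = 1e-3
    sd_log: float = 0.3
    noise_sd: float = 0.05


@dataclass
class LengthPosterior:
    samples: pd.DataFrame              # n_samples x branches
    true_rates: pd.Series
    true_lengths: pd.Series
    tree: DatedSpeciesTree


def simulate_length_posterior(
    tree: DatedSpeciesTree,
    clock: ClockParams,
    n_samples: int,
    seed: int = 0,
) -> LengthPosterior:
    """Draw a pseudo-posterior sample matrix of branch lengths.

    Branch rates are iid lognormal with mean ``clock.mean_rate``; the true
    branch length is rate x duration, and each posterior draw multiplies it
    by mean-one lognormal noise of magnitude ``clock.noise_sd``.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xB1)))
    branch_nodes = tree.branch_nodes
    labels = [tree.labels[i] for i in branch_nodes]
    durations = tree.ages[tree.parent[branch_nodes]] - tree.ages[branch_nodes]
    mu_log = np.log(clock.mean_rate) - clock.sd_log**2 / 2
    rates = np.exp(rng.normal(mu_log, clock.sd_log, size=len(labels))) \
        if clock.sd_log > 0 else np.full(len(labels), clock.mean_rate)
    lengths = rates * durations
    if clock.noise_sd > 0:
        noise = np.exp(
            rng.normal(-clock.noise_sd**2 / 2, clock.noise_sd,
                       size=(n_samples, len(labels)))
        )
    else:
        noise = np.ones((n_samples, len(labels)))
    samples = pd.DataFrame(lengths[None, :] * noise, columns=labels)
    return LengthPosterior(
        samples=samples,
        true_rates=pd.Series(rates, index=labels),
        true_lengths=pd.Series(lengths, index=labels),
        tree=tree,
    )
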