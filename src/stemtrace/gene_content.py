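"""Ancestral gene-content summaries derived from reconciliations.

Aggregates per-family reconciliation results into branchwise event totals
(duplications, incoming transfers, losses, originations), expected copy
numbers at ancestral nodes, per-Myr event rates, presence/absence calls over
tips and ancestral nodes, and shared-family counts between nodes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .reconciliation import ReconciliationResult
from .trees import DatedSpeciesTree, TreeError

__all__ = [
    "BranchEventTable",
    "PresenceAbsenceMatrix",
    "low_copy_filter",
    "branch_event_table",
    "events_per_time",
    "node_presence",
    "shared_families",
]


# --------------------------------------------------------------------------
# low-copy family selection
# --------------------------------------------------------------------------

def low_copy_filter(
    counts: pd.DataFrame,
    max_copies_per_species: float = 1,
    min_species_fraction: float = 1.0,
) -> list[str]:
    """Select low-copy-number families suitable for phylogenomics.

    ``counts`` is a families x species table of non-negative integers.  A
    family passes if every species in which it is present has at most
    ``max_copies_per_species`` copies, and it is present (>=1 copy) in at
    least ``min_species_fraction`` of all species.
    """
    if counts.empty:
        raise ValueError("empty copy-number table")
    if not 0 < min_species_fraction <= 1:
        raise ValueError("min_species_fraction must lie in (0, 1]")
    vals = counts.values
    if (vals < 0).any():
        raise ValueError("copy numbers must be non-negative")
    present = vals >= 1
    ok_copies = np.where(present, vals <= max_copies_per_species, True).all(axis=1)
    ok_presence = present.mean(axis=1) >= min_species_fraction - 1e-12
    return list(counts.index[ok_copies & ok_presence])


# --------------------------------------------------------------------------
# branchwise events
# --------------------------------------------------------------------------

@dataclass
class BranchEventTable:
    """Per-branch event totals summed over families.

    ``table`` is indexed by branch label (the branch's child node) with
    columns ``dup``, ``trans_in``, ``trans_out``, ``loss``, ``orig``,
    ``copies`` (expected copy number at the child node), ``parent_copies``,
    ``duration_Myr`` and ``reduced`` (True where the expected copy number
    decreases from the parent node).
    """

    table: pd.DataFrame
    n_families: int


def branch_event_table(
    reconciliations: list[ReconciliationResult],
    tree: DatedSpeciesTree,
) -> BranchEventTable:
    """Sum per-family expected event counts and copy numbers per branch."""
    labels = tree.labels
    ev_cols = ["dup", "trans_in", "trans_out", "loss", "orig"]
    acc = pd.DataFrame(0.0, index=labels, columns=ev_cols)
    copies = pd.Series(0.0, index=labels)
    for res in reconciliations:
        if set(res.expected_events.index) != set(labels):
            raise TreeError(
                f"reconciliation {res.family_id} is on a different tree")
        acc = acc.add(res.expected_events[ev_cols], fill_value=0.0)
        copies = copies.add(res.expected_copies, fill_value=0.0)

    rows = []
    for i in tree.branch_nodes:
        lab, plab = labels[i], labels[tree.parent[i]]
        rows.append({
            "branch": lab,
            **{c: acc.at[lab, c] for c in ev_cols},
            "copies": copies[lab],
            "parent_copies": copies[plab],
            "duration_Myr": tree.branch_duration(i),
            "reduced": bool(copies[lab] < copies[plab]),
        })
    table = pd.DataFrame(rows).set_index("branch")
    return BranchEventTable(table=table, n_families=len(reconciliations))


def events_per_time(bet: BranchEventTable) -> pd.DataFrame:
    """Event counts per branch divided by branch duration (events/Myr)."""
    dur = bet.table["duration_Myr"]
    zero = dur.index[dur <= 0]
    if len(zero):
        raise ValueError(f"zero-duration branches: {list(zero)}")
    cols = ["dup", "trans_in", "trans_out", "loss", "orig"]
    out = bet.table[cols].div(dur, axis=0)
    return out.rename(columns={c: f"{c}_per_Myr" for c in cols})


# --------------------------------------------------------------------------
# presence / absence
# --------------------------------------------------------------------------

@dataclass
class PresenceAbsenceMatrix:
    """Families x nodes binary matrix of gene-family presence."""

    table: pd.DataFrame          # families x node labels, values in {0, 1}
    threshold: float

    @property
    def nodes(self) -> list[str]:
        return list(self.table.columns)

    def presence_count(self, node: str) -> int:
        return int(self.table[node].sum())


def node_presence(
    reconciliations: list[ReconciliationResult],
    tree: DatedSpeciesTree,
    threshold: float = 0.5,
    observed_tip_counts: dict[str, dict[str, int]] | None = None,
) -> PresenceAbsenceMatrix:
    """Call gene-family presence at every tip and ancestral node.

    A family is present at a node when its expected copy number there is at
    least ``threshold``.  When ``observed_tip_counts`` is given (family ->
    species -> copies), tip columns are set from the observed data instead of
    the reconstruction.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    cols = tree.labels
    rows = {}
    tipset = set(tree.tip_labels)
    for res in reconciliations:
        pres = (res.expected_copies.reindex(cols) >= threshold).astype(int)
        if observed_tip_counts is not None:
            obs = observed_tip_counts.get(res.family_id, {})
            for sp in tipset:
                pres[sp] = 1 if obs.get(sp, 0) > 0 else 0
        rows[res.family_id] = pres
    table = pd.DataFrame(rows).T
    table = table[cols]
    return PresenceAbsenceMatrix(table=table, threshold=threshold)


def shared_families(matrix: PresenceAbsenceMatrix, node_a: str, node_b: str
                    ) -> dict[str, int]:
    """Families present at both nodes, and unique to each.

    Returns ``{"shared": ..., "unique_a": ..., "unique_b": ...}``; symmetric
    in its node arguments up to the labelling of the unique counts.
    """
    for n in (node_a, node_b):
        if n not in matrix.table.columns:
            raise KeyError(f"unknown node label {n!r}")
    a = matrix.table[node_a].astype(bool)
    b = matrix.table[node_b].astype(bool)
    return {
        "shared": int((a & b).sum()),
        "unique_a": int((a & ~b).sum()),
        "unique_b": int((~a & b).sum()),
    }


def write_gene_content(bet: BranchEventTable, pa: PresenceAbsenceMatrix,
                       shared: dict, outdir) -> None:
    """Write branch_events.tsv, presence_absence.tsv and shared_counts.json."""
    import os

    os.makedirs(outdir, exist_ok=True)
    bet.table.to_csv(os.path.join(outdir, "branch_events.tsv"), sep="\t")
    pa.table.to_csv(os.path.join(outdir, "presence_absence.tsv"), sep="\t")
    with open(os.path.join(outdir, "shared_counts.json"), "w") as fh:
        json.dump(shared, fh, indent=2)
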