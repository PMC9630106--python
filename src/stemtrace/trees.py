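"""Core dated-tree container shared by all analysis stages.

A :class:`DatedSpeciesTree` is a rooted binary tree over named tips in which
every node carries an age in Ma (million years before present).  Tips sit at
age 0 and every parent is strictly older than each of its children, so the
tree is ultrametric and branch durations are differences of node ages.

Newick parsing and writing are delegated to :mod:`dendropy`; internally nodes
live in flat numpy arrays indexed so that the branch subtending node ``i`` can
be referred to simply as branch ``i`` (the root has no branch).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "DatedSpeciesTree",
    "read_node_ages",
    "write_node_ages",
]


class TreeError(ValueError):
    """Raised for structurally invalid trees or inconsistent age tables."""


@dataclass
class DatedSpeciesTree:
    """Rooted ultrametric tree with node ages in Ma.

    Attributes
    ----------
    parent:
        ``parent[i]`` is the index of node ``i``'s parent, ``-1`` for the root.
    left, right:
        Child indices for internal nodes, ``-1`` for tips.
    ages:
        Node ages in Ma; ``ages[tip] == 0``.
    labels:
        Node labels.  Tips always carry their species name; internal labels
        are synthesized (``n<k>``) when the source tree does not provide one.
    """

    parent: np.ndarray
    left: np.ndarray
    right: np.ndarray
    ages: np.ndarray
    labels: list[str]
    _clades: list[frozenset] = field(default_factory=list, repr=False)

    # ---------------------------------------------------------------- basics
    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent == -1)[0])

    @property
    def tips(self) -> np.ndarray:
        return np.flatnonzero(self.left == -1)

    @property
    def internal_nodes(self) -> np.ndarray:
        return np.flatnonzero(self.left != -1)

    @property
    def n_tips(self) -> int:
        return int(np.sum(self.left == -1))

    @property
    def tip_labels(self) -> list[str]:
        return [self.labels[i] for i in self.tips]

    @property
    def root_age(self) -> float:
        return float(self.ages[self.root])

    @property
    def branch_nodes(self) -> np.ndarray:
        """Indices of nodes that subtend a branch (all but the root)."""
        return np.flatnonzero(self.parent != -1)

    def children(self, i: int) -> tuple[int, int]:
        return int(self.left[i]), int(self.right[i])

    def branch_duration(self, i: int) -> float:
        """Duration in Myr of the branch from ``parent[i]`` down to ``i``."""
        p = self.parent[i]
        if p == -1:
            raise TreeError("root has no subtending branch")
        return float(self.ages[p] - self.ages[i])

    @property
    def total_branch_duration(self) -> float:
        """Sum of all branch durations in Myr."""
        p = self.parent
        mask = p != -1
        return float(np.sum(self.ages[p[mask]] - self.ages[mask]))

    def postorder(self) -> list[int]:
        order: list[int] = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            if self.left[v] != -1:
                stack.append(int(self.left[v]))
                stack.append(int(self.right[v]))
        order.reverse()
        return order

    def clade(self, i: int) -> frozenset:
        """Set of tip labels descending from node ``i`` (cached)."""
        if not self._clades:
            clades: list = [None] * self.n_nodes
            for v in self.postorder():
                if self.left[v] == -1:
                    clades[v] = frozenset([self.labels[v]])
                else:
                    clades[v] = clades[self.left[v]] | clades[self.right[v]]
            self._clades = clades
        return self._clades[i]

    def find_clade(self, tip_set) -> int:
        """Return the node whose descendant tip set equals ``tip_set``."""
        want = frozenset(tip_set)
        for i in range(self.n_nodes):
            if self.clade(i) == want:
                return i
        raise TreeError(f"no node with clade {sorted(want)}")

    def mrca(self, tip_set) -> int:
        """Most recent common ancestor of the given tips."""
        want = frozenset(tip_set)
        missing = want - frozenset(self.tip_labels)
        if missing:
            raise TreeError(f"unknown tips: {sorted(missing)}")
        for v in self.postorder():
            if want <= self.clade(v):
                return v
        raise TreeError("unreachable")  # pragma: no cover

    def index_of(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise TreeError(f"no node labelled {label!r}") from None

    # ------------------------------------------------------------ validation
    def validate(self, tol: float = 1e-9) -> None:
        n = self.n_nodes
        if n < 3:
            raise TreeError("tree needs at least 2 tips")
        if np.sum(self.parent == -1) != 1:
            raise TreeError("tree must have exactly one root")
        if not np.all(np.isfinite(self.ages)) or np.any(self.ages < 0):
            raise TreeError("node ages must be finite and non-negative")
        for i in self.tips:
            if abs(self.ages[i]) > tol:
                raise TreeError(f"tip {self.labels[i]} has nonzero age")
        for i in self.branch_nodes:
            if self.ages[self.parent[i]] <= self.ages[i]:
                raise TreeError(
                    f"node {self.labels[i]} (age {self.ages[i]:g}) is not "
                    f"younger than its parent (age {self.ages[self.parent[i]]:g})"
                )
        if self.root_age <= 0:
            raise TreeError("root age must be positive")

    # ----------------------------------------------------------- conversion
    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "DatedSpeciesTree":
        nodes = list(tree.preorder_node_iter())
        for nd in nodes:
            if nd.child_nodes() and len(nd.child_nodes()) != 2:
                raise TreeError("tree must be strictly bifurcating")
        index = {id(nd): i for i, nd in enumerate(nodes)}
        n = len(nodes)
        parent = np.full(n, -1, dtype=int)
        left = np.full(n, -1, dtype=int)
        right = np.full(n, -1, dtype=int)
        depth = np.zeros(n)
        labels: list[str] = []
        k = 0
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                depth[i] = depth[parent[i]] + (nd.edge.length or 0.0)
            kids = nd.child_nodes()
            if kids:
                left[i], right[i] = index[id(kids[0])], index[id(kids[1])]
                if nd.label:
                    labels.append(str(nd.label))
                else:
                    labels.append(f"n{k}")
                    k += 1
            else:
                if nd.taxon is None or not nd.taxon.label:
                    raise TreeError("every tip must be named")
                labels.append(nd.taxon.label)
        height = depth[left == -1].max()
        ages = height - depth
        ages[left == -1] = 0.0  # snap tips exactly to the present
        if np.any(np.abs((height - depth)[left == -1]) > 1e-6 * max(height, 1.0)):
            raise TreeError("input tree is not ultrametric")
        out = cls(parent=parent, left=left, right=right, ages=ages, labels=labels)
        out.validate()
        return out

    @classmethod
    def from_newick(cls, newick: str) -> "DatedSpeciesTree":
        tree = dendropy.Tree.get(data=newick, schema="newick",
                                 preserve_underscores=True)
        return cls.from_dendropy(tree)

    @classmethod
    def read(cls, path) -> "DatedSpeciesTree":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    def to_dendropy(self) -> dendropy.Tree:
        taxa = dendropy.TaxonNamespace()
        tree = dendropy.Tree(taxon_namespace=taxa)
        dnodes = {}
        for v in self.postorder():
            nd = dendropy.Node()
            if self.left[v] == -1:
                nd.taxon = taxa.new_taxon(self.labels[v])
            else:
                nd.label = self.labels[v]
                for c in self.children(v):
                    nd.add_child(dnodes[c])
            if self.parent[v] != -1:
                nd.edge.length = self.branch_duration(v)
            dnodes[v] = nd
        tree.seed_node = dnodes[self.root]
        return tree

    def to_newick(self) -> str:
        return self.to_dendropy().as_string(
            schema="newick", suppress_rooting=True
        ).strip()

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    # ------------------------------------------------------------ age tables
    def node_age_table(self) -> pd.DataFrame:
        """Two-column table (node_label, age_Ma) over all nodes."""
        return pd.DataFrame(
            {"node_label": self.labels, "age_Ma": self.ages.astype(float)}
        )

    def copy(self) -> "DatedSpeciesTree":
        return DatedSpeciesTree(
            parent=self.parent.copy(),
            left=self.left.copy(),
            right=self.right.copy(),
            ages=self.ages.copy(),
            labels=list(self.labels),
        )


def write_node_ages(tree: DatedSpeciesTree, path) -> None:
    tree.node_age_table().to_csv(path, sep="\t", index=False)


def read_node_ages(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"node_label", "age_Ma"} <= set(df.columns):
        raise TreeError("node age table needs columns node_label, age_Ma")
    return df
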