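"""Independent brute-force oracles used by the test suite.

The main oracle enumerates reconciliations of a gene tree with a time-sliced
dated species tree explicitly -- every embedding of the gene tree's nodes
into (branch, slice) cells, decorated with up to ``max_events`` DTL events
including explicit losses in extinct sub-lineages -- and sums their
probabilities under the same per-step transition factors the dynamic program
uses.  It shares no code with the implementation: no amalgamation tables, no
extinction-probability propagation, no array recursion.
"""

from __future__ import annotations

import numpy as np

import dendropy


def _parse(newick: str):
    t = dendropy.Tree.get(data=newick, schema="newick",
                          preserve_underscores=True)

    def conv(nd):
        kids = nd.child_nodes()
        if not kids:
            return ("leaf", nd.taxon.label)
        assert len(kids) == 2
        return ("int", conv(kids[0]), conv(kids[1]))

    return conv(t.seed_node)


def _shift(vec: np.ndarray, k: int) -> np.ndarray:
    out = np.zeros_like(vec)
    if k < len(vec):
        out[k:] = vec[:len(vec) - k]
    return out


def _conv(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    n = len(a)
    return np.convolve(a, b)[:n]


def enumerate_loglik(
    gene_tree_newick: str,
    leaf_to_species: dict,
    sliced,
    rates,
    origination: str = "uniform_branch",
    max_events: int = 2,
):
    """Total probability of all reconciliations with <= max_events events.

    Returns the probability (not its log); compare against
    ``exp(family_loglik(..., condition_on_survival=False))``.
    """
    tree = sliced.tree
    times = sliced.times
    live = sliced.live
    d, t, l = rates.as_tuple()
    B = max_events + 1
    eps = 1e-9 * max(tree.root_age, 1.0)

    def at_node(e, j):
        return abs(tree.ages[e] - times[j]) < eps and tree.left[e] != -1

    ghost_memo: dict = {}
    embed_memo: dict = {}

    def ghost(e, j):
        """Event-count vector for an extinct lineage entering (e, level j)."""
        if (e, j) in ghost_memo:
            return ghost_memo[(e, j)]
        out = np.zeros(B)
        if j == 0:
            ghost_memo[(e, j)] = out
            return out
        if at_node(e, j):
            lc, rc = tree.children(e)
            out = _conv(ghost(lc, j), ghost(rc, j))
            ghost_memo[(e, j)] = out
            return out
        g = j - 1
        h = times[j] - times[g]
        n = len(live[g])
        tot = d + t + l
        out += _shift(np.eye(B)[0], 1) * h * l          # dies in this step
        out += (1 - h * tot) * ghost(e, g)
        if d > 0:
            out += h * d * _shift(_conv(ghost(e, g), ghost(e, g)), 1)
        if t > 0 and n > 1:
            for f in live[g]:
                if f == e:
                    continue
                out += h * t / (n - 1) * _shift(
                    _conv(ghost(e, g), ghost(f, g)), 1)
        ghost_memo[(e, j)] = out
        return out

    def embed(u, e, j):
        """Vector of probabilities by event count for gene node ``u``
        entering branch ``e`` at level ``j``."""
        key = (id(u), e, j)
        if key in embed_memo:
            return embed_memo[key]
        out = np.zeros(B)
        if at_node(e, j):
            lc, rc = tree.children(e)
            if u[0] == "int":
                for (x, y) in ((lc, rc), (rc, lc)):
                    out += _conv(embed(u[1], x, j), embed(u[2], y, j))
            out += _conv(embed(u, lc, j), ghost(rc, j))
            out += _conv(embed(u, rc, j), ghost(lc, j))
            embed_memo[key] = out
            return out
        if j == 0:
            if u[0] == "leaf" and leaf_to_species[u[1]] == tree.labels[e]:
                out[0] = 1.0
            embed_memo[key] = out
            return out
        g = j - 1
        h = times[j] - times[g]
        n = len(live[g])
        tot = d + t + l
        out += (1 - h * tot) * embed(u, e, g)
        if d > 0:
            if u[0] == "int":
                out += h * d * _shift(_conv(embed(u[1], e, g),
                                            embed(u[2], e, g)), 1)
            out += 2 * h * d * _shift(_conv(embed(u, e, g), ghost(e, g)), 1)
        if t > 0 and n > 1:
            for f in live[g]:
                if f == e:
                    continue
                w = h * t / (n - 1)
                if u[0] == "int":
                    for (a, b) in ((u[1], u[2]), (u[2], u[1])):
                        out += w * _shift(_conv(embed(a, e, g),
                                                embed(b, f, g)), 1)
                out += w * _shift(_conv(embed(u, e, g), ghost(f, g)), 1)
                out += w * _shift(_conv(embed(u, f, g), ghost(e, g)), 1)
        embed_memo[key] = out
        return out

    root_u = _parse(gene_tree_newick)
    G = len(times) - 1
    if origination == "root":
        rl, rc_ = tree.children(tree.root)
        vec = np.zeros(B)
        if root_u[0] == "int":
            for (x, y) in ((rl, rc_), (rc_, rl)):
                vec += _conv(embed(root_u[1], x, G), embed(root_u[2], y, G))
        vec += _conv(embed(root_u, rl, G), ghost(rc_, G))
        vec += _conv(embed(root_u, rc_, G), ghost(rl, G))
    else:
        T = tree.total_branch_duration
        vec = np.zeros(B)
        for g in range(G):
            h = times[g + 1] - times[g]
            for e in live[g]:
                vec += (h / T) * embed(root_u, int(e), g + 1)
    return float(vec.sum())
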