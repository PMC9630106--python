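"""Genome disparity: ordination of gene-content profiles.

Presence/absence profiles of tips and ancestral nodes are compared by
Euclidean distance and embedded in two dimensions with non-metric
multidimensional scaling (NMDS, Kruskal stress-1 with monotone regression of
fitted on observed distances).  Tree branches are drawn between the embedded
parent/child nodes, and convex hulls are fitted around user-defined clades,
so gene-content evolution can be read as trajectories through the ordination.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist, squareform
from sklearn.manifold import smacof

from .gene_content import PresenceAbsenceMatrix
from .trees import DatedSpeciesTree

__all__ = [
    "DistanceMatrix",
    "OrdinationResult",
    "pa_distance",
    "nmds",
    "ordination_layout",
]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances over labelled nodes."""

    table: pd.DataFrame

    def __post_init__(self):
        v = self.table.values
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(v < 0) or not np.all(np.isfinite(v)):
            raise ValueError("distances must be finite and non-negative")

    @property
    def labels(self) -> list[str]:
        return list(self.table.index)

    @property
    def values(self) -> np.ndarray:
        return self.table.values


def pa_distance(matrix: PresenceAbsenceMatrix) -> DistanceMatrix:
    """Euclidean distances between node presence/absence profiles.

    Profiles differing in exactly ``k`` families are at distance ``sqrt(k)``.
    """
    X = matrix.table.values.T.astype(float)   # nodes x families
    if X.shape[0] < 2:
        raise ValueError("need at least two nodes")
    if np.isnan(X).any():
        raise ValueError("presence/absence matrix contains NaN")
    D = squareform(pdist(X, metric="euclidean"))
    return DistanceMatrix(
        table=pd.DataFrame(D, index=matrix.nodes, columns=matrix.nodes))


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame          # node -> (x, y)
    stress: float                      # Kruskal stress-1 of the best start
    n_starts: int
    converged: bool
    start_stresses: list[float] = field(default_factory=list, repr=False)


def nmds(
    dist: DistanceMatrix,
    n_dim: int = 2,
    n_starts: int = 20,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int = 0,
) -> OrdinationResult:
    """Non-metric MDS minimizing Kruskal stress-1, best of ``n_starts``.

    Each start runs SMACOF with isotonic regression of the fitted on the
    observed dissimilarities.  The first start is initialized from the
    classical (metric) MDS solution; subsequent starts jitter it with
    Gaussian noise, which avoids the poor local optima of fully random
    initializations.  The configuration with the lowest final normalized
    stress is returned.  Non-convergence is reported through ``converged``,
    never raised.
    """
    if n_dim < 1:
        raise ValueError("n_dim must be >= 1")
    D = dist.values
    init0 = _classical_mds(D, n_dim)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xD15)))
    best = None
    stresses = []
    for s in range(n_starts):
        init = init0 if s == 0 else \
            init0 + rng.normal(0, 0.05 * max(D.max(), 1e-12), init0.shape)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            X, stress, n_iter = smacof(
                D, metric=False, n_components=n_dim, init=init, n_init=1,
                max_iter=max_iter, eps=tol, random_state=s,
                normalized_stress=True, return_n_iter=True,
            )
        stresses.append(float(stress))
        if best is None or stress < best[1]:
            best = (X, float(stress), n_iter)
    X, stress, n_iter = best
    coords = pd.DataFrame(X, index=dist.labels,
                          columns=[f"axis{i+1}" for i in range(n_dim)])
    return OrdinationResult(
        coordinates=coords,
        stress=stress,
        n_starts=n_starts,
        converged=bool(n_iter < max_iter),
        start_stresses=stresses,
    )


def _classical_mds(D: np.ndarray, k: int) -> np.ndarray:
    """Classical (Torgerson) MDS embedding used to initialize SMACOF."""
    n = len(D)
    J = np.eye(n) - 1.0 / n
    B = -0.5 * J @ (D ** 2) @ J
    w, V = np.linalg.eigh(B)
    idx = np.argsort(w)[::-1][:k]
    return V[:, idx] * np.sqrt(np.maximum(w[idx], 0.0))


def ordination_layout(
    ordination: OrdinationResult,
    tree: DatedSpeciesTree,
    clade_map: dict[str, list[str]] | None = None,
    plot_path: str | None = None,
) -> dict:
    """Figure-ready layout: branch segments and per-clade convex hulls.

    ``clade_map`` maps clade names to lists of node labels; hulls of clades
    with fewer than 3 distinct points degenerate to a segment or point (with
    a warning).  Returns a JSON-serializable dict and optionally renders a
    matplotlib figure to ``plot_path``.
    """
    coords = ordination.coordinates
    missing = [lab for lab in tree.labels if lab not in coords.index]
    if missing:
        raise KeyError(f"nodes missing from ordination: {missing}")
    segments = []
    for i in tree.branch_nodes:
        a, b = tree.labels[tree.parent[i]], tree.labels[i]
        segments.append({
            "parent": a, "child": b,
            "from": [float(v) for v in coords.loc[a]],
            "to": [float(v) for v in coords.loc[b]],
        })
    hulls = {}
    for name, members in (clade_map or {}).items():
        pts = coords.loc[members].values
        uniq = np.unique(pts, axis=0)
        if len(uniq) < 3:
            warnings.warn(f"clade {name!r} has <3 distinct points; hull "
                          "degenerates")
            hulls[name] = [[float(x) for x in p] for p in uniq]
        else:
            hull = ConvexHull(uniq)
            hulls[name] = [[float(x) for x in uniq[v]] for v in hull.vertices]
    layout = {
        "stress": ordination.stress,
        "coordinates": {lab: [float(v) for v in coords.loc[lab]]
                        for lab in coords.index},
        "segments": segments,
        "hulls": hulls,
    }
    if plot_path:
        _render(layout, plot_path)
    return layout


def write_layout(layout: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(layout, fh, indent=2)


def _render(layout: dict, path: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    for seg in layout["segments"]:
        xs = [seg["from"][0], seg["to"][0]]
        ys = [seg["from"][1], seg["to"][1]]
        ax.plot(xs, ys, color="0.6", lw=0.8, zorder=1)
    for name, verts in layout["hulls"].items():
        if len(verts) >= 3:
            poly = plt.Polygon(verts, closed=True, alpha=0.2, label=name)
            ax.add_patch(poly)
    for lab, (x, y) in layout["coordinates"].items():
        ax.scatter([x], [y], s=10, color="k", zorder=2)
    ax.set_xlabel("NMDS axis 1")
    ax.set_ylabel("NMDS axis 2")
    ax.set_title(f"gene-content disparity (stress={layout['stress']:.3f})")
    if layout["hulls"]:
        ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
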