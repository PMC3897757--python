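"""Perfect-LD clusters and their hierarchical (UPGMA) ordering.

A cluster is a maximal set of >= 2 markers in perfect LD: connected
components of the graph joining markers whose r-squared is at least
1 - epsilon.  With complete data, r-squared = 1 is transitive, so
components are cliques; under missing-data artifacts a component can fail
the clique property and is flagged with :class:`NonCliqueWarning`.

Clusters are then ordered by average-linkage (UPGMA) agglomeration of the
distance 1 - r-squared, where the distance between two blocks is one minus
the mean r-squared over their defined cross-pairs (with exact perfect LD
inside blocks, all cross-pairs agree, so the mean equals any representative
pair).  Ties in the merge queue are broken by the smallest (row, column)
node-id pair so output is platform-independent.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .errors import ContractError, NonCliqueWarning, UndefinedDistanceWarning, UndefinedLDError
from .ld import LDMatrix
from .model import Marker

__all__ = [
    "Cluster",
    "Dendrogram",
    "build_clusters",
    "cluster_distance",
    "cluster_distance_matrix",
    "agglomerate",
    "leaf_order",
    "to_newick",
    "to_scipy_linkage",
]


@dataclass(frozen=True)
class Cluster:
    """A set of >= 2 markers in perfect LD, named after its leftmost member."""

    members: tuple[Marker, ...]

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ContractError("a cluster needs at least 2 members")
        ordered = tuple(sorted(self.members, key=lambda mk: mk.pos))
        object.__setattr__(self, "members", ordered)

    @property
    def name(self) -> str:
        return self.members[0].id

    @property
    def member_ids(self) -> tuple[str, ...]:
        return tuple(mk.id for mk in self.members)

    @property
    def chrom(self) -> str:
        return self.members[0].chrom

    @property
    def min_pos(self) -> int:
        return self.members[0].pos

    @property
    def max_pos(self) -> int:
        return self.members[-1].pos

    @property
    def span(self) -> tuple[str, int, int]:
        return (self.chrom, self.min_pos, self.max_pos)

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class Dendrogram:
    """Average-linkage merge tree over ``n_leaves`` items.

    Leaves are 0..n_leaves-1; the t-th merge creates node ``n_leaves + t``
    from the two listed nodes at the given height.  Merge heights are
    non-decreasing (average linkage admits no inversions on a proper
    distance matrix).
    """

    n_leaves: int
    merges: tuple[tuple[int, int, float], ...]

    @property
    def heights(self) -> tuple[float, ...]:
        return tuple(h for _, _, h in self.merges)


def build_clusters(
    ldm: LDMatrix, epsilon: float = 1e-6
) -> tuple[list[Cluster], list[str]]:
    """Connected components of the perfect-LD graph at threshold 1 - epsilon.

    Returns clusters (components of size >= 2, sorted by leftmost position)
    and singleton marker ids (sorted by position).  Each component is
    verified to be a clique at the same threshold; violations — possible
    only through missing-data artifacts — emit :class:`NonCliqueWarning`.
    """
    if epsilon < 0:
        raise ContractError(f"epsilon must be >= 0, got {epsilon}")
    if ldm.k == 0:
        return [], []
    adj = ldm.defined & (ldm.r2 >= 1.0 - epsilon)
    np.fill_diagonal(adj, False)
    _, labels = connected_components(csr_matrix(adj), directed=False)

    groups: dict[int, list[int]] = {}
    for idx, lab in enumerate(labels):
        groups.setdefault(int(lab), []).append(idx)

    clusters: list[Cluster] = []
    singletons: list[Marker] = []
    for comp in groups.values():
        if len(comp) == 1:
            singletons.append(ldm.markers[comp[0]])
            continue
        bad = [
            (ldm.markers[a].id, ldm.markers[b].id)
            for ai, a in enumerate(comp)
            for b in comp[ai + 1 :]
            if not adj[a, b]
        ]
        if bad:
            warnings.warn(
                f"component {sorted(ldm.markers[c].id for c in comp)} is not a "
                f"clique at r2 >= {1.0 - epsilon}; non-edges: {bad} "
                "(missing-data artifact)",
                NonCliqueWarning,
                stacklevel=2,
            )
        clusters.append(Cluster(members=tuple(ldm.markers[c] for c in comp)))
    clusters.sort(key=lambda c: c.min_pos)
    singletons.sort(key=lambda mk: mk.pos)
    return clusters, [mk.id for mk in singletons]


def cluster_distance(ldm: LDMatrix, cluster_a: Cluster, cluster_b: Cluster) -> float:
    """1 - mean r-squared over all defined cross-pairs between two clusters."""
    ia = [ldm.index(mid) for mid in cluster_a.member_ids]
    ib = [ldm.index(mid) for mid in cluster_b.member_ids]
    sub = ldm.r2[np.ix_(ia, ib)]
    mask = ldm.defined[np.ix_(ia, ib)]
    if not mask.any():
        raise UndefinedLDError(
            f"no defined cross-pair between clusters {cluster_a.name!r} and "
            f"{cluster_b.name!r}"
        )
    return 1.0 - float(sub[mask].mean())


def cluster_distance_matrix(ldm: LDMatrix, clusters: Sequence[Cluster]) -> np.ndarray:
    """Symmetric block-distance matrix for agglomeration.

    An undefined cluster pair (no defined cross-pair, a missing-data
    artifact) is assigned the maximal distance 1.0 with a warning.
    """
    k = len(clusters)
    dist = np.zeros((k, k))
    for a in range(k):
        for b in range(a + 1, k):
            try:
                d = cluster_distance(ldm, clusters[a], clusters[b])
            except UndefinedLDError:
                warnings.warn(
                    f"distance between clusters {clusters[a].name!r} and "
                    f"{clusters[b].name!r} undefined; using maximal distance 1.0",
                    UndefinedDistanceWarning,
                    stacklevel=2,
                )
                d = 1.0
            dist[a, b] = dist[b, a] = d
    return dist


def agglomerate(distances: np.ndarray) -> Dendrogram:
    """UPGMA (average-linkage) agglomeration of a distance matrix.

    Repeatedly merges the pair of current nodes with minimal average
    inter-member distance; the merge height is that average.  Ties are
    broken by the smallest (row, column) node-id pair.  A single item
    yields an empty merge list.
    """
    d_mat = np.asarray(distances, dtype=float)
    if d_mat.ndim != 2 or d_mat.shape[0] != d_mat.shape[1]:
        raise ContractError(f"distance matrix must be square, got shape {d_mat.shape}")
    if not np.allclose(d_mat, d_mat.T, rtol=0.0, atol=1e-12):
        raise ContractError("distance matrix must be symmetric")
    if (d_mat < 0).any():
        raise ContractError("distances must be non-negative")
    k = d_mat.shape[0]
    if k == 0:
        raise ContractError("distance matrix must have at least one item")
    if k == 1:
        return Dendrogram(n_leaves=1, merges=())

    active: list[int] = list(range(k))  # kept sorted; new ids only grow
    size = {i: 1 for i in range(k)}
    dist: dict[tuple[int, int], float] = {
        (a, b): float(d_mat[a, b]) for a in range(k) for b in range(a + 1, k)
    }
    merges: list[tuple[int, int, float]] = []
    next_id = k
    while len(active) > 1:
        best: tuple[float, int, int] | None = None
        for ai in range(len(active)):
            for bj in range(ai + 1, len(active)):
                a, b = active[ai], active[bj]
                cand = (dist[(a, b)], a, b)
                if best is None or cand < best:
                    best = cand
        h, a, b = best  # type: ignore[misc]
        sa, sb = size[a], size[b]
        for m in active:
            if m in (a, b):
                continue
            dist[(m, next_id)] = (sa * dist[tuple(sorted((a, m)))] +
                                  sb * dist[tuple(sorted((b, m)))]) / (sa + sb)
        active = [m for m in active if m not in (a, b)] + [next_id]
        size[next_id] = sa + sb
        merges.append((a, b, h))
        next_id += 1
    return Dendrogram(n_leaves=k, merges=tuple(merges))


def leaf_order(dendro: Dendrogram) -> list[int]:
    """Left-to-right leaf sequence of the dendrogram.

    Depth-first traversal; at each internal node the child whose own
    minimum leaf index is smaller is visited first, giving a deterministic
    layout in which every subtree occupies a contiguous run.
    """
    if not dendro.merges:
        return list(range(dendro.n_leaves))
    children = {
        dendro.n_leaves + t: (a, b) for t, (a, b, _) in enumerate(dendro.merges)
    }
    min_leaf: dict[int, int] = {}

    def _min_leaf(node: int) -> int:
        if node not in min_leaf:
            if node < dendro.n_leaves:
                min_leaf[node] = node
            else:
                a, b = children[node]
                min_leaf[node] = min(_min_leaf(a), _min_leaf(b))
        return min_leaf[node]

    root = dendro.n_leaves + len(dendro.merges) - 1
    order: list[int] = []
    stack = [root]
    while stack:
        node = stack.pop()
        if node < dendro.n_leaves:
            order.append(node)
        else:
            a, b = children[node]
            first, second = (a, b) if _min_leaf(a) <= _min_leaf(b) else (b, a)
            stack.append(second)
            stack.append(first)
    return order


def to_newick(dendro: Dendrogram, labels: Sequence[str] | None = None) -> str:
    """Render the dendrogram as Newick text with ultrametric branch lengths.

    Node heights are half the merge height (so the tree distance between
    two leaves equals their average-linkage merge distance).
    """
    if labels is None:
        labels = [f"L{i}" for i in range(dendro.n_leaves)]
    if len(labels) != dendro.n_leaves:
        raise ContractError("one label per leaf required")
    if not dendro.merges:
        return f"{labels[0]};"
    children = {
        dendro.n_leaves + t: (a, b, h) for t, (a, b, h) in enumerate(dendro.merges)
    }

    def height(node: int) -> float:
        return 0.0 if node < dendro.n_leaves else children[node][2] / 2.0

    def render(node: int, parent_h: float) -> str:
        bl = parent_h - height(node)
        if node < dendro.n_leaves:
            return f"{labels[node]}:{bl:.10g}"
        a, b, h = children[node]
        first, second = (a, b)
        inner = f"({render(first, h / 2.0)},{render(second, h / 2.0)})"
        return f"{inner}:{bl:.10g}"

    root = dendro.n_leaves + len(dendro.merges) - 1
    a, b, h = children[root]
    return f"({render(a, h / 2.0)},{render(b, h / 2.0)});"


def to_scipy_linkage(dendro: Dendrogram) -> np.ndarray:
    """Convert to a scipy ``linkage``-style matrix (for plotting/cross-checks)."""
    sizes = {i: 1 for i in range(dendro.n_leaves)}
    rows = []
    for t, (a, b, h) in enumerate(dendro.merges):
        sizes[dendro.n_leaves + t] = sizes[a] + sizes[b]
        rows.append([float(a), float(b), float(h), float(sizes[dendro.n_leaves + t])])
    return np.array(rows, dtype=float).reshape(len(rows), 4)


def plot_dendrogram(dendro: Dendrogram, labels: Sequence[str] | None = None, ax=None):
    """Draw the dendrogram with matplotlib (optional dependency)."""
    from scipy.cluster.hierarchy import dendrogram as scipy_dendrogram

    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    scipy_dendrogram(to_scipy_linkage(dendro), labels=list(labels) if labels else None, ax=ax)
    ax.set_ylabel("1 - r$^2$ (average linkage)")
    return ax
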