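"""Correlation-distance agglomerative clustering of cells (UPGMA) and
cluster-enriched gene ranking.

Cells are compared by Pearson correlation of their log2 expression profiles
over the filter-retained probes; the distance is ``1 - r`` so perfectly
correlated cells coincide and anti-correlated cells are maximally distant.
Average linkage merges the pair of clusters with the smallest mean pairwise
member distance; ties are broken by the lexicographically smallest member
id so the merge sequence is platform-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .matrixio import ExpressionMatrix, ProbeAnnotation
from .qc import detect_calls


def correlation_distance(
    matrix: ExpressionMatrix, probes: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """Cell-by-cell Pearson correlation distance d = 1 - r over ``probes``.

    Symmetric, zero diagonal, values in [0, 2].  A cell with zero variance
    over the chosen probes has no defined correlation and is a hard error.
    """
    sub = matrix if probes is None else matrix.subset(probes=list(probes))
    if sub.shape[1] < 2:
        raise ValueError("need at least 2 cells")
    if sub.shape[0] < 2:
        raise ValueError("need at least 2 probes")
    log2 = sub.log2().to_numpy()
    sds = log2.std(axis=0)
    for j, s in enumerate(sds):
        if s == 0:
            raise ValueError(
                f"cell {sub.cell_ids[j]!r} has zero variance over the selected probes"
            )
    r = np.corrcoef(log2, rowvar=False)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = np.clip(0.5 * (d + d.T), 0.0, 2.0)
    return pd.DataFrame(d, index=sub.cell_ids, columns=sub.cell_ids)


@dataclass(frozen=True)
class Merge:
    node_a: str
    node_b: str
    height: float
    new_node: str


@dataclass
class Dendrogram:
    """An agglomerative merge tree over named leaves."""

    leaves: list[str]
    merges: list[Merge]

    def __post_init__(self) -> None:
        heights = [m.height for m in self.merges]
        if any(b < a - 1e-12 for a, b in zip(heights, heights[1:])):
            raise ValueError("merge heights must be nondecreasing (no inversions)")

    def members(self) -> dict[str, tuple[str, ...]]:
        """node id -> leaf members, for every node in the tree."""
        mem: dict[str, tuple[str, ...]] = {leaf: (leaf,) for leaf in self.leaves}
        for m in self.merges:
            mem[m.new_node] = mem[m.node_a] + mem[m.node_b]
        return mem

    def leaf_order(self) -> list[str]:
        """Left-to-right leaf order of the final tree (heatmap column order)."""
        if not self.merges:
            return list(self.leaves)
        children: dict[str, tuple[str, str]] = {
            m.new_node: (m.node_a, m.node_b) for m in self.merges
        }
        merged = {m.node_a for m in self.merges} | {m.node_b for m in self.merges}
        roots = [m.new_node for m in self.merges if m.new_node not in merged]
        order: list[str] = []

        def walk(node: str) -> None:
            if node in children:
                a, b = children[node]
                walk(a)
                walk(b)
            else:
                order.append(node)

        for root in roots:
            walk(root)
        for leaf in self.leaves:  # never-merged leaves (k-forest edge case)
            if leaf not in order:
                order.append(leaf)
        return order

    def to_scipy_linkage(self) -> tuple[np.ndarray, list[str]]:
        """Convert to a scipy linkage matrix; returns (Z, leaf order used)."""
        index = {leaf: i for i, leaf in enumerate(self.leaves)}
        sizes = {leaf: 1 for leaf in self.leaves}
        Z = np.zeros((len(self.merges), 4))
        for i, m in enumerate(self.merges):
            a, b = index[m.node_a], index[m.node_b]
            size = sizes[m.node_a] + sizes[m.node_b]
            Z[i] = [min(a, b), max(a, b), m.height, size]
            index[m.new_node] = len(self.leaves) + i
            sizes[m.new_node] = size
        return Z, list(self.leaves)

    def to_newick(self) -> str:
        """Newick export with ultrametric branch lengths (node depth = h/2)."""
        children = {m.new_node: (m.node_a, m.node_b) for m in self.merges}
        depth = {leaf: 0.0 for leaf in self.leaves}
        for m in self.merges:
            depth[m.new_node] = m.height / 2.0

        def render(node: str, parent_depth: float) -> str:
            bl = parent_depth - depth[node]
            if node in children:
                a, b = children[node]
                inner = ",".join(
                    (render(a, depth[node]), render(b, depth[node]))
                )
                return f"({inner}):{bl:.10g}"
            return f"{node}:{bl:.10g}"

        if not self.merges:
            return "(" + ",".join(f"{l}:0" for l in self.leaves) + ");"
        root = self.merges[-1].new_node
        a, b = children[root]
        inner = ",".join((render(a, depth[root]), render(b, depth[root])))
        return f"({inner});"


def average_linkage(distances: pd.DataFrame) -> Dendrogram:
    """UPGMA agglomeration of a symmetric distance grid.

    Repeatedly merges the pair of clusters with minimal average inter-cluster
    member distance (maintained by the Lance-Williams update); the merge
    height is that average.  Ties are resolved toward the pair whose smallest
    member id sorts first.
    """
    leaves = list(distances.index)
    if len(leaves) < 2:
        raise ValueError("need at least 2 cells to cluster")
    if list(distances.columns) != leaves:
        raise ValueError("distance grid must have identical row and column ids")

    d: dict[frozenset[str], float] = {}
    arr = distances.to_numpy()
    for i in range(len(leaves)):
        for j in range(i + 1, len(leaves)):
            d[frozenset((leaves[i], leaves[j]))] = float(arr[i, j])

    active: dict[str, int] = {leaf: 1 for leaf in leaves}  # node -> size
    min_member: dict[str, str] = {leaf: leaf for leaf in leaves}
    merges: list[Merge] = []
    next_id = 0
    while len(active) > 1:
        best: Optional[tuple[float, tuple[str, str], tuple[str, str]]] = None
        for pair, dist in d.items():
            a, b = sorted(pair, key=lambda n: min_member[n])
            key = (dist, (min_member[a], min_member[b]))
            if best is None or key < (best[0], best[2]):
                best = (dist, (a, b), key[1])
        assert best is not None
        height, (a, b), _ = best
        next_id += 1
        new = f"N{next_id}"
        na, nb = active[a], active[b]
        for other in list(active):
            if other in (a, b):
                continue
            da = d.pop(frozenset((a, other)))
            db = d.pop(frozenset((b, other)))
            d[frozenset((new, other))] = (na * da + nb * db) / (na + nb)
        d.pop(frozenset((a, b)))
        del active[a], active[b]
        active[new] = na + nb
        min_member[new] = min(min_member[a], min_member[b])
        merges.append(Merge(a, b, height, new))
    return Dendrogram(leaves=leaves, merges=merges)


@dataclass
class ClusterAssignment:
    """cell -> cluster label in 1..k; labels ordered by decreasing size
    (ties: cluster containing the lexicographically smallest cell first)."""

    labels: dict[str, int]
    k: int

    def __post_init__(self) -> None:
        used = set(self.labels.values())
        if used != set(range(1, self.k + 1)):
            raise ValueError(f"labels must exhaust 1..{self.k}, got {sorted(used)}")

    def cells_in(self, label: int) -> list[str]:
        return [c for c, l in self.labels.items() if l == label]

    def sizes(self) -> dict[int, int]:
        return {l: len(self.cells_in(l)) for l in range(1, self.k + 1)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"cell_id": list(self.labels), "cluster": list(self.labels.values())}
        ).set_index("cell_id")


def cut_tree(dendrogram: Dendrogram, k: int) -> ClusterAssignment:
    """Cut the tree into k groups by undoing the last k-1 merges."""
    n = len(dendrogram.leaves)
    if not (1 <= k <= n):
        raise ValueError(f"k must lie in [1, {n}], got {k}")
    kept = dendrogram.merges[: n - k]
    parent: dict[str, str] = {}

    def find(node: str) -> str:
        while node in parent:
            node = parent[node]
        return node

    for m in kept:
        parent[m.node_a] = m.new_node
        parent[m.node_b] = m.new_node
    clusters: dict[str, list[str]] = {}
    for leaf in dendrogram.leaves:
        clusters.setdefault(find(leaf), []).append(leaf)
    ordered = sorted(clusters.values(), key=lambda cs: (-len(cs), min(cs)))
    labels = {c: i for i, cs in enumerate(ordered, start=1) for c in cs}
    return ClusterAssignment(labels=labels, k=k)


def cluster_enriched_genes(
    matrix: ExpressionMatrix,
    assignment: ClusterAssignment,
    cluster_label: int,
    detection_threshold: float,
    min_in_prev: float = 0.75,
    max_out_prev: float = 0.25,
    probe_map: Optional[ProbeAnnotation] = None,
) -> pd.DataFrame:
    """Rank genes by detection-prevalence contrast for one cluster.

    score = in-cluster prevalence - out-of-cluster prevalence; a gene passes
    when in-prevalence >= ``min_in_prev`` and out-prevalence <=
    ``max_out_prev``.  Sorted by score descending, ties by symbol.
    """
    in_cells = assignment.cells_in(cluster_label)
    if not in_cells:
        raise ValueError(f"cluster {cluster_label} is empty")
    clustered = [c for c in matrix.cell_ids if c in assignment.labels]
    out_cells = [c for c in clustered if assignment.labels[c] != cluster_label]
    calls = detect_calls(matrix, detection_threshold)
    in_prev = calls[in_cells].mean(axis=1)
    out_prev = (
        calls[out_cells].mean(axis=1) if out_cells else pd.Series(0.0, index=calls.index)
    )
    score = in_prev - out_prev
    passes = (in_prev >= min_in_prev) & (out_prev <= max_out_prev)
    out = pd.DataFrame(
        {
            "probe_id": calls.index,
            "gene": [
                (probe_map.symbol_for(p) or p) if probe_map else p for p in calls.index
            ],
            "in_prevalence": in_prev.to_numpy(),
            "out_prevalence": out_prev.to_numpy(),
            "score": score.to_numpy(),
        }
    )[passes.to_numpy()]
    return out.sort_values(
        ["score", "gene", "probe_id"], ascending=[False, True, True]
    ).reset_index(drop=True)
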