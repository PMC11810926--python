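"""UPGMA clustering of the gene distance matrix into functional groups.

A hand-rolled UPGMA keeps the merge order fully deterministic: ties on merge
distance are broken by the lexicographically smallest combined member list,
so permuting the input gene order never changes the dendrogram. The tree is
cut into k groups by undoing the k−1 highest merges, and each group is
represented by its medoid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .go_semantics import GeneDistanceMatrix


@dataclass(frozen=True)
class Node:
    """Dendrogram node: a cluster with its merge height (0 for leaves)."""

    members: tuple[str, ...]
    height: float = 0.0
    children: Optional[tuple["Node", "Node"]] = None

    @property
    def is_leaf(self) -> bool:
        return self.children is None


@dataclass
class Dendrogram:
    leaves: tuple[str, ...]
    merges: tuple[Node, ...]  # internal nodes in merge order

    @property
    def root(self) -> Node:
        return self.merges[-1]

    @property
    def heights(self) -> list[float]:
        return [n.height for n in self.merges]


def upgma(matrix: GeneDistanceMatrix) -> Dendrogram:
    """Average-linkage (UPGMA) agglomeration of a gene distance matrix.

    Iteratively merges the closest pair of clusters; the distance between a
    merged cluster and any other is the size-weighted mean of the member
    cluster distances (equivalently, the mean over all member gene pairs).
    Deterministic: ties go to the pair whose sorted union of labels is
    lexicographically smallest.
    """
    labels = list(matrix.genes)
    if len(labels) < 2:
        raise ValueError("UPGMA needs at least two genes")

    nodes: dict[tuple[str, ...], Node] = {
        (lab,): Node(members=(lab,)) for lab in labels
    }
    idx = {lab: i for i, lab in enumerate(labels)}
    dist: dict[frozenset[tuple[str, ...]], float] = {}
    keys = sorted(nodes)
    for i, a in enumerate(keys):
        for b in keys[i + 1:]:
            dist[frozenset((a, b))] = float(
                matrix.matrix[idx[a[0]], idx[b[0]]]
            )

    merges: list[Node] = []
    while len(nodes) > 1:
        best_pair: tuple[tuple[str, ...], tuple[str, ...]] | None = None
        best_d = np.inf
        best_union: tuple[str, ...] | None = None
        for pair_key, d in dist.items():
            a, b = sorted(pair_key)
            union = tuple(sorted(a + b))
            if d < best_d or (d == best_d and union < best_union):
                best_d, best_pair, best_union = d, (a, b), union
        a, b = best_pair
        node = Node(members=best_union, height=best_d,
                    children=(nodes[a], nodes[b]))
        size_a, size_b = len(a), len(b)

        del nodes[a], nodes[b]
        new_dist: dict[frozenset[tuple[str, ...]], float] = {}
        for pair_key, d in dist.items():
            if a in pair_key or b in pair_key:
                continue
            new_dist[pair_key] = d
        for other in nodes:
            d_a = dist[frozenset((a, other))]
            d_b = dist[frozenset((b, other))]
            new_dist[frozenset((best_union, other))] = (
                (size_a * d_a + size_b * d_b) / (size_a + size_b)
            )
        nodes[best_union] = node
        dist = new_dist
        merges.append(node)

    return Dendrogram(leaves=tuple(sorted(labels)), merges=tuple(merges))


@dataclass
class FunctionalGroups:
    """A k-way partition of the genes, each group labeled by its smallest member."""

    groups: dict[str, tuple[str, ...]]
    representatives: dict[str, str] = field(default_factory=dict)

    @property
    def k(self) -> int:
        return len(self.groups)

    def partition(self) -> list[tuple[str, ...]]:
        return [self.groups[lab] for lab in sorted(self.groups)]

    def group_of(self, gene: str) -> str:
        for lab, members in self.groups.items():
            if gene in members:
                return lab
        raise KeyError(gene)


def cut_groups(dendrogram: Dendrogram, k: int) -> FunctionalGroups:
    """Cut the dendrogram into k groups by undoing the k−1 highest merges.

    Since UPGMA merge heights are non-decreasing, this equals replaying the
    first n−k merges from singletons.
    """
    n = len(dendrogram.leaves)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    clusters: dict[str, set[str]] = {lab: {lab} for lab in dendrogram.leaves}
    for node in dendrogram.merges[: n - k]:
        left, right = node.children
        lab_l = min(left.members)
        lab_r = min(right.members)
        merged = clusters.pop(lab_l) | clusters.pop(lab_r)
        clusters[min(lab_l, lab_r)] = merged
    groups = {lab: tuple(sorted(members)) for lab, members in clusters.items()}
    return FunctionalGroups(groups=groups)


def pick_representative(group: Sequence[str], matrix: GeneDistanceMatrix) -> str:
    """Group medoid: the gene minimizing its summed within-group distance.

    Singletons represent themselves; ties resolve lexicographically.
    """
    group = list(group)
    if not group:
        raise ValueError("group must be non-empty")
    if len(group) == 1:
        return group[0]
    idx = {g: matrix.genes.index(g) for g in group}
    best_gene, best_cost = None, np.inf
    for g in sorted(group):
        cost = sum(matrix.matrix[idx[g], idx[h]] for h in group if h != g)
        if cost < best_cost:
            best_gene, best_cost = g, cost
    return best_gene


def assign_representatives(
    groups: FunctionalGroups, matrix: GeneDistanceMatrix
) -> FunctionalGroups:
    groups.representatives = {
        lab: pick_representative(members, matrix)
        for lab, members in sorted(groups.groups.items())
    }
    return groups


def to_newick(dendrogram: Dendrogram) -> str:
    """Newick export with ultrametric branch lengths (leaf depth = height/2)."""

    def render(node: Node) -> str:
        if node.is_leaf:
            return node.members[0]
        left, right = node.children
        parts = []
        for child in sorted((left, right), key=lambda c: c.members):
            length = (node.height - child.height) / 2.0
            parts.append(f"{render(child)}:{length:.6g}")
        return "(" + ",".join(parts) + ")"

    return render(dendrogram.root) + ";"
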