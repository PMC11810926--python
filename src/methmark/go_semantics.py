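"""Gene functional distance from an ontology DAG plus gene annotations.

The distance between two terms averages an information-content component
(based on the weight of their minimum-weight common ancestor) and a
Sørensen–Dice component (symmetric difference of their propagated gene
sets). Gene–gene distance averages term distances over the full cross
product of the two genes' annotated terms; the resulting matrix is
max-scaled into [0, 1] when raw values exceed 1.

Terms in different namespaces share no ancestor: their information-content
distance is exactly 1, and two genes annotated only to disjoint cross-
namespace terms are at distance exactly 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .io_formats import TermRecord

logger = logging.getLogger("methmark")


@dataclass
class GoResource:
    """Ontology DAG with true-path-propagated term→gene annotation sets.

    ``dag`` has one edge per ``is_a`` link, child → parent. ``term_genes``
    holds the propagated annotation closure: a gene annotated to a term
    belongs to every ancestor's set as well, so each parent's set is a
    superset of each child's. ``ancestors_of`` includes the term itself.
    """

    dag: nx.DiGraph
    namespace: dict[str, str]
    term_genes: dict[str, frozenset[str]]
    gene_terms: dict[str, frozenset[str]]
    total_genes: int
    _ancestor_cache: dict[str, frozenset[str]] = field(
        default_factory=dict, repr=False
    )

    def ancestors_of(self, term: str) -> frozenset[str]:
        cached = self._ancestor_cache.get(term)
        if cached is None:
            # dag edges run child -> parent, so graph-descendants are ancestors
            cached = frozenset(nx.descendants(self.dag, term)) | {term}
            self._ancestor_cache[term] = cached
        return cached


def build_resource(
    terms: Sequence[TermRecord], annotations: Iterable[tuple[str, str]]
) -> GoResource:
    """Assemble a :class:`GoResource`, applying the true-path rule.

    Every (gene, term) annotation is propagated to all of the term's
    ancestors. Annotations to unknown terms are skipped with a warning;
    a cyclic graph is an error.
    """
    dag = nx.DiGraph()
    namespace: dict[str, str] = {}
    for t in terms:
        dag.add_node(t.id)
        namespace[t.id] = t.namespace
        for parent in t.parents:
            dag.add_edge(t.id, parent)
    if not nx.is_directed_acyclic_graph(dag):
        raise ValueError("ontology is_a graph contains a cycle")

    resource = GoResource(
        dag=dag, namespace=namespace, term_genes={}, gene_terms={}, total_genes=0
    )

    term_genes: dict[str, set[str]] = {t: set() for t in dag.nodes}
    gene_terms: dict[str, set[str]] = {}
    for gene, term in annotations:
        if term not in term_genes:
            logger.warning("annotation (%s, %s) references unknown term; skipped",
                           gene, term)
            continue
        gene_terms.setdefault(gene, set()).add(term)
        for anc in resource.ancestors_of(term):
            term_genes[anc].add(gene)

    resource.term_genes = {t: frozenset(g) for t, g in term_genes.items()}
    resource.gene_terms = {g: frozenset(t) for g, t in gene_terms.items()}
    resource.total_genes = len(gene_terms)
    return resource


def term_weight(term: str, resource: GoResource) -> float:
    """Fraction of all annotated genes carried by ``term`` after propagation.

    An upper-level term annotates more genes and so has a higher weight; the
    root of a fully annotated namespace has weight 1. Terms with an empty
    propagated set get weight 0 (flagged via warning).
    """
    if resource.total_genes == 0:
        raise ValueError("resource has no annotated genes")
    genes = resource.term_genes.get(term)
    if genes is None:
        raise KeyError(f"unknown term {term!r}")
    if not genes:
        logger.warning("term %s has an empty propagated gene set; weight 0", term)
        return 0.0
    return len(genes) / resource.total_genes


def lca_weight(ti: str, tj: str, resource: GoResource) -> float | None:
    """Weight of the minimum-weight (most specific) common ancestor.

    A term is its own ancestor. Returns None when the terms share no common
    ancestor (e.g. they live in different namespaces).
    """
    common = resource.ancestors_of(ti) & resource.ancestors_of(tj)
    if not common:
        return None
    return min(term_weight(t, resource) for t in common)


def dist_ic(ti: str, tj: str, resource: GoResource) -> float:
    """Information-content distance between two terms.

    ``2·W(LCA) − W(ti) − W(tj)`` when a common ancestor exists, else exactly
    1. Non-negative under the propagation closure because the common
    ancestor's gene set contains both terms' sets.
    """
    w_lca = lca_weight(ti, tj, resource)
    if w_lca is None:
        return 1.0
    return 2.0 * w_lca - term_weight(ti, resource) - term_weight(tj, resource)


def dist_sc(ti: str, tj: str, resource: GoResource) -> float:
    """Sørensen–Dice distance between two terms' propagated gene sets:
    ``|AΔB| / (|A∪B| + |A∩B|)``."""
    a = resource.term_genes.get(ti, frozenset())
    b = resource.term_genes.get(tj, frozenset())
    if not a and not b:
        raise ValueError(f"both {ti!r} and {tj!r} have empty gene sets")
    sym = len(a ^ b)
    return sym / (len(a | b) + len(a & b))


def term_distance(ti: str, tj: str, resource: GoResource) -> float:
    """Arithmetic mean of the information-content and Sørensen–Dice distances."""
    return 0.5 * (dist_ic(ti, tj, resource) + dist_sc(ti, tj, resource))


def gene_distance(a: str, b: str, resource: GoResource) -> float:
    """Functional distance between two genes.

    The mean of ``term_distance`` over the full cross product of the genes'
    directly annotated term sets. The self-distance is 0 by convention.
    Genes without annotations are an error.
    """
    if a == b:
        return 0.0
    terms_a = resource.gene_terms.get(a)
    terms_b = resource.gene_terms.get(b)
    if not terms_a:
        raise ValueError(f"gene {a!r} has no annotations")
    if not terms_b:
        raise ValueError(f"gene {b!r} has no annotations")
    total = 0.0
    for ti in terms_a:
        for tj in terms_b:
            total += term_distance(ti, tj, resource)
    return total / (len(terms_a) * len(terms_b))


@dataclass
class GeneDistanceMatrix:
    """Symmetric gene–gene functional distance matrix, normalized to [0, 1]."""

    genes: list[str]
    matrix: np.ndarray
    normalization_factor: float = 1.0

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape != (len(self.genes), len(self.genes)):
            raise ValueError("matrix shape does not match gene list")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(m) != 0.0):
            raise ValueError("diagonal must be zero")

    def loc(self, a: str, b: str) -> float:
        i, j = self.genes.index(a), self.genes.index(b)
        return float(self.matrix[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.genes, columns=self.genes)

    def write(self, path: str | Path) -> None:
        frame = self.to_frame()
        frame.index.name = "gene"
        frame.to_csv(path, sep="\t")


def build_matrix(genes: Sequence[str], resource: GoResource) -> GeneDistanceMatrix:
    """Pairwise gene distance matrix, max-scaled into [0, 1] when needed.

    Raw information-content distances can exceed 1 (two specific siblings
    under a heavy ancestor), so when the largest off-diagonal entry is
    above 1 every off-diagonal entry is divided by that maximum. Entries
    are left untouched when the maximum is already ≤ 1. Diagonal is 0.
    """
    genes = list(genes)
    if len(genes) < 2:
        raise ValueError("need at least two genes")
    n = len(genes)
    m = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            d = gene_distance(genes[i], genes[j], resource)
            m[i, j] = m[j, i] = d
    off_max = float(m.max())
    factor = 1.0
    if off_max > 1.0:
        factor = off_max
        m = m / off_max
        np.fill_diagonal(m, 0.0)
    return GeneDistanceMatrix(genes=genes, matrix=m, normalization_factor=factor)
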