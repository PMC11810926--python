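"""Shared fixtures and independent oracles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from methmark.go_semantics import GoResource, build_resource
from methmark.io_formats import BetaMatrix, ManifestRecord, ProbeManifest, RunConfig, TermRecord


@pytest.fixture
def config() -> RunConfig:
    return RunConfig()


def make_resource(term_specs, annotations) -> GoResource:
    """Build a GoResource from (id, namespace, parents) triples."""
    terms = [
        TermRecord(id=t, name=t, namespace=ns, parents=tuple(parents))
        for t, ns, parents in term_specs
    ]
    return build_resource(terms, annotations)


@pytest.fixture
def sibling_resource() -> GoResource:
    """Root annotating 10 genes; two leaf siblings with one gene each.

    W(root) = 1.0, W(leaf) = 0.1, so the raw information-content distance
    between the leaves is 2·1.0 − 0.1 − 0.1 = 1.8.
    """
    terms = [
        ("GO:R", "biological_process", []),
        ("GO:L1", "biological_process", ["GO:R"]),
        ("GO:L2", "biological_process", ["GO:R"]),
    ]
    annotations = [("gene1", "GO:L1"), ("gene2", "GO:L2")]
    annotations += [(f"bg{i}", "GO:R") for i in range(8)]
    return make_resource(terms, annotations)


@pytest.fixture
def cross_namespace_resource() -> GoResource:
    """One annotated term per namespace; no shared ancestors, disjoint sets."""
    terms = [
        ("GO:BP", "biological_process", []),
        ("GO:MF", "molecular_function", []),
    ]
    return make_resource(terms, [("geneA", "GO:BP"), ("geneB", "GO:MF")])


def make_beta_matrix(data: dict[str, list[float]], groups: dict[str, str],
                     samples: list[str]) -> BetaMatrix:
    values = pd.DataFrame.from_dict(data, orient="index", columns=samples)
    return BetaMatrix(values=values, group_of=groups)


def make_manifest(entries: dict[str, tuple[str | None, str]]) -> ProbeManifest:
    return ProbeManifest(records={
        p: ManifestRecord(gene=g, region=r) for p, (g, r) in entries.items()
    })


# ---------------------------------------------------------------------------
# Independent oracles (kept free of the implementations they check)
# ---------------------------------------------------------------------------

def bh_stepup_oracle(p: np.ndarray) -> np.ndarray:
    """Literal step-up definition: q_(i) = min_{j>=i} p_(j)·m/j, capped at 1."""
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    for rank_pos, idx in enumerate(order):
        candidates = [
            p[order[j]] * m / (j + 1) for j in range(rank_pos, m)
        ]
        q[idx] = min(1.0, min(candidates))
    return q


def naive_ancestors(term: str, parents: dict[str, list[str]]) -> set[str]:
    """Ancestor closure (incl. self) by plain BFS over the parent mapping."""
    seen = {term}
    frontier = [term]
    while frontier:
        nxt = []
        for t in frontier:
            for p in parents.get(t, []):
                if p not in seen:
                    seen.add(p)
                    nxt.append(p)
        frontier = nxt
    return seen


def naive_term_genes(parents: dict[str, list[str]],
                     annotations: list[tuple[str, str]]) -> dict[str, set[str]]:
    """Propagated term→gene sets computed without the package's machinery."""
    out: dict[str, set[str]] = {t: set() for t in parents}
    for gene, term in annotations:
        for anc in naive_ancestors(term, parents):
            out.setdefault(anc, set()).add(gene)
    return out


def random_dag(rng: np.random.Generator, max_terms: int = 50):
    """Random single-namespace DAG with random gene annotations.

    Returns (term_specs, annotations, parents) where parents maps each term
    to its parent list; term i may only point at earlier terms, guaranteeing
    acyclicity.
    """
    n_terms = int(rng.integers(2, max_terms + 1))
    names = [f"GO:{i:04d}" for i in range(n_terms)]
    parents: dict[str, list[str]] = {names[0]: []}
    for i in range(1, n_terms):
        k = int(rng.integers(1, min(i, 3) + 1))
        parents[names[i]] = list(
            rng.choice(names[:i], size=k, replace=False)
        )
    n_genes = int(rng.integers(1, 15))
    annotations = []
    for g in range(n_genes):
        for term in rng.choice(names, size=int(rng.integers(1, 4)), replace=True):
            annotations.append((f"g{g}", str(term)))
    term_specs = [(t, "biological_process", parents[t]) for t in names]
    return term_specs, annotations, parents
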