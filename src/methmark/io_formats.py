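"""Readers/writers for β-value matrices, gene sets, ontologies, and run configuration.

All science-free plumbing lives here: delimited-text β-matrices with sample
group labels, one-symbol-per-line gene lists, a minimal OBO 1.2 subset
(``id``/``name``/``namespace``/``is_a``), two-column gene→term annotation
tables, and the YAML run configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("methmark")

GROUP_TUMOR = "tumor"
GROUP_NORMAL = "normal"
VALID_GROUPS = (GROUP_TUMOR, GROUP_NORMAL)

REGION_PROMOTER = "promoter"
REGION_OTHER = "other"
VALID_REGIONS = (REGION_PROMOTER, REGION_OTHER)

GO_NAMESPACES = ("biological_process", "cellular_component", "molecular_function")


class FormatError(ValueError):
    """Raised on malformed or out-of-contract input files."""


# ---------------------------------------------------------------------------
# β-value matrix
# ---------------------------------------------------------------------------

@dataclass
class BetaMatrix:
    """Probe × sample matrix of methylation β-values with tumor/normal labels.

    Parameters
    ----------
    values
        DataFrame indexed by probe id with sample ids as columns. Entries are
        β-values in [0, 1]; NaN marks a missing measurement.
    group_of
        Mapping from sample id to ``"tumor"`` or ``"normal"``. Every column of
        ``values`` must be labeled and both groups must be non-empty.
    """

    values: pd.DataFrame
    group_of: dict[str, str]

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate probe ids: {dups[:5]}")
        for sample in self.values.columns:
            group = self.group_of.get(sample)
            if group is None:
                raise FormatError(f"sample {sample!r} has no group label")
            if group not in VALID_GROUPS:
                raise FormatError(
                    f"sample {sample!r} has invalid group {group!r}; "
                    f"expected one of {VALID_GROUPS}"
                )
        present = {self.group_of[s] for s in self.values.columns}
        for group in VALID_GROUPS:
            if group not in present:
                raise FormatError(f"no samples labeled {group!r}")
        self._check_range()

    def _check_range(self) -> None:
        arr = self.values.to_numpy(dtype=float)
        bad = (arr < 0.0) | (arr > 1.0)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            probe = self.values.index[i]
            sample = self.values.columns[j]
            raise FormatError(
                f"β-value {arr[i, j]!r} out of [0, 1] at probe {probe!r}, "
                f"sample {sample!r}"
            )

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.group_of[s] == group]

    def write(self, matrix_path: str | Path, labels_path: str | Path) -> None:
        """Write the matrix as TSV and the sample labels as two-column TSV."""
        self.values.to_csv(matrix_path, sep="\t", index_label="probe")
        labels = pd.DataFrame(
            {"sample": self.sample_ids,
             "group": [self.group_of[s] for s in self.sample_ids]}
        )
        labels.to_csv(labels_path, sep="\t", index=False)


def read_beta_matrix(path: str | Path, labels: str | Path) -> BetaMatrix:
    """Read a probe × sample β-matrix plus its sample→group label table.

    Rows whose values are all missing are dropped with a warning. Values
    outside [0, 1] are a hard error naming the offending probe and sample —
    never clamped.
    """
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    # round_trip parsing keeps written β-values bit-exact
    values = pd.read_csv(path, sep=sep, index_col=0,
                         float_precision="round_trip")
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    try:
        values = values.astype(float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"non-numeric β-value in {path}: {exc}") from exc

    all_missing = values.isna().all(axis=1)
    if all_missing.any():
        dropped = values.index[all_missing].tolist()
        logger.warning(
            "dropping %d all-missing probe row(s): %s", len(dropped), dropped[:10]
        )
        values = values.loc[~all_missing]

    label_df = pd.read_csv(labels, sep=None, engine="python", dtype=str)
    if label_df.shape[1] < 2:
        raise FormatError(f"label file {labels} needs two columns (sample, group)")
    group_of = dict(zip(label_df.iloc[:, 0], label_df.iloc[:, 1]))
    return BetaMatrix(values=values, group_of=group_of)


# ---------------------------------------------------------------------------
# Probe manifest
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ManifestRecord:
    """Per-probe annotation: gene symbol, region class, 0-based coordinate."""

    gene: str | None
    region: str
    chrom: str = "."
    pos: int = 0

    def __post_init__(self) -> None:
        if self.region not in VALID_REGIONS:
            raise FormatError(
                f"region {self.region!r} not in {VALID_REGIONS}"
            )


@dataclass
class ProbeManifest:
    """Mapping probe id → :class:`ManifestRecord` (each probe → ≤1 gene)."""

    records: dict[str, ManifestRecord]

    def get(self, probe: str) -> ManifestRecord | None:
        return self.records.get(probe)

    def probes_for_gene(self, gene: str) -> list[str]:
        return [p for p, r in self.records.items() if r.gene == gene]

    def __len__(self) -> int:
        return len(self.records)

    def write(self, path: str | Path) -> None:
        rows = [
            {"probe": p, "gene": r.gene or "", "region": r.region,
             "chrom": r.chrom, "pos": r.pos}
            for p, r in self.records.items()
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_manifest(path: str | Path) -> ProbeManifest:
    df = pd.read_csv(path, sep="\t", dtype={"probe": str, "gene": str,
                                            "region": str, "chrom": str})
    required = {"probe", "gene", "region"}
    if not required.issubset(df.columns):
        raise FormatError(f"manifest {path} missing columns {required - set(df.columns)}")
    records: dict[str, ManifestRecord] = {}
    for row in df.itertuples(index=False):
        gene = getattr(row, "gene", None)
        if gene is not None and (pd.isna(gene) or gene == ""):
            gene = None
        records[str(row.probe)] = ManifestRecord(
            gene=gene,
            region=str(row.region),
            chrom=str(getattr(row, "chrom", ".")),
            pos=int(getattr(row, "pos", 0)),
        )
    return ProbeManifest(records=records)


# ---------------------------------------------------------------------------
# Gene sets (comorbidity exports)
# ---------------------------------------------------------------------------

def read_gene_sets(paths: Iterable[str | Path]) -> dict[str, set[str]]:
    """Read one-symbol-per-line gene lists, keyed by file stem.

    Symbols are upper-cased and de-duplicated. An empty file yields an empty
    set with a warning; a missing file is a hard error.
    """
    out: dict[str, set[str]] = {}
    for path in paths:
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"gene-set file not found: {path}")
        symbols = {
            line.strip().upper()
            for line in path.read_text().splitlines()
            if line.strip()
        }
        if not symbols:
            logger.warning("gene-set file %s is empty", path)
        out[path.stem] = symbols
    return out


def write_gene_set(genes: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in sorted(genes)))


# ---------------------------------------------------------------------------
# Ontology (OBO 1.2 subset) and annotations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TermRecord:
    """Raw ontology term: id, display name, namespace, ``is_a`` parents."""

    id: str
    name: str
    namespace: str
    parents: tuple[str, ...] = ()


def read_obo(path: str | Path) -> list[TermRecord]:
    """Parse an OBO file's ``[Term]`` stanzas (id/name/namespace/is_a only).

    Obsolete terms are skipped. A cyclic ``is_a`` graph is a hard error: the
    ontology must be a DAG.
    """
    terms: list[TermRecord] = []
    stanza: dict[str, object] | None = None

    def flush() -> None:
        if stanza is None or "id" not in stanza:
            return
        if stanza.get("obsolete"):
            logger.warning("skipping obsolete term %s", stanza["id"])
            return
        ns = stanza.get("namespace", "")
        if ns not in GO_NAMESPACES:
            raise FormatError(
                f"term {stanza['id']} has namespace {ns!r}; "
                f"expected one of {GO_NAMESPACES}"
            )
        terms.append(TermRecord(
            id=str(stanza["id"]),
            name=str(stanza.get("name", "")),
            namespace=str(ns),
            parents=tuple(stanza.get("parents", [])),
        ))

    in_term = False
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if line.startswith("["):
            if in_term:
                flush()
            in_term = line == "[Term]"
            stanza = {"parents": []} if in_term else None
            continue
        if not in_term or not line or ":" not in line:
            continue
        key, _, value = line.partition(":")
        value = value.strip()
        if key == "id":
            stanza["id"] = value
        elif key == "name":
            stanza["name"] = value
        elif key == "namespace":
            stanza["namespace"] = value
        elif key == "is_a":
            stanza["parents"].append(value.split("!")[0].strip())
        elif key == "is_obsolete" and value.lower() == "true":
            stanza["obsolete"] = True
    if in_term:
        flush()

    graph = nx.DiGraph()
    graph.add_nodes_from(t.id for t in terms)
    for t in terms:
        for parent in t.parents:
            graph.add_edge(t.id, parent)
    if not nx.is_directed_acyclic_graph(graph):
        raise FormatError(f"cyclic is_a graph in {path}")
    return terms


def read_annotations(
    path: str | Path, known_terms: set[str] | None = None
) -> list[tuple[str, str]]:
    """Read a two-column (gene, term) annotation table.

    Pairs pointing at terms absent from ``known_terms`` are skipped with a
    warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"annotation file {path} needs two columns (gene, term)")
    pairs: list[tuple[str, str]] = []
    for gene, term in zip(df.iloc[:, 0], df.iloc[:, 1]):
        if known_terms is not None and term not in known_terms:
            logger.warning("annotation (%s, %s) references unknown term; skipped",
                           gene, term)
            continue
        pairs.append((str(gene), str(term)))
    return pairs


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """All pipeline thresholds and knobs, YAML-round-trippable.

    Defaults follow the study design: DMP calling at |Δβ| ≥ 0.35 with
    BH-adjusted p < 0.01, cross-cancer commonality at |Δβ| > 0.2, Tukey
    fences at k = 1.5, three functional groups.
    """

    dmp_abs_dbeta_threshold: float = 0.35
    dmp_q_threshold: float = 0.01
    gene_q_threshold: float = 0.01
    common_abs_dbeta_threshold: float = 0.2
    iqr_k: float = 1.5
    min_group_size_after_outliers: int = 3
    promoter_only: bool = True
    n_groups: int = 3
    seed: int = 0
    test_fraction: float = 0.2
    svm_c: float = 1.0
    svm_gamma: str | float = "scale"
    feature_mode: str = "probe"  # "probe" (representative probe) or "gene_mean"

    def __post_init__(self) -> None:
        for name in ("dmp_abs_dbeta_threshold", "dmp_q_threshold",
                     "gene_q_threshold", "common_abs_dbeta_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.iqr_k < 0:
            raise ValueError("iqr_k must be non-negative")
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must be in (0, 1)")
        if self.min_group_size_after_outliers < 1:
            raise ValueError("min_group_size_after_outliers must be >= 1")
        if self.n_groups < 1:
            raise ValueError("n_groups must be >= 1")
        if self.feature_mode not in ("probe", "gene_mean"):
            raise ValueError("feature_mode must be 'probe' or 'gene_mean'")

    @classmethod
    def from_dict(cls, data: Mapping[str, object]) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        data = {f.name: getattr(self, f.name) for f in fields(self)}
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
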