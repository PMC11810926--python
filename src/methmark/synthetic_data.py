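"""Synthetic inputs with planted ground truth for every pipeline stage.

β-values are drawn from beta distributions parameterized by (mean, precision)
so a planted effect is an interpretable shift of the tumor-group mean at a
gene's promoter probe. Outliers replace values with draws near the opposite
methylation extreme. The ontology generator emits a three-namespace DAG in
which genes of the same planted functional group share one specific term per
namespace and genes of different groups share only the namespace roots.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .io_formats import (
    BetaMatrix,
    GO_NAMESPACES,
    GROUP_NORMAL,
    GROUP_TUMOR,
    ManifestRecord,
    ProbeManifest,
    REGION_OTHER,
    REGION_PROMOTER,
    write_gene_set,
)

logger = logging.getLogger("methmark")

# planted normal-group mean is drawn from these windows so mean + effect
# stays inside (0.02, 0.98) by construction
_POS_WINDOW = (0.15, 0.35)
_NEG_WINDOW = (0.65, 0.85)
_MEAN_BOUNDS = (0.02, 0.98)


@dataclass
class SimSpec:
    """Full description of a synthetic multi-cancer study.

    ``pan_effects`` genes are planted with the same signed Δβ effect in every
    cancer (the intended common biomarkers); ``extra_effects`` genes are
    planted in a single cancer only. ``functional_groups`` partitions the
    pan genes into the ground-truth functional groups used by the ontology
    generator.
    """

    cancers: tuple[str, ...] = ("cancer_a", "cancer_b", "cancer_c",
                                "cancer_d", "cancer_e")
    n_tumor: int = 30
    n_normal: int = 30
    n_null_genes: int = 40
    probes_per_gene: int = 2
    pan_effects: dict[str, float] = field(default_factory=dict)
    extra_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    functional_groups: dict[str, tuple[str, ...]] = field(default_factory=dict)
    base_mean_low: float = 0.25
    base_mean_high: float = 0.6
    precision: float = 60.0
    outlier_rate: float = 0.0
    comorbidities_per_cancer: int = 2
    decoys_per_comorbidity: int = 10
    coverage: float = 1.0
    n_go_background_genes: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_tumor < 2 or self.n_normal < 2:
            raise ValueError("need at least 2 samples per group")
        if not 0.0 <= self.outlier_rate < 1.0:
            raise ValueError("outlier_rate must be in [0, 1)")
        if not 0.0 <= self.coverage <= 1.0:
            raise ValueError("coverage must be in [0, 1]")
        all_effects: list[tuple[str, float]] = list(self.pan_effects.items())
        for per_cancer in self.extra_effects.values():
            all_effects.extend(per_cancer.items())
        for gene, effect in all_effects:
            if not -1.0 <= effect <= 1.0:
                raise ValueError(f"effect for {gene} outside [-1, 1]: {effect}")
            lo, hi = _POS_WINDOW if effect >= 0 else _NEG_WINDOW
            if not (_MEAN_BOUNDS[0] < lo + effect and
                    hi + effect < _MEAN_BOUNDS[1]):
                raise ValueError(
                    f"effect {effect} for {gene} pushes the shifted mean "
                    f"outside {_MEAN_BOUNDS}"
                )
        grouped = [g for members in self.functional_groups.values()
                   for g in members]
        if len(grouped) != len(set(grouped)):
            raise ValueError("functional groups must be disjoint")
        unknown = set(grouped) - set(self.pan_effects)
        if unknown:
            raise ValueError(
                f"functional-group genes missing from pan_effects: {sorted(unknown)}"
            )

    # ---- derived gene/probe universe (deterministic order) -----------------

    def planted_genes(self, cancer: str) -> dict[str, float]:
        effects = dict(self.pan_effects)
        effects.update(self.extra_effects.get(cancer, {}))
        return effects

    def all_genes(self) -> list[str]:
        extras = sorted({g for per in self.extra_effects.values() for g in per})
        nulls = [f"NULL{i:04d}" for i in range(1, self.n_null_genes + 1)]
        return sorted(self.pan_effects) + extras + nulls

    def probes_of(self, gene: str) -> list[str]:
        return [f"{gene}_p{k}" for k in range(self.probes_per_gene)]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimSpec":
        data = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("cancers",):
            if key in data:
                data[key] = tuple(data[key])
        if "functional_groups" in data:
            data["functional_groups"] = {
                k: tuple(v) for k, v in data["functional_groups"].items()
            }
        return cls(**data)


def default_spec(seed: int = 0, **overrides) -> SimSpec:
    """Desk-scale default: 5 cancers, 8 pan-cancer genes in 5/2/1 groups.

    Six hypermethylated and two hypomethylated pan genes (effects ±0.4),
    two extra per-cancer-only planted genes per cancer, 40 null genes.
    """
    pan = {
        "GENEA": 0.4, "GENEB": 0.4, "GENEC": 0.4, "GENED": 0.4,
        "GENEE": -0.4, "GENEF": 0.4, "GENEG": -0.4, "GENEH": 0.4,
    }
    groups = {
        "g1": ("GENEA", "GENEB", "GENEC", "GENED", "GENEE"),
        "g2": ("GENEF", "GENEG"),
        "g3": ("GENEH",),
    }
    cancers = ("cancer_a", "cancer_b", "cancer_c", "cancer_d", "cancer_e")
    extras = {
        c: {f"XTRA{c[-1].upper()}{k}": 0.45 for k in (1, 2)} for c in cancers
    }
    params = dict(cancers=cancers, pan_effects=pan, extra_effects=extras,
                  functional_groups=groups, seed=seed)
    params.update(overrides)
    return SimSpec(**params)


# ---------------------------------------------------------------------------
# β-matrix simulation
# ---------------------------------------------------------------------------

def build_manifest(spec: SimSpec) -> ProbeManifest:
    """Shared probe manifest: probe 0 of each gene is the promoter probe."""
    records: dict[str, ManifestRecord] = {}
    pos = 0
    for gene in spec.all_genes():
        for k, probe in enumerate(spec.probes_of(gene)):
            records[probe] = ManifestRecord(
                gene=gene,
                region=REGION_PROMOTER if k == 0 else REGION_OTHER,
                chrom="chr1",
                pos=pos,
            )
            pos += 1000
    return ProbeManifest(records=records)


def _beta_draw(rng: np.random.Generator, mean: float, precision: float,
               size: int) -> np.ndarray:
    a = mean * precision
    b = (1.0 - mean) * precision
    return rng.beta(a, b, size=size)


def simulate_beta_matrix(
    spec: SimSpec, cancer: str
) -> tuple[BetaMatrix, pd.DataFrame]:
    """Simulate one cancer's probe × sample β-matrix plus its truth table.

    Null probes share a group-common mean; each planted gene's promoter probe
    has tumor mean = normal mean + effect. With ``outlier_rate`` > 0,
    individual values are replaced by draws near the opposite methylation
    extreme. Deterministic in (spec.seed, cancer).
    """
    if cancer not in spec.cancers:
        raise ValueError(f"unknown cancer {cancer!r}")
    rng = np.random.default_rng([spec.seed, spec.cancers.index(cancer)])
    planted = spec.planted_genes(cancer)

    tumor_ids = [f"{cancer}_T{i:03d}" for i in range(spec.n_tumor)]
    normal_ids = [f"{cancer}_N{i:03d}" for i in range(spec.n_normal)]
    group_of = {s: GROUP_TUMOR for s in tumor_ids}
    group_of.update({s: GROUP_NORMAL for s in normal_ids})

    rows: dict[str, np.ndarray] = {}
    for gene in spec.all_genes():
        effect = planted.get(gene, 0.0)
        for k, probe in enumerate(spec.probes_of(gene)):
            if k == 0 and effect != 0.0:
                lo, hi = _POS_WINDOW if effect >= 0 else _NEG_WINDOW
                normal_mean = rng.uniform(lo, hi)
                tumor_mean = normal_mean + effect
            else:
                normal_mean = tumor_mean = rng.uniform(
                    spec.base_mean_low, spec.base_mean_high
                )
            t_vals = _beta_draw(rng, tumor_mean, spec.precision, spec.n_tumor)
            n_vals = _beta_draw(rng, normal_mean, spec.precision, spec.n_normal)
            if spec.outlier_rate > 0.0:
                for vals, mean in ((t_vals, tumor_mean), (n_vals, normal_mean)):
                    mask = rng.random(vals.size) < spec.outlier_rate
                    if mask.any():
                        opposite = 0.95 if mean < 0.5 else 0.05
                        vals[mask] = _beta_draw(rng, opposite, spec.precision,
                                                int(mask.sum()))
            rows[probe] = np.concatenate([t_vals, n_vals])

    values = pd.DataFrame.from_dict(rows, orient="index",
                                    columns=tumor_ids + normal_ids)
    truth = pd.DataFrame(
        [{"gene": g, "effect": e, "pan_cancer": g in spec.pan_effects}
         for g, e in sorted(planted.items())]
    )
    truth["seed"] = spec.seed
    return BetaMatrix(values=values, group_of=group_of), truth


# ---------------------------------------------------------------------------
# Ontology simulation
# ---------------------------------------------------------------------------

@dataclass
class GoSim:
    obo_text: str
    annotations: list[tuple[str, str]]
    truth_groups: dict[str, tuple[str, ...]]


def simulate_go(spec: SimSpec) -> GoSim:
    """Three-namespace DAG with one shared specific term per group per namespace.

    Genes within a planted group are annotated to the same leaf term in each
    namespace; genes of different groups share only the namespace roots (via
    true-path propagation). Background genes annotated at the roots pad the
    total gene count so group-term weights are small. Output text is fully
    deterministic for a given spec.
    """
    if not spec.functional_groups:
        raise ValueError("spec has no functional groups to simulate")
    lines: list[str] = ["format-version: 1.2", ""]
    annotations: list[tuple[str, str]] = []

    def stanza(term_id: str, name: str, ns: str, parent: str | None) -> None:
        lines.extend(["[Term]", f"id: {term_id}", f"name: {name}",
                      f"namespace: {ns}"])
        if parent is not None:
            lines.append(f"is_a: {parent} ! parent")
        lines.append("")

    background = [f"BGG{i:03d}" for i in range(1, spec.n_go_background_genes + 1)]
    for ns_idx, ns in enumerate(GO_NAMESPACES, start=1):
        root = f"GO:{ns_idx:07d}"
        stanza(root, f"{ns} root", ns, None)
        for g_idx, (group, members) in enumerate(
                sorted(spec.functional_groups.items()), start=1):
            term = f"GO:{ns_idx}1{g_idx:05d}"
            stanza(term, f"{ns} term for {group}", ns, root)
            for gene in sorted(members):
                annotations.append((gene, term))
        for gene in background:
            annotations.append((gene, root))

    return GoSim(
        obo_text="\n".join(lines),
        annotations=annotations,
        truth_groups={g: tuple(sorted(m))
                      for g, m in sorted(spec.functional_groups.items())},
    )


# ---------------------------------------------------------------------------
# Comorbidity gene-set simulation
# ---------------------------------------------------------------------------

def simulate_comorbidity_sets(
    spec: SimSpec, cancer: str
) -> dict[str, set[str]]:
    """Per-comorbidity gene sets covering the cancer's planted genes.

    A ``coverage`` fraction of the planted genes (rounded down, deterministic
    in the spec seed) is distributed round-robin over the comorbidity sets;
    each set is padded with inert decoy symbols.
    """
    rng = np.random.default_rng([spec.seed, 10_000 + spec.cancers.index(cancer)])
    planted = sorted(spec.planted_genes(cancer))
    n_cover = int(np.floor(spec.coverage * len(planted)))
    covered = sorted(rng.choice(planted, size=n_cover, replace=False).tolist())

    sets: dict[str, set[str]] = {}
    for i in range(spec.comorbidities_per_cancer):
        name = f"{cancer}_comorbidity{i + 1}"
        decoys = {f"DEC{cancer[-1].upper()}{i}{j:02d}"
                  for j in range(spec.decoys_per_comorbidity)}
        sets[name] = decoys
    names = sorted(sets)
    for j, gene in enumerate(covered):
        sets[names[j % len(names)]].add(gene)
    return sets


# ---------------------------------------------------------------------------
# Whole-study emission
# ---------------------------------------------------------------------------

def simulate_study(spec: SimSpec, out_dir: str | Path) -> dict[str, object]:
    """Write every input the pipeline consumes, in the formats io_formats reads.

    Emits per-cancer β-matrix and label TSVs, the probe manifest, the OBO
    ontology and annotation table, per-cancer comorbidity gene lists, the
    truth tables, and a ready-to-run pipeline ``config.yaml``. Returns a
    manifest of written paths plus the truth objects.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    manifest = build_manifest(spec)
    manifest_path = out / "manifest.tsv"
    manifest.write(manifest_path)

    cancer_entries: dict[str, dict[str, str]] = {}
    truth_frames = []
    for cancer in spec.cancers:
        matrix, truth = simulate_beta_matrix(spec, cancer)
        beta_path = out / f"beta_{cancer}.tsv"
        labels_path = out / f"labels_{cancer}.tsv"
        matrix.write(beta_path, labels_path)
        truth["cancer"] = cancer
        truth_frames.append(truth)

        comorbidity_dir = out / "comorbidities" / cancer
        comorbidity_dir.mkdir(parents=True, exist_ok=True)
        comorbidity_paths = []
        for name, genes in sorted(simulate_comorbidity_sets(spec, cancer).items()):
            path = comorbidity_dir / f"{name}.txt"
            write_gene_set(genes, path)
            comorbidity_paths.append(str(path))
        cancer_entries[cancer] = {
            "beta": str(beta_path),
            "labels": str(labels_path),
            "comorbidities": comorbidity_paths,
        }

    go_sim = simulate_go(spec)
    obo_path = out / "go.obo"
    obo_path.write_text(go_sim.obo_text)
    ann_path = out / "annotations.tsv"
    pd.DataFrame(go_sim.annotations, columns=["gene", "term"]).to_csv(
        ann_path, sep="\t", index=False
    )

    pd.concat(truth_frames, ignore_index=True).to_csv(
        out / "truth_markers.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        [{"group": g, "gene": gene, "seed": spec.seed}
         for g, members in go_sim.truth_groups.items() for gene in members]
    ).to_csv(out / "truth_groups.tsv", sep="\t", index=False)

    config = {
        "cancers": cancer_entries,
        "manifest": str(manifest_path),
        "obo": str(obo_path),
        "annotations": str(ann_path),
        "out": str(out / "results"),
        "run": {"seed": spec.seed},
    }
    config_path = out / "config.yaml"
    config_path.write_text(yaml.safe_dump(config, sort_keys=False))

    return {
        "config": str(config_path),
        "manifest": str(manifest_path),
        "obo": str(obo_path),
        "annotations": str(ann_path),
        "cancers": cancer_entries,
        "truth_groups": go_sim.truth_groups,
        "pan_genes": sorted(spec.pan_effects),
    }
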