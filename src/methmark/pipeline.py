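"""End-to-end orchestration: files in → ranked biomarker panels out.

Stages: per-cancer differential methylation and primary-marker calling;
comorbidity-based secondary markers; candidate intersection; cross-cancer
common-marker selection; GO functional distance matrix; UPGMA grouping with
medoid representatives; panel enumeration and per-cancer SVM evaluation;
optimal-panel selection. Each stage's tables are written under the output
directory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import (
    combo_eval,
    dmp_analysis,
    functional_clustering,
    go_semantics,
    marker_selection,
)
from .io_formats import (
    BetaMatrix,
    ProbeManifest,
    RunConfig,
    read_annotations,
    read_beta_matrix,
    read_gene_sets,
    read_manifest,
    read_obo,
)

logger = logging.getLogger("methmark")


@dataclass
class PipelineResult:
    config: RunConfig
    probe_records: dict[str, pd.DataFrame]
    primary: dict[str, dmp_analysis.PrimaryMarkerSet]
    candidates: dict[str, marker_selection.MarkerSet]
    common: marker_selection.CommonMarkerTable | None
    distance: go_semantics.GeneDistanceMatrix | None = None
    groups: functional_clustering.FunctionalGroups | None = None
    dendrogram: functional_clustering.Dendrogram | None = None
    reports: list[combo_eval.EvalReport] = field(default_factory=list)
    optimal_panel: tuple[str, ...] | None = None


def load_inputs(config: Mapping) -> tuple[
    dict[str, BetaMatrix], dict[str, dict[str, set[str]]],
    ProbeManifest, go_semantics.GoResource, RunConfig,
]:
    """Read every file referenced by a pipeline config mapping."""
    run_config = RunConfig.from_dict(config.get("run", {}))
    manifest = read_manifest(config["manifest"])
    terms = read_obo(config["obo"])
    annotations = read_annotations(config["annotations"],
                                   known_terms={t.id for t in terms})
    resource = go_semantics.build_resource(terms, annotations)

    matrices: dict[str, BetaMatrix] = {}
    comorbidities: dict[str, dict[str, set[str]]] = {}
    for cancer, entry in config["cancers"].items():
        matrices[cancer] = read_beta_matrix(entry["beta"], entry["labels"])
        comorbidities[cancer] = read_gene_sets(entry["comorbidities"])
    return matrices, comorbidities, manifest, resource, run_config


def run_pipeline(config: Mapping, out_dir: str | Path | None = None) -> PipelineResult:
    """Run the full analysis described by a pipeline config mapping.

    The config layout matches what :func:`methmark.synthetic_data.simulate_study`
    emits: per-cancer ``beta``/``labels``/``comorbidities`` paths plus shared
    ``manifest``/``obo``/``annotations`` and a ``run`` section of
    :class:`RunConfig` overrides.
    """
    matrices, comorbidities, manifest, resource, run_config = load_inputs(config)
    out = Path(out_dir if out_dir is not None else config.get("out", "results"))
    out.mkdir(parents=True, exist_ok=True)

    probe_records: dict[str, pd.DataFrame] = {}
    primary: dict[str, dmp_analysis.PrimaryMarkerSet] = {}
    candidates: dict[str, marker_selection.MarkerSet] = {}
    for cancer, matrix in matrices.items():
        records = dmp_analysis.probe_stats(matrix, manifest, run_config)
        probe_records[cancer] = records
        dmp_analysis.write_probe_records(records, out / f"probes_{cancer}.tsv")
        markers = dmp_analysis.call_primary_markers(records, run_config, cancer)
        primary[cancer] = markers
        dmp_analysis.write_primary_markers(markers, out / f"primary_{cancer}.tsv")
        secondary = marker_selection.secondary_markers(comorbidities[cancer])
        candidates[cancer] = marker_selection.candidate_markers(markers, secondary)
        logger.info("%s: %d primary, %d secondary, %d candidate genes",
                    cancer, len(markers.calls), len(secondary),
                    len(candidates[cancer]))

    common = marker_selection.common_markers(candidates, run_config)
    common.write(out / "common_markers.tsv")
    result = PipelineResult(
        config=run_config, probe_records=probe_records, primary=primary,
        candidates=candidates, common=common,
    )
    if len(common.genes) < 2:
        logger.warning("only %d common biomarker(s); skipping functional "
                       "grouping and panel evaluation", len(common.genes))
        return result

    distance = go_semantics.build_matrix(common.genes, resource)
    distance.write(out / "distance_matrix.tsv")
    dendrogram = functional_clustering.upgma(distance)
    (out / "dendrogram.nwk").write_text(
        functional_clustering.to_newick(dendrogram) + "\n"
    )
    k = min(run_config.n_groups, len(common.genes))
    groups = functional_clustering.cut_groups(dendrogram, k)
    functional_clustering.assign_representatives(groups, distance)
    pd.DataFrame(
        [{"gene": gene, "group": lab,
          "representative": int(gene == groups.representatives[lab])}
         for lab, members in sorted(groups.groups.items()) for gene in members]
    ).to_csv(out / "groups.tsv", sep="\t", index=False)
    result.distance = distance
    result.dendrogram = dendrogram
    result.groups = groups

    panels = combo_eval.enumerate_panels(groups)
    reports: list[combo_eval.EvalReport] = []
    for panel in panels:
        for cancer, matrix in matrices.items():
            reports.append(combo_eval.evaluate_panel(
                matrix, manifest, panel, run_config, cancer=cancer
            ))
    combo_eval.reports_frame(reports).to_csv(
        out / "panel_reports.tsv", sep="\t", index=False
    )
    optimal = combo_eval.select_optimal(reports)
    (out / "optimal_panel.txt").write_text("\n".join(optimal) + "\n")
    result.reports = reports
    result.optimal_panel = optimal
    logger.info("optimal panel: %s", "+".join(optimal))
    return result


def run_from_yaml(config_path: str | Path,
                  out_dir: str | Path | None = None) -> PipelineResult:
    config = yaml.safe_load(Path(config_path).read_text())
    return run_pipeline(config, out_dir=out_dir)
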