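# methmark

Multi-cancer DNA-methylation biomarker discovery on probe-level β-value
matrices:

1. **Differential methylation** (`dmp_analysis`) — per-probe Tukey-fence
   outlier removal within each group, Δβ = mean(tumor β) − mean(normal β),
   two-sided Welch t-test, Benjamini–Hochberg adjustment, volcano
   categorization (hyper / hypo / promoter / other), and gene-level primary
   biomarker calling (≥ 1 promoter probe with |Δβ| > 0.35 and q < 0.01 by
   default).
2. **Marker selection** (`marker_selection`) — secondary markers as the union
   of per-comorbidity gene lists, candidates as primary ∩ secondary, and
   common biomarkers as genes passing |Δβ| > 0.2 in every cancer's candidate
   set simultaneously.
3. **Functional distance** (`go_semantics`) — ontology-based gene distance:
   term weight = fraction of annotated genes after true-path propagation,
   information-content distance via the minimum-weight common ancestor
   (exactly 1 across namespaces), Sørensen–Dice distance on propagated gene
   sets, term distance as their mean, gene distance as the cross-product mean
   over annotated terms, and max-scaling of the matrix into [0, 1].
4. **Functional grouping** (`functional_clustering`) — deterministic UPGMA
   with lexicographic tie-breaks, cutting into k groups (default 3), medoid
   representatives, Newick export.
5. **Panel evaluation** (`combo_eval`) — enumeration of one-gene-per-group
   panels, leakage-free RBF-SVM evaluation (representative probe, imputation
   and scaling fitted on the training split only), accuracy / recall /
   precision / F with tumor positive, optimal-panel selection by mean
   accuracy, and a pooled universal model scored on held-out cohorts.
6. **Synthetic data** (`synthetic_data`) — beta-distributed β-values with
   planted group-shifted effects and injected outliers, a three-namespace
   ontology with planted functional groups, and comorbidity gene lists with
   configurable coverage — everything the pipeline consumes, with truth
   tables.

Raw IDAT/array ingestion, QC and normalization are out of scope: matrices
are assumed preprocessed β-values in [0, 1].

## CLI

Generate a synthetic study (writes β-matrices, labels, manifest, ontology,
annotations, comorbidity lists, truth tables and a ready `config.yaml`):

```bash
methmark simulate --out study/ --seed 7
```

Run the full pipeline:

```bash
methmark run --config study/config.yaml --out results/
# thresholds can be overridden, e.g.
methmark run --config study/config.yaml --dmp-threshold 0.3 --n-groups 4
```

Outputs per run: per-cancer probe records and primary-gene tables, the
common-biomarker table with per-cancer Δβ, the normalized gene distance
matrix, the dendrogram (Newick), group assignments with representatives,
per-panel per-cancer SVM metrics, and the selected optimal panel.

The config YAML maps each cancer to its β-matrix, label file and comorbidity
gene lists, plus shared `manifest` / `obo` / `annotations` paths and a `run`
section mirroring `methmark.io_formats.RunConfig`.

## Library use

```python
from methmark import synthetic_data as sd
from methmark.pipeline import run_pipeline
import yaml

paths = sd.simulate_study(sd.default_spec(seed=7), "study")
result = run_pipeline(yaml.safe_load(open(paths["config"])), out_dir="results")
print(result.common.genes, result.optimal_panel)
```
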