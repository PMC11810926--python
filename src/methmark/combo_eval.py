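"""Panel enumeration and SVM evaluation of biomarker combinations.

One gene per functional group forms a candidate panel; each panel is scored
by an RBF-kernel SVM on per-subject β-value features. The representative
probe per gene, imputation medians and standardization statistics are all
computed on the training split only and reused verbatim on the test split —
no leakage. Tumor is the positive class for recall/precision/F.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .dmp_analysis import STATUS_HYPER
from .functional_clustering import FunctionalGroups
from .io_formats import (
    BetaMatrix,
    GROUP_NORMAL,
    GROUP_TUMOR,
    ProbeManifest,
    RunConfig,
)

logger = logging.getLogger("methmark")


@dataclass
class FeatureTable:
    """Subjects × panel-gene β-value features with tumor/normal labels."""

    X: pd.DataFrame
    y: pd.Series
    cancer: str = ""

    def __post_init__(self) -> None:
        if not self.X.index.equals(self.y.index):
            raise ValueError("feature rows and labels must share an index")
        bad = set(self.y.unique()) - {GROUP_TUMOR, GROUP_NORMAL}
        if bad:
            raise ValueError(f"invalid labels {bad}")

    @property
    def panel(self) -> tuple[str, ...]:
        return tuple(self.X.columns)

    def __len__(self) -> int:
        return len(self.X)


@dataclass(frozen=True)
class EvalReport:
    """Classification metrics for one panel on one (test) cohort."""

    panel: tuple[str, ...]
    cancer: str
    accuracy: float
    recall: float
    precision: float
    f_score: float
    n_train: int
    n_test: int
    seed: int
    flags: tuple[str, ...] = ()


def enumerate_panels(groups: FunctionalGroups) -> list[tuple[str, ...]]:
    """All one-gene-per-group combinations (Cartesian product over groups).

    Panels are returned as sorted gene tuples; the list length equals the
    product of group sizes.
    """
    members = [groups.groups[lab] for lab in sorted(groups.groups)]
    if any(len(m) == 0 for m in members):
        raise ValueError("every group must be non-empty")
    return [tuple(sorted(combo)) for combo in itertools.product(*members)]


def choose_probes(
    matrix: BetaMatrix,
    manifest: ProbeManifest,
    panel: Sequence[str],
    samples: Sequence[str] | None = None,
) -> dict[str, str]:
    """Pick each panel gene's representative probe: max |Δβ| on ``samples``.

    ``samples`` should be the training subjects so the choice never sees test
    data. Genes with no probe in the matrix are an error.
    """
    if samples is None:
        samples = matrix.sample_ids
    samples = list(samples)
    tumor = [s for s in samples if matrix.group_of[s] == GROUP_TUMOR]
    normal = [s for s in samples if matrix.group_of[s] == GROUP_NORMAL]
    choice: dict[str, str] = {}
    for gene in panel:
        probes = [p for p in manifest.probes_for_gene(gene)
                  if p in matrix.values.index]
        if not probes:
            raise ValueError(f"gene {gene!r} has no probes in the matrix")
        best_probe, best_abs = None, -np.inf
        for probe in sorted(probes):
            row = matrix.values.loc[probe]
            d = abs(np.nanmean(row[tumor].to_numpy(dtype=float))
                    - np.nanmean(row[normal].to_numpy(dtype=float)))
            if np.isnan(d):
                d = -np.inf
            if d > best_abs:
                best_probe, best_abs = probe, d
        choice[gene] = best_probe
    return choice


def extract_features(
    matrix: BetaMatrix,
    manifest: ProbeManifest,
    panel: Sequence[str],
    probe_choice: Mapping[str, str],
    impute_medians: Mapping[str, float] | None = None,
    samples: Sequence[str] | None = None,
    cancer: str = "",
    feature_mode: str = "probe",
) -> FeatureTable:
    """Build the subjects × genes feature table for a panel.

    ``feature_mode="probe"`` uses each gene's representative probe
    (``probe_choice``); ``"gene_mean"`` averages all of the gene's probes.
    Missing values are imputed with ``impute_medians`` when given (the
    training-set medians), else with the table's own medians.
    """
    if samples is None:
        samples = matrix.sample_ids
    samples = list(samples)
    cols: dict[str, np.ndarray] = {}
    for gene in panel:
        if feature_mode == "gene_mean":
            probes = [p for p in manifest.probes_for_gene(gene)
                      if p in matrix.values.index]
            if not probes:
                raise ValueError(f"gene {gene!r} has no probes in the matrix")
            cols[gene] = matrix.values.loc[probes, samples].mean(axis=0).to_numpy()
        else:
            probe = probe_choice.get(gene)
            if probe is None:
                raise ValueError(f"no representative probe chosen for {gene!r}")
            cols[gene] = matrix.values.loc[probe, samples].to_numpy(dtype=float)
    X = pd.DataFrame(cols, index=samples)
    medians = (pd.Series(impute_medians) if impute_medians is not None
               else X.median())
    X = X.fillna(medians)
    if X.isna().any().any():
        raise ValueError("missing values remain after imputation")
    y = pd.Series([matrix.group_of[s] for s in samples], index=samples)
    return FeatureTable(X=X, y=y, cancer=cancer)


def compute_metrics(
    y_true: Sequence[str], y_pred: Sequence[str], positive: str = GROUP_TUMOR
) -> dict[str, float]:
    """Accuracy/recall/precision/F from the confusion matrix (tumor positive).

    Undefined ratios (no actual positives, no predicted positives, or
    precision+recall = 0) are reported as 0.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    tp = int(np.sum((y_true == positive) & (y_pred == positive)))
    fp = int(np.sum((y_true != positive) & (y_pred == positive)))
    fn = int(np.sum((y_true == positive) & (y_pred != positive)))
    tn = int(np.sum((y_true != positive) & (y_pred != positive)))
    n = tp + fp + fn + tn
    accuracy = (tp + tn) / n if n else 0.0
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    f_score = (2 * precision * recall / (precision + recall)
               if (precision + recall) else 0.0)
    return {"accuracy": accuracy, "recall": recall,
            "precision": precision, "f_score": f_score}


def _make_classifier(config: RunConfig) -> SVC:
    return SVC(kernel="rbf", C=config.svm_c, gamma=config.svm_gamma,
               class_weight="balanced", random_state=config.seed)


def fit_and_score(
    train: FeatureTable, test: FeatureTable, config: RunConfig
) -> EvalReport:
    """Fit the SVM on ``train`` and score it on ``test``.

    Standardization statistics come from the training table only. A test set
    lacking normals is evaluable (recall equals accuracy there) but flagged.
    """
    if train.y.nunique() < 2:
        raise ValueError("training set must contain both classes")
    if len(test) == 0:
        raise ValueError("test set is empty")
    if tuple(train.X.columns) != tuple(test.X.columns):
        raise ValueError("train/test feature columns differ")
    scaler = StandardScaler().fit(train.X)
    clf = _make_classifier(config)
    clf.fit(scaler.transform(train.X), train.y)
    pred = clf.predict(scaler.transform(test.X))
    metrics = compute_metrics(test.y.to_numpy(), pred)
    flags = []
    if (test.y == GROUP_NORMAL).sum() == 0:
        flags.append("no_normal_in_test")
    if (test.y == GROUP_TUMOR).sum() == 0:
        flags.append("no_tumor_in_test")
    return EvalReport(
        panel=tuple(train.X.columns), cancer=test.cancer,
        n_train=len(train), n_test=len(test), seed=config.seed,
        flags=tuple(flags), **metrics,
    )


def train_eval(features: FeatureTable, config: RunConfig) -> EvalReport:
    """Stratified split of one feature table, then :func:`fit_and_score`."""
    idx_train, idx_test = train_test_split(
        features.X.index, test_size=config.test_fraction,
        stratify=features.y, random_state=config.seed,
    )
    train = FeatureTable(X=features.X.loc[idx_train], y=features.y.loc[idx_train],
                         cancer=features.cancer)
    test = FeatureTable(X=features.X.loc[idx_test], y=features.y.loc[idx_test],
                        cancer=features.cancer)
    return fit_and_score(train, test, config)


def evaluate_panel(
    matrix: BetaMatrix,
    manifest: ProbeManifest,
    panel: Sequence[str],
    config: RunConfig,
    cancer: str = "",
) -> EvalReport:
    """End-to-end, leakage-free evaluation of one panel on one cohort.

    Samples are split first (stratified by group); the representative probe,
    imputation medians and scaling are then derived from the training side
    only.
    """
    samples = matrix.sample_ids
    labels = [matrix.group_of[s] for s in samples]
    train_ids, test_ids = train_test_split(
        samples, test_size=config.test_fraction, stratify=labels,
        random_state=config.seed,
    )
    probe_choice = choose_probes(matrix, manifest, panel, samples=train_ids)
    train = extract_features(matrix, manifest, panel, probe_choice,
                             samples=train_ids, cancer=cancer,
                             feature_mode=config.feature_mode)
    medians = train.X.median().to_dict()
    test = extract_features(matrix, manifest, panel, probe_choice,
                            impute_medians=medians, samples=test_ids,
                            cancer=cancer, feature_mode=config.feature_mode)
    return fit_and_score(train, test, config)


def select_optimal(reports: Sequence[EvalReport]) -> tuple[str, ...]:
    """Pick the panel with the highest cross-cohort mean accuracy.

    Ties go to the smaller panel, then the lexicographically smallest one.
    """
    if not reports:
        raise ValueError("no reports to select from")
    by_panel: dict[tuple[str, ...], list[float]] = {}
    for rep in reports:
        by_panel.setdefault(rep.panel, []).append(rep.accuracy)
    ranked = sorted(
        by_panel.items(),
        key=lambda item: (-float(np.mean(item[1])), len(item[0]), item[0]),
    )
    return ranked[0][0]


def universal_model(
    train_tables: Mapping[str, FeatureTable],
    test_tables: Mapping[str, FeatureTable],
    config: RunConfig,
) -> dict[str, EvalReport]:
    """Train one pooled model on all training cohorts; score each held-out cohort.

    All tables must share an identical panel (feature columns).
    """
    if not train_tables or not test_tables:
        raise ValueError("need at least one training and one test table")
    panels = {tuple(t.X.columns) for t in train_tables.values()}
    panels |= {tuple(t.X.columns) for t in test_tables.values()}
    if len(panels) != 1:
        raise ValueError(f"feature columns differ across tables: {panels}")

    pooled_X = pd.concat([t.X for t in train_tables.values()])
    pooled_y = pd.concat([t.y for t in train_tables.values()])
    pooled = FeatureTable(X=pooled_X, y=pooled_y, cancer="pooled")

    out: dict[str, EvalReport] = {}
    for cancer, table in test_tables.items():
        out[cancer] = fit_and_score(pooled, table, config)
    return out


def reports_frame(reports: Sequence[EvalReport]) -> pd.DataFrame:
    """Tabulate reports: one row per (panel, cohort)."""
    rows = [
        {"panel": "+".join(r.panel), "cancer": r.cancer,
         "accuracy": r.accuracy, "recall": r.recall,
         "precision": r.precision, "f_score": r.f_score,
         "n_train": r.n_train, "n_test": r.n_test,
         "flags": ";".join(r.flags)}
        for r in reports
    ]
    return pd.DataFrame(rows)
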