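"""Probe-level differential methylation analysis.

Per probe: Tukey-fence outlier removal within each group, Δβ (mean tumor β
minus mean normal β), a two-sided Welch t-test, Benjamini–Hochberg adjustment
across probes, volcano categorization, and gene-level primary-biomarker
calling (a gene qualifies through at least one probe passing the |Δβ| and
adjusted-p thresholds).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import (
    BetaMatrix,
    GROUP_NORMAL,
    GROUP_TUMOR,
    ProbeManifest,
    REGION_PROMOTER,
    RunConfig,
)

logger = logging.getLogger("methmark")

VOLCANO_HYPER = "hyper"
VOLCANO_HYPO = "hypo"
VOLCANO_PROMOTER = "promoter"
VOLCANO_OTHER = "other"

STATUS_HYPER = "hyper"
STATUS_HYPO = "hypo"

#: Columns of the probe-record frame returned by :func:`probe_stats`.
PROBE_RECORD_COLUMNS = (
    "probe", "gene", "region", "delta_beta", "p_value", "q_value",
    "n_tumor_used", "n_normal_used", "volcano_class",
)


def iqr_filter(values, k: float = 1.5) -> tuple[np.ndarray, bool]:
    """Remove Tukey-fence outliers from a vector of β-values.

    Retains values within ``[Q1 - k·IQR, Q3 + k·IQR]`` with quartiles by
    linear interpolation; input order is preserved. Inputs with fewer than 4
    finite values are passed through unchanged and flagged.

    Returns
    -------
    retained : ndarray
        Surviving finite values, original order.
    degenerate : bool
        True when the fence was not applied (fewer than 4 finite values).
    """
    arr = np.asarray(values, dtype=float)
    finite = arr[np.isfinite(arr)]
    if finite.size < 4:
        return finite, True
    q1, q3 = np.percentile(finite, [25.0, 75.0])
    iqr = q3 - q1
    if iqr == 0.0:
        lo, hi = q1, q3  # fences collapse to the quartile point
    else:
        lo, hi = q1 - k * iqr, q3 + k * iqr
    return finite[(finite >= lo) & (finite <= hi)], False


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any((p < 0.0) | (p > 1.0)):
        raise ValueError("p-values must be finite and in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m, dtype=float)
    q[order] = q_sorted
    return q


def welch_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Welch t-test p-value with degenerate-variance handling.

    When both groups are constant the t statistic is undefined; by convention
    the p-value is 1 for identical constants and 0 otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.std(ddof=1 if a.size > 1 else 0) == 0.0 and \
       b.std(ddof=1 if b.size > 1 else 0) == 0.0:
        return 1.0 if a.mean() == b.mean() else 0.0
    with np.errstate(all="ignore"):
        p = stats.ttest_ind(a, b, equal_var=False).pvalue
    if not np.isfinite(p):
        return 1.0 if np.isclose(a.mean(), b.mean()) else 0.0
    return float(p)


def classify_volcano(delta_beta: float, region: str, config: RunConfig) -> str:
    """Volcano-plot category of a probe.

    Probes at or beyond the |Δβ| threshold are ``hyper``/``hypo`` by sign,
    except promoter-region probes which are classed ``promoter`` (promoter
    takes precedence over the color classes). Sub-threshold probes are
    ``other``.
    """
    thr = config.dmp_abs_dbeta_threshold
    if abs(delta_beta) >= thr:
        if region == REGION_PROMOTER:
            return VOLCANO_PROMOTER
        return VOLCANO_HYPER if delta_beta > 0 else VOLCANO_HYPO
    return VOLCANO_OTHER


def probe_stats(
    matrix: BetaMatrix, manifest: ProbeManifest, config: RunConfig
) -> pd.DataFrame:
    """Per-probe Δβ, Welch p-value and BH q-value after outlier removal.

    Outliers are removed per probe within each group separately. Probes where
    either group retains fewer than ``config.min_group_size_after_outliers``
    values are dropped (logged). BH adjustment runs across all surviving
    probes. Returns a DataFrame with :data:`PROBE_RECORD_COLUMNS`.
    """
    tumor = matrix.samples_in_group(GROUP_TUMOR)
    normal = matrix.samples_in_group(GROUP_NORMAL)
    if not tumor or not normal:
        raise ValueError("both tumor and normal groups must be non-empty")

    tumor_vals = matrix.values[tumor].to_numpy(dtype=float)
    normal_vals = matrix.values[normal].to_numpy(dtype=float)

    rows: list[dict] = []
    n_dropped = 0
    for i, probe in enumerate(matrix.probe_ids):
        t_kept, _ = iqr_filter(tumor_vals[i], config.iqr_k)
        n_kept, _ = iqr_filter(normal_vals[i], config.iqr_k)
        if (t_kept.size < config.min_group_size_after_outliers
                or n_kept.size < config.min_group_size_after_outliers):
            n_dropped += 1
            logger.debug("probe %s dropped: %d/%d values after outlier removal",
                         probe, t_kept.size, n_kept.size)
            continue
        rec = manifest.get(probe)
        rows.append({
            "probe": probe,
            "gene": rec.gene if rec is not None else None,
            "region": rec.region if rec is not None else "other",
            "delta_beta": float(t_kept.mean() - n_kept.mean()),
            "p_value": welch_p(t_kept, n_kept),
            "n_tumor_used": int(t_kept.size),
            "n_normal_used": int(n_kept.size),
        })
    if n_dropped:
        logger.info("dropped %d probe(s) with too few values after outlier removal",
                    n_dropped)
    if not rows:
        return pd.DataFrame(columns=list(PROBE_RECORD_COLUMNS))

    records = pd.DataFrame(rows)
    records["q_value"] = bh_adjust(records["p_value"].to_numpy())
    records["volcano_class"] = [
        classify_volcano(d, r, config)
        for d, r in zip(records["delta_beta"], records["region"])
    ]
    return records[list(PROBE_RECORD_COLUMNS)]


@dataclass(frozen=True)
class MarkerCall:
    """Gene-level call: signed Δβ of the strongest qualifying probe."""

    delta_beta: float
    status: str  # "hyper" iff delta_beta > 0, else "hypo"


@dataclass
class PrimaryMarkerSet:
    """Genes qualifying as primary methylation biomarkers for one cancer."""

    cancer: str
    calls: dict[str, MarkerCall]

    @property
    def genes(self) -> set[str]:
        return set(self.calls)

    @property
    def delta(self) -> dict[str, float]:
        return {g: c.delta_beta for g, c in self.calls.items()}


def call_primary_markers(
    records: pd.DataFrame, config: RunConfig, cancer: str = "cancer"
) -> PrimaryMarkerSet:
    """Gene-level primary-biomarker calling from probe records.

    A gene qualifies iff it has at least one probe with strictly
    ``|Δβ| > dmp_abs_dbeta_threshold`` and ``q < gene_q_threshold`` (and,
    when ``promoter_only``, the probe lies in a promoter region). The gene's
    reported Δβ is the signed Δβ of its maximum-|Δβ| qualifying probe.
    """
    if records.empty:
        return PrimaryMarkerSet(cancer=cancer, calls={})
    mask = (
        (records["delta_beta"].abs() > config.dmp_abs_dbeta_threshold)
        & (records["q_value"] < config.gene_q_threshold)
        & records["gene"].notna()
    )
    if config.promoter_only:
        mask &= records["region"] == REGION_PROMOTER
    qualifying = records.loc[mask]
    calls: dict[str, MarkerCall] = {}
    for gene, sub in qualifying.groupby("gene"):
        best = sub.loc[sub["delta_beta"].abs().idxmax()]
        d = float(best["delta_beta"])
        calls[str(gene)] = MarkerCall(
            delta_beta=d, status=STATUS_HYPER if d > 0 else STATUS_HYPO
        )
    return PrimaryMarkerSet(cancer=cancer, calls=calls)


def write_probe_records(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(path, sep="\t", index=False)


def write_primary_markers(markers: PrimaryMarkerSet, path: str | Path) -> None:
    rows = [
        {"gene": g, "delta_beta": c.delta_beta, "status": c.status}
        for g, c in sorted(markers.calls.items())
    ]
    pd.DataFrame(rows, columns=["gene", "delta_beta", "status"]).to_csv(
        path, sep="\t", index=False
    )


def volcano_plot(records: pd.DataFrame, path: str | Path, title: str = "") -> None:
    """Render a Δβ vs −log10(p) volcano plot colored by class (needs matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {
        VOLCANO_HYPER: "#90ee90",
        VOLCANO_HYPO: "#f08080",
        VOLCANO_PROMOTER: "black",
        VOLCANO_OTHER: "#dddddd",
    }
    fig, ax = plt.subplots(figsize=(6, 5))
    logp = -np.log10(np.clip(records["p_value"].to_numpy(), 1e-300, None))
    for cls, color in colors.items():
        sel = records["volcano_class"] == cls
        ax.scatter(records.loc[sel, "delta_beta"], logp[sel.to_numpy()],
                   s=8, c=color, label=cls, edgecolors="none")
    ax.set_xlabel("Δβ")
    ax.set_ylabel("−log10 p")
    ax.set_title(title)
    ax.legend(markerscale=2, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
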