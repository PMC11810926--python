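"""Secondary-marker assembly and cross-cancer common-biomarker selection.

Secondary markers are the union of a cancer's comorbidity gene sets;
candidates are the intersection of primary (methylation) and secondary
(comorbidity) markers; common biomarkers are genes that qualify as candidates
with |Δβ| above the commonality threshold in every cancer simultaneously.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from .dmp_analysis import PrimaryMarkerSet, STATUS_HYPER, STATUS_HYPO
from .io_formats import RunConfig


@dataclass
class MarkerSet:
    """A named gene set for one cancer with per-gene signed Δβ."""

    cancer: str
    provenance: str  # primary | secondary | candidate | common
    delta: dict[str, float] = field(default_factory=dict)

    @property
    def genes(self) -> set[str]:
        return set(self.delta)

    def __len__(self) -> int:
        return len(self.delta)


def secondary_markers(comorbidity_sets: Mapping[str, set[str]]) -> set[str]:
    """Union of one cancer's comorbidity gene sets."""
    if not comorbidity_sets:
        raise ValueError("at least one comorbidity gene set is required")
    out: set[str] = set()
    for genes in comorbidity_sets.values():
        out |= genes
    return out


def candidate_markers(primary: PrimaryMarkerSet, secondary: set[str]) -> MarkerSet:
    """Intersection of primary and secondary markers, keeping primary Δβ."""
    delta = {g: c.delta_beta for g, c in primary.calls.items() if g in secondary}
    return MarkerSet(cancer=primary.cancer, provenance="candidate", delta=delta)


@dataclass
class CommonMarkerTable:
    """Genes common to every cancer's candidate set at |Δβ| > threshold.

    ``delta`` is a genes × cancers DataFrame of signed Δβ; ``status`` maps
    (gene, cancer) → hyper/hypo by sign.
    """

    genes: list[str]
    delta: pd.DataFrame
    status: pd.DataFrame

    def write(self, path: str | Path) -> None:
        out = self.delta.copy()
        out.index.name = "gene"
        out.to_csv(path, sep="\t")


def common_markers(
    candidates: Mapping[str, MarkerSet], config: RunConfig
) -> CommonMarkerTable:
    """Cross-cancer common-biomarker selection.

    A gene is kept iff it appears in every cancer's candidate set with
    strictly ``|Δβ| > common_abs_dbeta_threshold`` in each. Hyper/hypo status
    is reported per cancer; sign consistency across cancers is not required.
    """
    if len(candidates) < 2:
        raise ValueError("common-marker selection needs candidates from >= 2 cancers")
    thr = config.common_abs_dbeta_threshold
    kept_per_cancer = [
        {g for g, d in ms.delta.items() if abs(d) > thr}
        for ms in candidates.values()
    ]
    common = sorted(set.intersection(*kept_per_cancer))
    cancers = sorted(candidates)
    delta = pd.DataFrame(
        {c: [candidates[c].delta[g] for g in common] for c in cancers},
        index=common,
    )
    status = delta.map(lambda d: STATUS_HYPER if d > 0 else STATUS_HYPO)
    return CommonMarkerTable(genes=common, delta=delta, status=status)
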