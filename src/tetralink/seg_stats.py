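"""Dataset-level descriptive statistics: non-Mendelian segregation tallies,
spore-viability distributions and sporulation efficiency."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .tetrad_data import (
    MISSING,
    TetradDataset,
    detect_conversions,
    segregation_label,
)

logger = logging.getLogger(__name__)

_NMS_CLASSES = ("2:2", "3:1", "1:3", "4:0", "0:4")


@dataclass
class SegregationTally:
    """Per-locus segregation class counts over four-spore-viable tetrads.

    ``per_locus[marker][cls]`` counts tetrads in which ``marker`` segregated
    ``cls`` (P1:P2).  ``total_tetrads`` is the number of tetrads considered;
    ``merged_events`` counts conversion events after merging adjacent non-2:2
    loci into single events.
    """

    per_locus: dict[str, dict[str, int]]
    total_tetrads: int
    merged_events: int

    def pct(self, marker: str, cls: str) -> float:
        return 100.0 * self.per_locus[marker][cls] / self.total_tetrads

    @property
    def total_nms_pct(self) -> float:
        """Summed per-locus percentage of non-2:2 segregation."""
        return sum(
            self.pct(m, c) for m in self.per_locus for c in _NMS_CLASSES[1:]
        )

    def fold_change_vs(self, control: "SegregationTally") -> float:
        """Total NMS percentage relative to a control tally (1.0 = identical)."""
        denom = control.total_nms_pct
        if denom <= 0:
            raise ValueError("control tally has no non-Mendelian events")
        return self.total_nms_pct / denom

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "locus": m,
                "total_tetrads": self.total_tetrads,
                "pct_3:1_1:3": self.pct(m, "3:1") + self.pct(m, "1:3"),
                "pct_4:0_0:4": self.pct(m, "4:0") + self.pct(m, "0:4"),
            }
            for m in self.per_locus
        ]
        return pd.DataFrame(rows)


def tally_segregation(dataset: TetradDataset) -> SegregationTally:
    """Tally segregation classes per locus.

    The dataset should already be restricted to four-spore-viable tetrads
    with at most two merged conversion events
    (:func:`~tetralink.tetrad_data.filter_for_conversion_analysis`).  Loci
    with a missing call in a tetrad are skipped for that tetrad.
    """
    per_locus = {
        m.name: {c: 0 for c in _NMS_CLASSES} for m in dataset.markers
    }
    merged = 0
    for tet in dataset.tetrads:
        if tet.n_viable != 4:
            raise ValueError("tally_segregation requires four-spore-viable tetrads")
        for m in dataset.markers:
            calls = [sp.call(m.name) for sp in tet.spores]
            if MISSING in calls:
                logger.warning(
                    "locus %s missing in tetrad %s; skipped", m.name, tet.tetrad_id
                )
                continue
            per_locus[m.name][segregation_label(sum(c == "P1" for c in calls))] += 1
        merged += len(detect_conversions(tet, dataset.markers))
    return SegregationTally(per_locus, len(dataset.tetrads), merged)


@dataclass(frozen=True)
class ViabilityDistribution:
    """Counts of tetrads by number of viable spores (index 0..4)."""

    counts: tuple[int, int, int, int, int]

    @property
    def total_tetrads(self) -> int:
        return sum(self.counts)

    @property
    def pct_viability(self) -> float:
        """Overall spore viability: viable spores / all spores, as percent."""
        return 100.0 * sum(k * c for k, c in enumerate(self.counts)) / (
            4 * self.total_tetrads
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "viable_spores": [4, 3, 2, 1, 0],
                "tetrads": [self.counts[k] for k in (4, 3, 2, 1, 0)],
            }
        )


def viability_distribution(dataset: TetradDataset) -> ViabilityDistribution:
    if not dataset.tetrads:
        raise ValueError("empty dataset")
    counts = [0] * 5
    for tet in dataset.tetrads:
        counts[tet.n_viable] += 1
    return ViabilityDistribution(tuple(counts))


def sporulation_efficiency(
    n_2spore: int, n_3spore: int, n_4spore: int, n_unsporulated: int
) -> float:
    """Percent of cells that formed 2-, 3- or 4-spore asci."""
    sporulated = n_2spore + n_3spore + n_4spore
    total = sporulated + n_unsporulated
    if total <= 0:
        raise ValueError("no cells counted")
    return 100.0 * sporulated / total
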