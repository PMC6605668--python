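"""Tetrad data model, file I/O, interval classification and filtering.

A tetrad is the set of four haploid spores recovered from one yeast meiosis.
Each spore is genotyped at a set of mapped heterozygous markers; calls are
recorded against the two parental haplotypes as ``P1``/``P2`` (``-`` for
missing).  For any pair of linked markers a four-spore-viable tetrad falls
into one of three classes:

* **PD** (parental ditype): two spores of each parental two-marker combination;
* **TT** (tetratype): one spore of each of the four combinations;
* **NPD** (non-parental ditype): two spores of each recombinant combination,
  requiring a four-strand double crossover.

Tetrads in which either marker fails to segregate 2:2 (gene conversion), or
in which any spore is inviable or uncalled at either marker, are unscorable
for that interval and tallied separately.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

logger = logging.getLogger(__name__)

MISSING = "-"
ALLELES = ("P1", "P2")


class TetradClass(enum.Enum):
    """Two-marker tetrad configuration."""

    PD = "PD"
    TT = "TT"
    NPD = "NPD"
    UNSCORABLE = "unscorable"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class TetradFormatError(ValueError):
    """Raised for malformed tetrad tables (wrong spore count, unknown markers)."""


@dataclass(frozen=True)
class MarkerDef:
    """A scored locus: name, chromosome, order along it, and parental phase.

    ``parental_phase`` names the allele label carried by parent 1; calls in
    tetrad tables are already expressed on the P1/P2 scale, so the default
    phase is ``"P1"``.  Mapping raw phenotype scores (drug resistance,
    auxotrophy) onto P1/P2 is the caller's responsibility.
    """

    name: str
    chromosome: str
    order_index: int
    parental_phase: str = "P1"


@dataclass(frozen=True)
class IntervalDef:
    """A genetic interval between two ordered markers on one chromosome."""

    left_marker: str
    right_marker: str
    chromosome: str

    @property
    def name(self) -> str:
        return f"{self.left_marker}-{self.right_marker}"

    def __str__(self) -> str:
        return self.name


@dataclass
class SporeGenotype:
    spore_id: str
    viable: bool
    calls: dict[str, str] = field(default_factory=dict)

    def call(self, marker: str) -> str:
        return self.calls.get(marker, MISSING)


@dataclass
class Tetrad:
    tetrad_id: str
    spores: list[SporeGenotype]

    def __post_init__(self) -> None:
        if len(self.spores) != 4:
            raise TetradFormatError(
                f"tetrad {self.tetrad_id!r} has {len(self.spores)} spores; expected 4"
            )
        ids = {s.spore_id for s in self.spores}
        if len(ids) != 4:
            raise TetradFormatError(f"tetrad {self.tetrad_id!r} has duplicate spore ids")

    @property
    def n_viable(self) -> int:
        return sum(s.viable for s in self.spores)


@dataclass
class TetradDataset:
    """A collection of tetrads genotyped against a declared marker map."""

    markers: list[MarkerDef]
    tetrads: list[Tetrad]
    strain_label: str = ""

    def __post_init__(self) -> None:
        validate_marker_map(self.markers)
        names = {m.name for m in self.markers}
        for tet in self.tetrads:
            for spore in tet.spores:
                unknown = set(spore.calls) - names
                if unknown:
                    raise TetradFormatError(
                        f"tetrad {tet.tetrad_id!r} calls undeclared marker(s) {sorted(unknown)}"
                    )

    def __len__(self) -> int:
        return len(self.tetrads)

    def marker(self, name: str) -> MarkerDef:
        for m in self.markers:
            if m.name == name:
                return m
        raise KeyError(name)

    def default_intervals(self) -> list[IntervalDef]:
        """Intervals between consecutive markers on each chromosome."""
        out: list[IntervalDef] = []
        by_chrom: dict[str, list[MarkerDef]] = {}
        for m in self.markers:
            by_chrom.setdefault(m.chromosome, []).append(m)
        for chrom, ms in by_chrom.items():
            ms = sorted(ms, key=lambda m: m.order_index)
            out.extend(
                IntervalDef(a.name, b.name, chrom) for a, b in zip(ms, ms[1:])
            )
        return out

    def to_frame(self) -> pd.DataFrame:
        names = [m.name for m in self.markers]
        rows = []
        for tet in self.tetrads:
            for sp in tet.spores:
                row = {
                    "tetrad_id": tet.tetrad_id,
                    "spore_id": sp.spore_id,
                    "viable": int(sp.viable),
                }
                row.update({n: sp.call(n) for n in names})
                rows.append(row)
        return pd.DataFrame(rows, columns=["tetrad_id", "spore_id", "viable", *names])


def validate_marker_map(markers: Sequence[MarkerDef]) -> None:
    names = [m.name for m in markers]
    if len(set(names)) != len(names):
        raise ValueError("marker names must be unique")
    by_chrom: dict[str, list[int]] = {}
    for m in markers:
        by_chrom.setdefault(m.chromosome, []).append(m.order_index)
    for chrom, idx in by_chrom.items():
        if sorted(idx) != idx or len(set(idx)) != len(idx):
            raise ValueError(
                f"order_index must be strictly increasing within chromosome {chrom!r}"
            )


# ---------------------------------------------------------------------------
# File I/O.  Tetrad TSV dialect: header
#   tetrad_id  spore_id  viable  <marker1> <marker2> ...
# one row per spore, viable in {1,0}, calls in {P1,P2,-}.
# Marker map TSV: marker  chromosome  order_index  phase
# ---------------------------------------------------------------------------


def read_marker_map(path) -> list[MarkerDef]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"marker", "chromosome", "order_index", "phase"}
    if not required.issubset(df.columns):
        raise TetradFormatError(
            f"marker map must have columns {sorted(required)}; got {list(df.columns)}"
        )
    markers = [
        MarkerDef(r.marker, r.chromosome, int(r.order_index), r.phase)
        for r in df.itertuples()
    ]
    validate_marker_map(markers)
    return markers


def write_marker_map(markers: Sequence[MarkerDef], path) -> None:
    pd.DataFrame(
        {
            "marker": [m.name for m in markers],
            "chromosome": [m.chromosome for m in markers],
            "order_index": [m.order_index for m in markers],
            "phase": [m.parental_phase for m in markers],
        }
    ).to_csv(path, sep="\t", index=False)


def read_tetrad_table(path, marker_map: Sequence[MarkerDef], strain_label: str = "") -> TetradDataset:
    """Read a tetrad TSV into a :class:`TetradDataset`.

    Raises :class:`TetradFormatError` if any tetrad does not have exactly four
    spore rows or if a marker column is not declared in ``marker_map``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    fixed = ["tetrad_id", "spore_id", "viable"]
    if list(df.columns[:3]) != fixed:
        raise TetradFormatError(f"tetrad table must start with columns {fixed}")
    declared = {m.name for m in marker_map}
    marker_cols = [c for c in df.columns[3:]]
    unknown = set(marker_cols) - declared
    if unknown:
        raise TetradFormatError(f"unknown marker column(s): {sorted(unknown)}")
    tetrads = []
    for tid, grp in df.groupby("tetrad_id", sort=False):
        if len(grp) != 4:
            raise TetradFormatError(
                f"tetrad {tid!r} has {len(grp)} spore rows; expected 4"
            )
        spores = []
        for r in grp.itertuples(index=False):
            viable = str(r.viable) == "1"
            calls = {
                c: getattr(r, c) if getattr(r, c) in ALLELES else MISSING
                for c in marker_cols
            }
            if not viable:
                calls = {c: MISSING for c in marker_cols}
            spores.append(SporeGenotype(r.spore_id, viable, calls))
        tetrads.append(Tetrad(str(tid), spores))
    return TetradDataset(list(marker_map), tetrads, strain_label=strain_label)


def write_tetrad_table(dataset: TetradDataset, path) -> None:
    dataset.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------


def classify_interval(tetrad: Tetrad, interval: IntervalDef) -> TetradClass:
    """Classify one tetrad at one interval as PD, TT, NPD or unscorable.

    Unscorable covers: any spore inviable or missing a call at either marker,
    or non-2:2 segregation (gene conversion) at either marker.  The result is
    invariant under permutation of the four spores; swapping the P1/P2 labels
    at exactly one marker exchanges PD and NPD and fixes TT.
    """
    pairs = []
    for spore in tetrad.spores:
        a = spore.call(interval.left_marker)
        b = spore.call(interval.right_marker)
        if not spore.viable or a == MISSING or b == MISSING:
            return TetradClass.UNSCORABLE
        pairs.append((a, b))
    # 2:2 segregation required at each marker
    for k in (0, 1):
        if sum(p[k] == "P1" for p in pairs) != 2:
            return TetradClass.UNSCORABLE
    parental = sum(p in (("P1", "P1"), ("P2", "P2")) for p in pairs)
    if parental == 4:
        return TetradClass.PD
    if parental == 0:
        return TetradClass.NPD
    # given 2:2 at both markers, the only remaining configuration is one spore
    # of each of the four combinations
    return TetradClass.TT


@dataclass(frozen=True)
class IntervalClassCounts:
    """PD/TT/NPD tallies for one interval.

    ``n`` is the number of scorable tetrads (PD+TT+NPD); ``unscorable``
    counts tetrads excluded for inviability, missing calls or non-2:2
    segregation at either marker.
    """

    PD: int
    TT: int
    NPD: int
    unscorable: int = 0

    def __post_init__(self) -> None:
        if min(self.PD, self.TT, self.NPD, self.unscorable) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return self.PD + self.TT + self.NPD


def tally_intervals(
    dataset: TetradDataset, intervals: Sequence[IntervalDef] | None = None
) -> dict[IntervalDef, IntervalClassCounts]:
    """Tally PD/TT/NPD/unscorable per interval over a dataset.

    Intervals referencing markers not declared in the dataset are skipped
    with a warning (some strains lack particular markers).  For every tallied
    interval, PD+TT+NPD+unscorable equals the number of tetrads.
    """
    if intervals is None:
        intervals = dataset.default_intervals()
    declared = {m.name for m in dataset.markers}
    out: dict[IntervalDef, IntervalClassCounts] = {}
    for iv in intervals:
        if iv.left_marker not in declared or iv.right_marker not in declared:
            logger.warning(
                "interval %s skipped: marker not declared in strain %r",
                iv, dataset.strain_label,
            )
            continue
        counts = {c: 0 for c in TetradClass}
        for tet in dataset.tetrads:
            counts[classify_interval(tet, iv)] += 1
        out[iv] = IntervalClassCounts(
            PD=counts[TetradClass.PD],
            TT=counts[TetradClass.TT],
            NPD=counts[TetradClass.NPD],
            unscorable=counts[TetradClass.UNSCORABLE],
        )
    return out


# ---------------------------------------------------------------------------
# Gene conversion (non-Mendelian segregation)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConversionEvent:
    """One merged gene-conversion event.

    ``markers`` lists the non-2:2 loci involved, in map order; ``labels``
    gives the segregation class per locus (``3:1``, ``1:3``, ``4:0``, ``0:4``,
    counted as P1:P2).  Runs of adjacent non-2:2 loci on a chromosome are a
    single event.
    """

    chromosome: str
    markers: tuple[str, ...]
    labels: tuple[str, ...]

    @property
    def label(self) -> str:
        return self.labels[0]


def segregation_label(p1_count: int) -> str:
    return {0: "0:4", 1: "1:3", 2: "2:2", 3: "3:1", 4: "4:0"}[p1_count]


def detect_conversions(tetrad: Tetrad, markers: Sequence[MarkerDef]) -> list[ConversionEvent]:
    """Find merged non-2:2 segregation events in a four-spore-viable tetrad.

    Adjacency is defined by consecutive ``order_index`` on the same
    chromosome; a maximal run of adjacent non-2:2 loci is one event.  Loci
    with any missing call among the four viable spores are skipped.
    """
    if tetrad.n_viable != 4:
        raise ValueError(
            f"tetrad {tetrad.tetrad_id!r} has {tetrad.n_viable} viable spores; "
            "conversion detection requires 4 (filter first)"
        )
    by_chrom: dict[str, list[MarkerDef]] = {}
    for m in markers:
        by_chrom.setdefault(m.chromosome, []).append(m)
    events: list[ConversionEvent] = []
    for chrom, ms in by_chrom.items():
        ms = sorted(ms, key=lambda m: m.order_index)
        run_markers: list[str] = []
        run_labels: list[str] = []

        def flush() -> None:
            if run_markers:
                events.append(
                    ConversionEvent(chrom, tuple(run_markers), tuple(run_labels))
                )
                run_markers.clear()
                run_labels.clear()

        for m in ms:
            calls = [sp.call(m.name) for sp in tetrad.spores]
            if MISSING in calls:
                flush()
                continue
            p1 = sum(c == "P1" for c in calls)
            if p1 == 2:
                flush()
            else:
                run_markers.append(m.name)
                run_labels.append(segregation_label(p1))
        flush()
    return events


def filter_for_conversion_analysis(
    dataset: TetradDataset, max_events: int = 2
) -> TetradDataset:
    """Retain four-spore-viable tetrads with at most ``max_events`` merged
    conversion events."""
    kept = [
        tet
        for tet in dataset.tetrads
        if tet.n_viable == 4
        and len(detect_conversions(tet, dataset.markers)) <= max_events
    ]
    return TetradDataset(list(dataset.markers), kept, strain_label=dataset.strain_label)
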