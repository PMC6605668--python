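"""Meiosis simulator: gamma-renewal crossover interference, gene conversion
and spore viability, emitting tetrad datasets in the package's TSV dialect.

Crossovers on a bivalent (four-chromatid bundle) are placed by a stationary
renewal process on genetic distance whose inter-event gaps are
Gamma-distributed with integer shape ``m + 1`` and mean ``1/(2*(m+1))``
Morgans, so events occur at rate 2 per Morgan on the bivalent and each
chromatid's expected recombination equals the map length.  ``m = 0`` reduces
exactly to a homogeneous Poisson process; larger ``m`` yields under-dispersed
counts — positive crossover interference, visible in the data as observed/
expected NPD ratios below 1.  By default the first event is drawn from the
renewal process's equilibrium (length-biased residual) distribution so the
process is stationary along the chromosome; an origin-anchored start is
available for comparison.  Each crossover involves one chromatid from each
homolog, chosen uniformly and independently (no chromatid interference), and
exchanges all marker content distal to the crossover position.

Gene conversion is applied marker-locally and independently of crossover
placement: each locus converts with probability ``conversion_rate`` per
meiosis, to a class drawn from ``conversion_mix`` (3:1, 1:3, 4:0, 0:4 as
P1:P2).  Each spore is then independently inviable with probability
``1 - spore_viability``, blanking its calls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import yaml

from .tetrad_data import (
    MISSING,
    MarkerDef,
    SporeGenotype,
    Tetrad,
    TetradDataset,
)

CONVERSION_CLASSES = ("3:1", "1:3", "4:0", "0:4")

# Wild-type study conditions: the seven intervals of chromosomes III and VIII
# at their wild-type tetrad map lengths (cM), scored in ~675 tetrads.
WILD_TYPE_CHROMOSOMES = (
    ("III", ("HIS4", "CEN3", "MAT", "RAD18", "HMR"), (26.7, 20.1, 36.3, 22.9)),
    ("VIII", ("SPO11", "SPO13", "THR1", "LYS2"), (39.2, 7.6, 29.5)),
)


@dataclass(frozen=True)
class ChromosomeConfig:
    """One simulated chromosome: ordered markers and interval lengths."""

    name: str
    markers: tuple[str, ...]
    interval_lengths_M: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.markers) < 2:
            raise ValueError("a chromosome needs at least two markers")
        if len(self.interval_lengths_M) != len(self.markers) - 1:
            raise ValueError("need one interval length per adjacent marker pair")
        if any(x < 0 for x in self.interval_lengths_M):
            raise ValueError("interval lengths must be non-negative")

    @property
    def marker_positions_M(self) -> tuple[float, ...]:
        pos = [0.0]
        for x in self.interval_lengths_M:
            pos.append(pos[-1] + x)
        return tuple(pos)

    @property
    def length_M(self) -> float:
        return sum(self.interval_lengths_M)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for a simulated cross.

    Defaults emulate a wild-type BR1919-background strain scored at the nine
    loci of chromosomes III and VIII: wild-type interval lengths, 675 tetrads,
    strong interference (m=4), 98% spore viability and a 1% per-locus
    gene-conversion rate dominated by 3:1/1:3 events.
    """

    chromosomes: tuple[ChromosomeConfig, ...] = tuple(
        ChromosomeConfig(name, markers, tuple(x / 100.0 for x in lengths))
        for name, markers, lengths in WILD_TYPE_CHROMOSOMES
    )
    interference_m: int = 4
    n_tetrads: int = 675
    spore_viability: float = 0.98
    conversion_rate: float = 0.01
    conversion_mix: tuple[float, float, float, float] = (0.475, 0.475, 0.025, 0.025)
    renewal_start: str = "stationary"  # or "origin"
    seed: int = 0
    strain_label: str = "simulated"

    def __post_init__(self) -> None:
        if self.interference_m < 0:
            raise ValueError("interference_m must be >= 0")
        if self.n_tetrads <= 0:
            raise ValueError("n_tetrads must be positive")
        for p, name in (
            (self.spore_viability, "spore_viability"),
            (self.conversion_rate, "conversion_rate"),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if len(self.conversion_mix) != 4 or any(p < 0 for p in self.conversion_mix):
            raise ValueError("conversion_mix must be four non-negative proportions")
        if not math.isclose(sum(self.conversion_mix), 1.0, abs_tol=1e-9):
            raise ValueError("conversion_mix must sum to 1")
        if self.renewal_start not in ("stationary", "origin"):
            raise ValueError("renewal_start must be 'stationary' or 'origin'")
        if not self.chromosomes:
            raise ValueError("at least one chromosome required")

    def marker_map(self) -> list[MarkerDef]:
        out = []
        for chrom in self.chromosomes:
            out.extend(
                MarkerDef(name, chrom.name, i + 1)
                for i, name in enumerate(chrom.markers)
            )
        return out


def load_config(path) -> SimulationConfig:
    """Read a simulation config from a YAML file.

    Chromosome interval lengths are given in cM under ``interval_cM``::

        seed: 1
        n_tetrads: 675
        interference_m: 4
        chromosomes:
          - name: III
            markers: [HIS4, CEN3, MAT, RAD18, HMR]
            interval_cM: [26.7, 20.1, 36.3, 22.9]
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    kwargs = {}
    if "chromosomes" in raw:
        kwargs["chromosomes"] = tuple(
            ChromosomeConfig(
                str(c["name"]),
                tuple(str(m) for m in c["markers"]),
                tuple(float(x) / 100.0 for x in c["interval_cM"]),
            )
            for c in raw.pop("chromosomes")
        )
    if "conversion_mix" in raw:
        kwargs["conversion_mix"] = tuple(float(x) for x in raw.pop("conversion_mix"))
    for key in (
        "interference_m",
        "n_tetrads",
        "spore_viability",
        "conversion_rate",
        "renewal_start",
        "seed",
        "strain_label",
    ):
        if key in raw:
            kwargs[key] = raw.pop(key)
    if raw:
        raise ValueError(f"unknown config keys: {sorted(raw)}")
    return SimulationConfig(**kwargs)


@dataclass(frozen=True)
class ChiasmaRealization:
    """Crossovers on one bivalent: genetic positions (Morgans) and, per
    crossover, the pair of non-sister chromatids involved (one of 0/1 from
    homolog 1, one of 2/3 from homolog 2)."""

    positions: tuple[float, ...]
    chromatids: tuple[tuple[int, int], ...]


def draw_crossovers(
    length_M: float,
    m: int,
    rng: np.random.Generator,
    *,
    start: str = "stationary",
) -> list[float]:
    """Draw crossover positions on a bivalent of the given genetic length.

    Stationary gamma-renewal process with shape ``m + 1`` and event rate 2
    per Morgan (so the expected count per bivalent is ``2 * length_M`` and the
    expected recombination per chromatid equals ``length_M``).
    """
    if length_M < 0:
        raise ValueError("length must be non-negative")
    if length_M == 0:
        return []
    shape = m + 1
    scale = 1.0 / (2.0 * shape)  # mean gap 1/(2(m+1)) Morgans
    positions: list[float] = []
    if start == "stationary":
        # Equilibrium forward-recurrence time for an Erlang(shape) renewal
        # process: a uniform mixture of Gamma(j, scale) over j = 1..shape.
        j = int(rng.integers(1, shape + 1))
        x = rng.gamma(j, scale)
    elif start == "origin":
        x = rng.gamma(shape, scale)
    else:
        raise ValueError("start must be 'stationary' or 'origin'")
    while x <= length_M:
        positions.append(float(x))
        x += rng.gamma(shape, scale)
    return positions


def draw_realization(
    length_M: float,
    m: int,
    rng: np.random.Generator,
    *,
    start: str = "stationary",
) -> ChiasmaRealization:
    positions = draw_crossovers(length_M, m, rng, start=start)
    chromatids = tuple(
        (int(rng.integers(0, 2)), int(rng.integers(2, 4))) for _ in positions
    )
    return ChiasmaRealization(tuple(positions), chromatids)


def make_tetrad(
    realizations: dict[str, ChiasmaRealization],
    config: SimulationConfig,
    tetrad_id: str,
) -> Tetrad:
    """Resolve chiasma realizations into a four-spore tetrad.

    Crossover chromatid labels refer to the four positions (slots) in the
    pachytene bundle: slots 0/1 belong to homolog 1 (P1), slots 2/3 to
    homolog 2 (P2).  A gamete is assembled by following its centromere's slot
    rightward and jumping to the partner slot at every crossover involving
    the slot it currently occupies, so each interval's tetrad class depends
    only on the crossovers inside it (e.g. exactly one crossover in an
    interval always yields a tetratype there).
    """
    spore_ids = ("a", "b", "c", "d")
    calls: list[dict[str, str]] = [{} for _ in range(4)]
    for chrom in config.chromosomes:
        real = realizations[chrom.name]
        events = sorted(zip(real.positions, real.chromatids))
        # occupant[slot] = index of the gamete whose molecule currently runs
        # through that slot of the bundle
        occupant = [0, 1, 2, 3]
        k = 0
        markers = list(zip(chrom.markers, chrom.marker_positions_M))
        for x, (ci, cj) in events:
            while k < len(markers) and markers[k][1] <= x:
                name, _ = markers[k]
                for slot in range(4):
                    calls[occupant[slot]][name] = "P2" if slot >= 2 else "P1"
                k += 1
            occupant[ci], occupant[cj] = occupant[cj], occupant[ci]
        for name, _ in markers[k:]:
            for slot in range(4):
                calls[occupant[slot]][name] = "P2" if slot >= 2 else "P1"
    spores = [
        SporeGenotype(f"{tetrad_id}{sid}", True, calls[s])
        for s, sid in enumerate(spore_ids)
    ]
    return Tetrad(tetrad_id, spores)


def apply_conversion_and_viability(
    tetrad: Tetrad, config: SimulationConfig, rng: np.random.Generator
) -> Tetrad:
    """Overlay gene conversion and spore inviability on a clean tetrad."""
    marker_names = [m for chrom in config.chromosomes for m in chrom.markers]
    for name in marker_names:
        if config.conversion_rate == 0.0 or rng.random() >= config.conversion_rate:
            continue
        cls = CONVERSION_CLASSES[
            rng.choice(4, p=np.asarray(config.conversion_mix, dtype=float))
        ]
        donor = "P1" if cls in ("3:1", "4:0") else "P2"
        recipient = "P2" if donor == "P1" else "P1"
        targets = [sp for sp in tetrad.spores if sp.calls.get(name) == recipient]
        if cls in ("3:1", "1:3"):
            targets = [targets[int(rng.integers(0, len(targets)))]] if targets else []
        for sp in targets:
            sp.calls[name] = donor
    for sp in tetrad.spores:
        if rng.random() >= config.spore_viability:
            sp.viable = False
            sp.calls = {k: MISSING for k in sp.calls}
    return tetrad


def simulate_dataset(config: SimulationConfig) -> TetradDataset:
    """Simulate a full tetrad dataset; deterministic for a fixed seed."""
    rng = np.random.default_rng(config.seed)
    width = max(4, len(str(config.n_tetrads)))
    tetrads = []
    for i in range(config.n_tetrads):
        tid = f"t{i + 1:0{width}d}"
        realizations = {
            chrom.name: draw_realization(
                chrom.length_M,
                config.interference_m,
                rng,
                start=config.renewal_start,
            )
            for chrom in config.chromosomes
        }
        tet = make_tetrad(realizations, config, tid)
        tet = apply_conversion_and_viability(tet, config, rng)
        tetrads.append(tet)
    return TetradDataset(
        config.marker_map(), tetrads, strain_label=config.strain_label
    )
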