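"""Model/results objects for tetrad and random-spore linkage analysis.

:class:`TetradLinkage` is built either from a raw :class:`TetradDataset`
(tetrads are classified and tallied per interval) or directly from a table of
PD/TT/NPD counts; its :meth:`~TetradLinkage.fit` returns a
:class:`TetradLinkageResults` carrying Perkins map distances with delta-method
standard errors, Papazian expected-NPD interference ratios, chromosome totals
and a ``summary()`` table.  :class:`RandomSporeAnalysis` does the same for
pooled-spore recombinant counts.  Simulation (parametric regeneration of
tetrad data at the fitted map lengths) and plotting hang off the results.

Reporting conventions follow the field's spreadsheet practice: cM and SE are
displayed to one decimal, NPD ratios to two, percents of control as integers
(halves rounded away from zero).  Tetrad chromosome totals and all
percent-of-control values are computed from the display-rounded inputs;
random-spore totals from the unrounded percents.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import map_stats
from .map_stats import round_half_away
from .tetrad_data import (
    IntervalClassCounts,
    IntervalDef,
    TetradDataset,
    tally_intervals,
)

ND = "n.d."


def _fmt(x: float | None, ndigits: int) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return ND
    return f"{round_half_away(x, ndigits):.{ndigits}f}"


class TetradLinkage:
    """Tetrad-based linkage model for a set of marker intervals.

    Parameters
    ----------
    dataset
        Raw per-spore tetrad data; classified with
        :func:`~tetralink.tetrad_data.tally_intervals`.
    intervals
        Intervals to score; defaults to consecutive marker pairs.
    counts
        Alternatively, a precomputed mapping of interval -> class counts
        (used by :meth:`from_counts` for published tallies).
    """

    def __init__(
        self,
        dataset: TetradDataset | None = None,
        intervals: Sequence[IntervalDef] | None = None,
        *,
        counts: Mapping[IntervalDef, IntervalClassCounts] | None = None,
        strain_label: str = "",
    ):
        if (dataset is None) == (counts is None):
            raise ValueError("provide exactly one of dataset or counts")
        self.dataset = dataset
        self.strain_label = strain_label or (dataset.strain_label if dataset else "")
        if counts is not None:
            self._counts = dict(counts)
        else:
            self._counts = tally_intervals(dataset, intervals)
        if not self._counts:
            raise ValueError("no scorable intervals")

    @classmethod
    def from_counts(cls, table: pd.DataFrame, strain_label: str = "") -> "TetradLinkage":
        """Build from a DataFrame with columns interval, chromosome, PD, TT,
        NPD (interval names "LEFT-RIGHT")."""
        counts = {}
        for row in table.itertuples(index=False):
            left, _, right = row.interval.partition("-")
            iv = IntervalDef(left, right, str(row.chromosome))
            counts[iv] = IntervalClassCounts(int(row.PD), int(row.TT), int(row.NPD))
        return cls(counts=counts, strain_label=strain_label)

    def fit(self) -> "TetradLinkageResults":
        rows = []
        for iv, c in self._counts.items():
            ratio = map_stats.npd_ratio(c)
            expected = map_stats.papazian_expected_npd(c)
            rows.append(
                {
                    "interval": iv.name,
                    "chromosome": iv.chromosome,
                    "PD": c.PD,
                    "TT": c.TT,
                    "NPD": c.NPD,
                    "total": c.n,
                    "unscorable": c.unscorable,
                    "cM": map_stats.perkins_cM(c),
                    "se_cM": map_stats.perkins_se(c),
                    "npd_expected": expected[1] if expected else np.nan,
                    "npd_ratio": ratio[0] if ratio else np.nan,
                    "npd_ratio_se": ratio[1] if ratio else np.nan,
                }
            )
        return TetradLinkageResults(self, pd.DataFrame(rows))


@dataclass
class TetradLinkageResults:
    model: TetradLinkage
    estimates: pd.DataFrame

    @property
    def intervals(self) -> list[IntervalDef]:
        return list(self.model._counts)

    def interval_cM(self) -> dict[IntervalDef, float]:
        return dict(zip(self.intervals, self.estimates["cM"]))

    def chromosome_totals(self) -> pd.Series:
        """Per-chromosome map length: sum of display-rounded interval cM."""
        values = self.interval_cM()
        chroms = list(dict.fromkeys(iv.chromosome for iv in values))
        return pd.Series(
            {
                ch: map_stats.chromosome_sum(values, ch, round_inputs_to=1).cM_total
                for ch in chroms
            },
            name="cM_by_chromosome",
        )

    def total_cM(self) -> float:
        """Map length summed over every scored interval (display-rounded)."""
        return float(
            sum(round_half_away(x, 1) for x in self.estimates["cM"])
        )

    def percent_of(self, control: "TetradLinkageResults") -> float:
        """Summed map distance as an integer percent of a control strain.

        Both sums run over the intervals scored in *both* strains (strains
        missing markers are compared on their shared intervals only) and use
        display-rounded interval values.
        """
        shared = {iv.name for iv in self.intervals} & {
            iv.name for iv in control.intervals
        }

        def total(res: "TetradLinkageResults") -> float:
            return sum(
                round_half_away(cm, 1)
                for iv, cm in res.interval_cM().items()
                if iv.name in shared
            )

        pct = map_stats.normalize_to_control(total(self), total(control))
        return round_half_away(pct, 0)

    def relative_to(self, control: "TetradLinkageResults") -> pd.DataFrame:
        """Estimates table with integer percent-of-control columns added.

        Intervals absent from the control are dropped with NaN percent.
        """
        ctrl = {
            iv.name: round_half_away(cm, 1)
            for iv, cm in control.interval_cM().items()
        }
        df = self.estimates.copy()
        df["pct_control"] = [
            round_half_away(
                map_stats.normalize_to_control(round_half_away(cm, 1), ctrl[name]), 0
            )
            if name in ctrl
            else np.nan
            for name, cm in zip(df["interval"], df["cM"])
        ]
        own_totals = self.chromosome_totals()
        ctrl_totals = control.chromosome_totals()
        df["cM_by_chrm"] = [own_totals[ch] for ch in df["chromosome"]]
        df["pct_control_by_chrm"] = [
            round_half_away(
                map_stats.normalize_to_control(own_totals[ch], ctrl_totals[ch]), 0
            )
            if ch in ctrl_totals
            else np.nan
            for ch in df["chromosome"]
        ]
        return df

    def report(self, control: "TetradLinkageResults" | None = None) -> pd.DataFrame:
        """Display-rounded report table (strings; ``n.d.`` where undefined)."""
        df = self.relative_to(control) if control is not None else self.estimates.copy()
        out = pd.DataFrame(
            {
                "interval": df["interval"],
                "chromosome": df["chromosome"],
                "PD": df["PD"],
                "TT": df["TT"],
                "NPD": df["NPD"],
                "total": df["total"],
                "cM": [_fmt(x, 1) for x in df["cM"]],
                "se": [_fmt(x, 1) for x in df["se_cM"]],
            }
        )
        if control is not None:
            out["pct_control"] = [_fmt(x, 0) for x in df["pct_control"]]
            out["cM_by_chrm"] = [_fmt(x, 1) for x in df["cM_by_chrm"]]
            out["pct_control_by_chrm"] = [
                _fmt(x, 0) for x in df["pct_control_by_chrm"]
            ]
        out["npd_ratio"] = [
            _fmt(x, 2) if not math.isnan(x) else ND for x in df["npd_ratio"]
        ]
        out["npd_ratio_se"] = [
            _fmt(x, 2) if not math.isnan(x) else ND for x in df["npd_ratio_se"]
        ]
        return out

    def summary(self, control: "TetradLinkageResults" | None = None) -> str:
        label = self.model.strain_label or "tetrad linkage"
        lines = [
            f"Tetrad linkage analysis: {label}",
            f"intervals: {len(self.estimates)}   "
            f"tetrads scored per interval (median): "
            f"{int(self.estimates['total'].median())}",
            "",
            self.report(control).to_string(index=False),
            "",
            "chromosome totals (cM): "
            + ", ".join(f"{ch}: {v:.1f}" for ch, v in self.chromosome_totals().items()),
        ]
        return "\n".join(lines)

    def to_tsv(self, path, control: "TetradLinkageResults" | None = None) -> None:
        self.report(control).to_csv(path, sep="\t", index=False)

    def simulate(
        self,
        n_tetrads: int | None = None,
        *,
        interference_m: int = 4,
        seed: int = 0,
        **kwargs,
    ) -> TetradDataset:
        """Simulate a tetrad dataset at the fitted map lengths.

        Interval order within each chromosome follows the fitted table, so
        this is meaningful when the scored intervals are the consecutive-
        marker intervals of the map.
        """
        from .meiosis_sim import ChromosomeConfig, SimulationConfig, simulate_dataset

        chroms: dict[str, list[IntervalDef]] = {}
        for iv in self.intervals:
            chroms.setdefault(iv.chromosome, []).append(iv)
        cM = {iv: x for iv, x in zip(self.intervals, self.estimates["cM"])}
        configs = []
        for name, ivs in chroms.items():
            markers = [ivs[0].left_marker] + [iv.right_marker for iv in ivs]
            configs.append(
                ChromosomeConfig(
                    name, tuple(markers), tuple(cM[iv] / 100.0 for iv in ivs)
                )
            )
        config = SimulationConfig(
            chromosomes=tuple(configs),
            interference_m=interference_m,
            n_tetrads=n_tetrads or int(self.estimates["total"].max()),
            seed=seed,
            strain_label=f"simulated:{self.model.strain_label}",
            **kwargs,
        )
        return simulate_dataset(config)

    def plot(self, ax=None, control: "TetradLinkageResults" | None = None):
        """Bar chart of interval map distances with SE bars."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        df = self.estimates
        x = np.arange(len(df))
        ax.bar(x, df["cM"], yerr=df["se_cM"], capsize=3, label=self.model.strain_label)
        if control is not None:
            ctrl = control.estimates.set_index("interval")["cM"]
            ax.plot(
                x,
                [ctrl.get(iv, np.nan) for iv in df["interval"]],
                "k_",
                markersize=14,
                label=control.model.strain_label or "control",
            )
        ax.set_xticks(x, df["interval"], rotation=45, ha="right")
        ax.set_ylabel("map distance (cM)")
        ax.legend()
        return ax


class RandomSporeAnalysis:
    """Recombinant-fraction model for pooled random spores.

    Built from a DataFrame with columns ``interval``, ``chromosome``, ``r``
    (recombinant colonies) and ``t`` (total viable colonies assessed).
    """

    def __init__(self, table: pd.DataFrame, strain_label: str = ""):
        if table.empty:
            raise ValueError("empty random-spore table")
        required = {"interval", "chromosome", "r", "t"}
        if not required.issubset(table.columns):
            raise ValueError(f"random-spore table needs columns {sorted(required)}")
        bad = table[(table["r"] > table["t"]) | (table["t"] <= 0) | (table["r"] < 0)]
        if not bad.empty:
            raise ValueError(
                f"invalid counts for interval(s) {list(bad['interval'])}"
            )
        self.table = table.reset_index(drop=True)
        self.strain_label = strain_label

    def fit(self) -> "RandomSporeResults":
        est = [
            map_stats.random_spore_pct(int(r), int(t))
            for r, t in zip(self.table["r"], self.table["t"])
        ]
        df = self.table.copy()
        df["pct_recombinant"] = [e.pct_recombinant for e in est]
        df["se_pct"] = [e.se_pct for e in est]
        return RandomSporeResults(self, df)


@dataclass
class RandomSporeResults:
    model: RandomSporeAnalysis
    estimates: pd.DataFrame

    def chromosome_totals(self) -> pd.Series:
        """Per-chromosome sum of unrounded recombinant percents."""
        df = self.estimates
        ivs = {
            IntervalDef(*name.partition("-")[::2], chrom): pct
            for name, chrom, pct in zip(
                df["interval"], df["chromosome"], df["pct_recombinant"]
            )
        }
        chroms = list(dict.fromkeys(df["chromosome"]))
        return pd.Series(
            {
                ch: round_half_away(
                    map_stats.chromosome_sum(ivs, ch, round_inputs_to=None).cM_total, 1
                )
                for ch in chroms
            },
            name="pct_by_chromosome",
        )

    def total_pct(self) -> float:
        return float(sum(round_half_away(x, 1) for x in self.estimates["pct_recombinant"]))

    def relative_to(self, control: "RandomSporeResults") -> pd.DataFrame:
        ctrl = {
            iv: round_half_away(p, 1)
            for iv, p in zip(
                control.estimates["interval"], control.estimates["pct_recombinant"]
            )
        }
        df = self.estimates.copy()
        df["pct_control"] = [
            round_half_away(
                map_stats.normalize_to_control(round_half_away(p, 1), ctrl[iv]), 0
            )
            if iv in ctrl
            else np.nan
            for iv, p in zip(df["interval"], df["pct_recombinant"])
        ]
        own = self.chromosome_totals()
        ctrl_totals = control.chromosome_totals()
        df["pct_by_chrm"] = [own[ch] for ch in df["chromosome"]]
        df["pct_control_by_chrm"] = [
            round_half_away(map_stats.normalize_to_control(own[ch], ctrl_totals[ch]), 0)
            if ch in ctrl_totals
            else np.nan
            for ch in df["chromosome"]
        ]
        return df

    def report(self, control: "RandomSporeResults" | None = None) -> pd.DataFrame:
        df = self.relative_to(control) if control is not None else self.estimates.copy()
        out = pd.DataFrame(
            {
                "interval": df["interval"],
                "chromosome": df["chromosome"],
                "r": df["r"],
                "t": df["t"],
                "pct_recombinant": [_fmt(x, 1) for x in df["pct_recombinant"]],
                "se": [_fmt(x, 1) for x in df["se_pct"]],
            }
        )
        if control is not None:
            out["pct_control"] = [_fmt(x, 0) for x in df["pct_control"]]
            out["pct_by_chrm"] = [_fmt(x, 1) for x in df["pct_by_chrm"]]
            out["pct_control_by_chrm"] = [
                _fmt(x, 0) for x in df["pct_control_by_chrm"]
            ]
        return out

    def summary(self, control: "RandomSporeResults" | None = None) -> str:
        label = self.model.strain_label or "random spore analysis"
        return "\n".join(
            [
                f"Random-spore recombination analysis: {label}",
                "",
                self.report(control).to_string(index=False),
                "",
                "chromosome totals (% recombinant): "
                + ", ".join(
                    f"{ch}: {v:.1f}" for ch, v in self.chromosome_totals().items()
                ),
            ]
        )

    def to_tsv(self, path, control: "RandomSporeResults" | None = None) -> None:
        self.report(control).to_csv(path, sep="\t", index=False)
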