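"""Bundled example data: interval count tables from a published yeast
*zip1*/*pch2* crossover-recombination study on chromosomes III and VIII.

The tables hold raw PD/TT/NPD tetrad tallies and random-spore recombinant
counts per interval for wild-type and mutant strains; all map statistics are
recomputed from them at run time.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

WILD_TYPE_STRAIN = "K842"
PCH2_CONTROL_STRAIN = "AM3724"

MARKER_ORDER = {
    "III": ("HIS4", "CEN3", "MAT", "RAD18", "HMR"),
    "VIII": ("SPO11", "SPO13", "THR1", "LYS2"),
}


def _read(name: str) -> pd.DataFrame:
    with resources.files("tetralink.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_tetrad_counts() -> pd.DataFrame:
    """Per-interval PD/TT/NPD tallies for every strain of the study.

    Columns: background (PCH2 or pch2), strain, genotype, interval,
    chromosome, PD, TT, NPD.
    """
    return _read("tetrad_counts.tsv")


def load_random_spore_counts() -> pd.DataFrame:
    """Per-interval random-spore counts (r recombinant of t viable colonies)
    for the pch2-background strains."""
    return _read("random_spore.tsv")
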