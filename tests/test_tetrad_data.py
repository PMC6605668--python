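"""Tetrad data model: classification, tallying, conversion detection, I/O."""

import itertools

import pytest
from hypothesis import given
from hypothesis import strategies as st

from tetralink.tetrad_data import (
    IntervalClassCounts,
    IntervalDef,
    MarkerDef,
    SporeGenotype,
    Tetrad,
    TetradClass,
    TetradDataset,
    TetradFormatError,
    classify_interval,
    detect_conversions,
    filter_for_conversion_analysis,
    read_marker_map,
    read_tetrad_table,
    tally_intervals,
    write_marker_map,
    write_tetrad_table,
)

from conftest import make_tetrad

IV = IntervalDef("HIS4", "CEN3", "III")

PD_SPORES = [("P1", "P1"), ("P1", "P1"), ("P2", "P2"), ("P2", "P2")]
TT_SPORES = [("P1", "P1"), ("P2", "P2"), ("P1", "P2"), ("P2", "P1")]
NPD_SPORES = [("P1", "P2"), ("P1", "P2"), ("P2", "P1"), ("P2", "P1")]


@pytest.mark.parametrize(
    "spores, expected",
    [
        (PD_SPORES, TetradClass.PD),
        (TT_SPORES, TetradClass.TT),
        (NPD_SPORES, TetradClass.NPD),
        # 3:1 gene conversion at the left marker -> unscorable
        ([("P1", "P1"), ("P1", "P1"), ("P1", "P2"), ("P2", "P2")], TetradClass.UNSCORABLE),
        # missing call -> unscorable
        ([("P1", "P1"), ("-", "P1"), ("P2", "P2"), ("P2", "P2")], TetradClass.UNSCORABLE),
    ],
)
def test_two_marker_classification(spores, expected):
    assert classify_interval(make_tetrad("t1", spores), IV) is expected


def test_inviable_spore_makes_interval_unscorable():
    tet = make_tetrad("t1", PD_SPORES, viable=[True, True, True, False])
    assert classify_interval(tet, IV) is TetradClass.UNSCORABLE


@given(perm=st.permutations(range(4)), spores=st.sampled_from([PD_SPORES, TT_SPORES, NPD_SPORES]))
def test_classification_invariant_under_spore_permutation(perm, spores):
    base = classify_interval(make_tetrad("t1", spores), IV)
    shuffled = make_tetrad("t1", [spores[i] for i in perm])
    assert classify_interval(shuffled, IV) is base


@given(spores=st.sampled_from([PD_SPORES, TT_SPORES, NPD_SPORES]))
def test_label_swap_symmetry(spores):
    """Swapping P1/P2 at both markers fixes the class; at one marker it
    exchanges PD and NPD and fixes TT."""
    flip = {"P1": "P2", "P2": "P1"}
    base = classify_interval(make_tetrad("t1", spores), IV)
    both = [(flip[a], flip[b]) for a, b in spores]
    assert classify_interval(make_tetrad("t1", both), IV) is base
    one = [(flip[a], b) for a, b in spores]
    swapped = classify_interval(make_tetrad("t1", one), IV)
    exchange = {TetradClass.PD: TetradClass.NPD, TetradClass.NPD: TetradClass.PD,
                TetradClass.TT: TetradClass.TT}
    assert swapped is exchange[base]


def test_tally_conserves_tetrad_count(chr3_markers):
    tetrads = [
        make_tetrad("t1", PD_SPORES),
        make_tetrad("t2", TT_SPORES),
        make_tetrad("t3", NPD_SPORES),
        make_tetrad("t4", PD_SPORES, viable=[True, False, True, True]),
    ]
    ds = TetradDataset(chr3_markers, tetrads)
    counts = tally_intervals(ds, [IV])[IV]
    assert (counts.PD, counts.TT, counts.NPD, counts.unscorable) == (1, 1, 1, 1)
    assert counts.n + counts.unscorable == len(ds)


def test_tally_brute_force_equivalence(chr3_markers):
    """Interval tallies equal an explicit per-tetrad classification loop."""
    from tetralink.meiosis_sim import SimulationConfig, ChromosomeConfig, simulate_dataset

    cfg = SimulationConfig(
        chromosomes=(ChromosomeConfig("III", ("HIS4", "CEN3", "MAT"), (0.2, 0.3)),),
        interference_m=0, n_tetrads=300, spore_viability=0.9,
        conversion_rate=0.05, seed=11,
    )
    ds = simulate_dataset(cfg)
    tallies = tally_intervals(ds)
    for iv, c in tallies.items():
        loop = {cls: 0 for cls in TetradClass}
        for tet in ds.tetrads:
            loop[classify_interval(tet, iv)] += 1
        assert (c.PD, c.TT, c.NPD, c.unscorable) == (
            loop[TetradClass.PD], loop[TetradClass.TT],
            loop[TetradClass.NPD], loop[TetradClass.UNSCORABLE],
        )


def test_tally_skips_undeclared_marker_intervals(chr3_markers):
    ds = TetradDataset(chr3_markers, [make_tetrad("t1", PD_SPORES)])
    missing = IntervalDef("THR1", "LYS2", "VIII")
    assert tally_intervals(ds, [IV, missing]) == tally_intervals(ds, [IV])


def test_zero_map_length_gives_only_parental_ditypes():
    from tetralink.meiosis_sim import SimulationConfig, ChromosomeConfig, simulate_dataset

    cfg = SimulationConfig(
        chromosomes=(ChromosomeConfig("c", ("A", "B"), (0.0,)),),
        interference_m=0, n_tetrads=50, spore_viability=1.0,
        conversion_rate=0.0, seed=3,
    )
    counts = list(tally_intervals(simulate_dataset(cfg)).values())[0]
    assert counts.TT == 0 and counts.NPD == 0 and counts.PD == 50


# ---------------------------------------------------------------------------
# conversion detection
# ---------------------------------------------------------------------------

MARKERS_5 = [
    MarkerDef("A", "III", 1), MarkerDef("B", "III", 2), MarkerDef("C", "III", 3),
    MarkerDef("D", "VIII", 1), MarkerDef("E", "VIII", 2),
]


def tetrad_with_p1_counts(p1_counts):
    """Tetrad whose per-locus P1 counts (order A,B,C,D,E) are as given."""
    names = [m.name for m in MARKERS_5]
    spores = []
    for i in range(4):
        calls = {n: ("P1" if i < k else "P2") for n, k in zip(names, p1_counts)}
        spores.append(SporeGenotype(f"s{i}", True, calls))
    return Tetrad("t1", spores)


@pytest.mark.parametrize(
    "p1_counts, n_events, labels",
    [
        ((2, 2, 2, 2, 2), 0, []),
        ((3, 2, 2, 2, 2), 1, ["3:1"]),
        ((1, 2, 2, 2, 2), 1, ["1:3"]),
        ((4, 2, 2, 2, 2), 1, ["4:0"]),
        ((0, 2, 2, 2, 2), 1, ["0:4"]),
        ((3, 3, 2, 2, 2), 1, ["3:1"]),       # adjacent loci merge
        ((3, 2, 3, 2, 2), 2, ["3:1", "3:1"]),  # non-adjacent: two events
        ((2, 2, 3, 3, 2), 2, ["3:1", "3:1"]),  # adjacency never spans chromosomes
    ],
)
def test_conversion_merge_rule(p1_counts, n_events, labels):
    events = detect_conversions(tetrad_with_p1_counts(p1_counts), MARKERS_5)
    assert len(events) == n_events
    assert [e.label for e in events] == labels


@given(st.lists(st.integers(0, 4), min_size=5, max_size=5))
def test_merge_rule_equals_run_finder_oracle(p1_counts):
    """Event count equals the number of maximal runs of non-2:2 loci,
    computed with an independent groupby run-finder."""
    events = detect_conversions(tetrad_with_p1_counts(p1_counts), MARKERS_5)
    runs = 0
    for chrom_counts in (p1_counts[:3], p1_counts[3:]):
        for key, _ in itertools.groupby(c != 2 for c in chrom_counts):
            runs += key
    assert len(events) == runs


def test_detect_conversions_requires_four_viable():
    tet = make_tetrad("t1", PD_SPORES, viable=[True, True, True, False])
    with pytest.raises(ValueError):
        detect_conversions(tet, MARKERS_5[:2])


def test_filter_for_conversion_analysis():
    def renamed(tid, tet):
        return Tetrad(tid, [SporeGenotype(f"{tid}{i}", s.viable, dict(s.calls))
                            for i, s in enumerate(tet.spores)])

    clean = renamed("t1", tetrad_with_p1_counts((2, 2, 2, 2, 2)))
    dead = renamed("t2", tetrad_with_p1_counts((2, 2, 2, 2, 2)))
    dead.spores[0].viable = False
    dead.spores[0].calls = {k: "-" for k in dead.spores[0].calls}
    two = renamed("t3", tetrad_with_p1_counts((3, 2, 3, 2, 2)))
    three = renamed("t4", tetrad_with_p1_counts((3, 2, 3, 3, 2)))
    ds = TetradDataset(list(MARKERS_5), [clean, dead, two, three])
    kept = filter_for_conversion_analysis(ds)
    assert [t.tetrad_id for t in kept.tetrads] == ["t1", "t3"]


def test_mixed_direction_adjacent_loci_still_merge():
    # 3:1 next to 1:3 is still one event per the adjacency rule
    events = detect_conversions(tetrad_with_p1_counts((3, 1, 2, 2, 2)), MARKERS_5)
    assert len(events) == 1 and events[0].labels == ("3:1", "1:3")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def test_tetrad_table_round_trip(tmp_path, chr3_markers):
    from tetralink.meiosis_sim import SimulationConfig, simulate_dataset

    ds = simulate_dataset(SimulationConfig(n_tetrads=40, seed=7))
    path = tmp_path / "tetrads.tsv"
    write_tetrad_table(ds, path)
    back = read_tetrad_table(path, ds.markers)
    assert back.to_frame().equals(ds.to_frame())

    mpath = tmp_path / "markers.tsv"
    write_marker_map(ds.markers, mpath)
    assert read_marker_map(mpath) == ds.markers


def test_read_rejects_three_spore_tetrad(tmp_path, chr3_markers):
    path = tmp_path / "bad.tsv"
    rows = ["tetrad_id\tspore_id\tviable\tHIS4", "t1\ta\t1\tP1", "t1\tb\t1\tP1", "t1\tc\t1\tP2"]
    path.write_text("\n".join(rows) + "\n")
    with pytest.raises(TetradFormatError, match="t1"):
        read_tetrad_table(path, chr3_markers)


def test_read_rejects_unknown_marker_column(tmp_path, chr3_markers):
    path = tmp_path / "bad.tsv"
    path.write_text("tetrad_id\tspore_id\tviable\tNOPE\nt1\ta\t1\tP1\n")
    with pytest.raises(TetradFormatError, match="NOPE"):
        read_tetrad_table(path, chr3_markers)


def test_interval_class_counts_invariants():
    c = IntervalClassCounts(3, 2, 1, unscorable=4)
    assert c.n == 6
    with pytest.raises(ValueError):
        IntervalClassCounts(-1, 0, 0)


def test_marker_map_order_must_increase():
    with pytest.raises(ValueError):
        TetradDataset(
            [MarkerDef("A", "III", 2), MarkerDef("B", "III", 1)], []
        )
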