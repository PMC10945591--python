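"""In-silico digest, filtering, fragment assignment, cognate collapse."""

import numpy as np
import pandas as pd
import pytest

from spacc import assembly
from spacc.io import SEGMENT_COLUMNS
from spacc.simulate import SimConfig, generate_genome


def make_segments(rows):
    df = pd.DataFrame(rows, columns=["read_id", "chrom", "start", "end", "strand", "mapq", "read_order"])
    df["fragment_id"] = pd.array([pd.NA] * len(df), dtype="Int64")
    return df[SEGMENT_COLUMNS]


def test_digest_hand_example():
    fm = assembly.digest_reference({"c": "AAGATCTTGATCAA"})
    assert list(fm.cuts("c")) == [2, 8]
    assert list(fm.bounds["c"]) == [0, 2, 8, 14]
    assert fm.n_fragments == 3


def test_digest_no_motif_single_fragment():
    fm = assembly.digest_reference({"c": "AAAATTTT"})
    assert fm.n_fragments == 1
    assert fm.fragment_interval(0) == ("c", 0, 8)


def test_digest_empty_sequence_rejected():
    with pytest.raises(ValueError):
        assembly.digest_reference({"c": ""})
    with pytest.raises(ValueError):
        assembly.digest_reference({})


def test_fragment_count_equals_motif_count_plus_one():
    g = generate_genome(SimConfig(seed=2, chrom_sizes={"chr1": 1_000_000}))
    seq = g.seqs["chr1"]
    # independent overlap-safe motif count
    count, i = 0, seq.find("GATC")
    while i != -1:
        count += 1
        i = seq.find("GATC", i + 1)
    fm = assembly.digest_reference(g.seqs)
    assert fm.n_fragments == count + 1


@pytest.mark.parametrize(
    "mapq, length, kept",
    [(30, 50, True), (29, 500, False), (60, 49, False), (60, 50, True)],
)
def test_filter_boundaries(mapq, length, kept):
    segs = make_segments([("r1", "chr1", 0, length, "+", mapq, 0)])
    out = assembly.filter_alignments(segs)
    assert (len(out) == 1) is kept


def test_filter_idempotent(small_sim):
    once = assembly.filter_alignments(small_sim.segments)
    twice = assembly.filter_alignments(once)
    pd.testing.assert_frame_equal(once, twice)


def test_assign_midpoint_boundary():
    fm = assembly.digest_reference({"c": "A" * 1000 + "GATC" + "A" * 996})  # cut at 1000
    segs = make_segments([("r1", "c", 900, 1100, "+", 60, 0), ("r1", "c", 0, 10, "+", 60, 1)])
    out = assembly.assign_fragments(segs, fm)
    assert list(out["fragment_id"]) == [1, 0]  # midpoint 1000 -> fragment starting there


def test_assign_matches_linear_scan_oracle():
    g = generate_genome(SimConfig(seed=4, chrom_sizes={"chr1": 200_000}))
    fm = assembly.digest_reference(g.seqs)
    rng = np.random.default_rng(0)
    starts = rng.integers(0, 199_000, 1000)
    segs = make_segments(
        [("r%d" % i, "chr1", int(s), int(s) + 500, "+", 60, 0) for i, s in enumerate(starts)]
    )
    out = assembly.assign_fragments(segs, fm)
    bed = fm.to_bed()
    for row in out.itertuples(index=False):
        mid = (row.start + row.end) // 2
        hit = bed[(bed["chrom"] == row.chrom) & (bed["start"] <= mid) & (mid < bed["end"])]
        assert int(row.fragment_id) == int(hit["name"].iloc[0])


def test_assign_unknown_chromosome():
    fm = assembly.digest_reference({"c": "AAAA"})
    segs = make_segments([("r1", "chrX", 0, 4, "+", 60, 0)])
    with pytest.raises(KeyError):
        assembly.assign_fragments(segs, fm)


def _collapse_fixture():
    # GATC motifs start at 100, 200, 300 -> fragments [0,100).. [300,400)
    seq = "A" * 100 + ("GATC" + "A" * 96) * 3
    return assembly.digest_reference({"c": seq})


def test_collapse_same_fragment_neighbours():
    fm = _collapse_fixture()
    segs = make_segments(
        [
            ("r1", "c", 10, 40, "+", 60, 0),
            ("r1", "c", 50, 90, "+", 60, 1),  # same fragment 0
            ("r1", "c", 210, 260, "+", 60, 2),
        ]
    )
    out = assembly.deduplicate_cognate(assembly.assign_fragments(segs, fm), fm)
    assert len(out) == 2
    assert list(out["fragment_id"]) == [0, 2]
    assert list(out["read_order"]) == [0, 1]


def test_collapse_abutting_adjacent_fragments():
    fm = _collapse_fixture()
    segs = make_segments(
        [
            ("r1", "c", 20, 100, "+", 60, 0),
            ("r1", "c", 100, 180, "-", 60, 1),  # abuts at the shared cut 100
        ]
    )
    out = assembly.deduplicate_cognate(assembly.assign_fragments(segs, fm), fm)
    assert len(out) == 1
    assert (out.iloc[0]["start"], out.iloc[0]["end"]) == (20, 180)


def test_distal_revisit_kept():
    fm = _collapse_fixture()
    segs = make_segments(
        [
            ("r1", "c", 10, 90, "+", 60, 0),
            ("r1", "c", 210, 290, "+", 60, 1),
            ("r1", "c", 20, 80, "+", 60, 2),  # revisit of fragment 0, non-consecutive
        ]
    )
    out = assembly.deduplicate_cognate(assembly.assign_fragments(segs, fm), fm)
    assert list(out["fragment_id"]) == [0, 2, 0]


def test_adjacent_fragments_not_abutting_kept():
    fm = _collapse_fixture()
    segs = make_segments(
        [("r1", "c", 20, 80, "+", 60, 0), ("r1", "c", 120, 180, "+", 60, 1)]
    )
    out = assembly.deduplicate_cognate(assembly.assign_fragments(segs, fm), fm)
    assert len(out) == 2


def test_build_concatemers_and_histogram():
    rows = []
    for rid, card in (("r1", 2), ("r2", 3), ("r3", 6)):
        rows += [(rid, "c", 100 * k, 100 * k + 50, "+", 60, k) for k in range(card)]
    segs = make_segments(rows)
    segs["fragment_id"] = pd.array(range(len(segs)), dtype="Int64")
    df, summary = assembly.build_concatemers(segs)
    hist = summary["cardinality_fractions"]
    assert hist == {"1": 0.0, "2": 1 / 3, "3-5": 1 / 3, ">5": 1 / 3}
    assert (df.groupby("read_id")["cardinality"].first() == pd.Series({"r1": 2, "r2": 3, "r3": 6})).all()


def test_duplicate_read_order_rejected():
    segs = make_segments([("r1", "c", 0, 50, "+", 60, 0), ("r1", "c", 60, 120, "+", 60, 0)])
    with pytest.raises(ValueError, match="duplicate"):
        assembly.build_concatemers(segs)


def test_assembly_partitions_filtered_segments(small_result):
    """Every filtered segment belongs to exactly one concatemer."""
    res = small_result
    kept = assembly.filter_alignments(res.sim.segments)
    n_collapsed_away = len(kept) - len(res.concatemers)
    assert n_collapsed_away >= 0
    assert res.concatemers["read_id"].nunique() == kept["read_id"].nunique()
    assert not res.concatemers.duplicated(subset=["read_id", "read_order"]).any()


def test_recovered_cardinality_split_matches_config(small_result):
    """Assembled cardinality bins approximate the configured split."""
    hist = small_result.assembly_summary["cardinality_fractions"]
    cfg = small_result.sim.config
    w = cfg.cardinality_weights
    want = {
        "1": w.get(1, 0),
        "2": w.get(2, 0),
        "3-5": sum(v for k, v in w.items() if 3 <= k <= 5),
        ">5": sum(v for k, v in w.items() if k > 5),
    }
    n = small_result.assembly_summary["n_reads"]
    for key, p in want.items():
        # filtering/collapse shifts bins slightly; allow 4 binomial sds + 2%
        tol = 4 * np.sqrt(p * (1 - p) / n) + 0.02
        assert abs(hist[key] - p) <= tol
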