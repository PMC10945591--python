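"""Site calling, GCG masking, window scan, region merging, classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from spacc import accessibility as acc
from spacc.simulate import SimConfig, generate_genome, scan_sites

from conftest import binom_tail_enumeration, binom_tail_oracle, union_bitmap_oracle

P = acc.AccessibilityParams()


def calls_frame(rows):
    return pd.DataFrame(rows, columns=["read_id", "chrom", "pos", "context", "llr"])


@pytest.mark.parametrize(
    "context, llr, meth",
    [
        ("GpC", 1.2, True),
        ("GpC", 1.0, False),  # strict boundary
        ("CpG", 1.4, False),
        ("CpG", 1.6, True),
        ("CpG", 1.5, False),
    ],
)
def test_llr_cutoffs_strict(context, llr, meth):
    out = acc.call_sites(calls_frame([("r1", "chr1", 10, context, llr)]), P)
    assert bool(out["methylated"].iloc[0]) is meth


def test_gcg_context_masked():
    seqs = {"chr1": "AAGCGTTAGCAA"}  # GCG at 2..5 -> GpC at 2, CpG at 3; lone GpC at 8
    sites = scan_sites(seqs)
    calls = acc.call_sites(
        calls_frame(
            [("r1", "chr1", 2, "GpC", 2.0), ("r1", "chr1", 3, "CpG", 2.0), ("r1", "chr1", 8, "GpC", 2.0)]
        ),
        P,
    )
    out = acc.mask_gcg(calls, sites)
    assert list(out["gcg_masked"]) == [True, True, False]


def test_mask_rejects_reference_mismatch():
    sites = scan_sites({"chr1": "AAGCAA"})
    calls = acc.call_sites(calls_frame([("r1", "chr1", 4, "GpC", 2.0)]), P)
    with pytest.raises(KeyError, match="site map"):
        acc.mask_gcg(calls, sites)


def test_masked_fraction_matches_sequence_scan():
    g = generate_genome(SimConfig(seed=6, chrom_sizes={"chr1": 50_000}))
    seq = g.seqs["chr1"]
    gpc = g.sites.gpc["chr1"]
    calls = acc.call_sites(
        calls_frame([("r1", "chr1", int(p), "GpC", 2.0) for p in gpc]), P
    )
    out = acc.mask_gcg(calls, g.sites)
    expected = np.array([seq[p : p + 3] == "GCG" for p in gpc])
    assert np.array_equal(out["gcg_masked"].to_numpy(), expected)
    assert out["gcg_masked"].mean() == pytest.approx(expected.mean())


# ---------------------------------------------------------------------------
# windows

def test_window_zero_methylated_fails():
    win = acc.scan_windows(np.arange(5) * 10, np.zeros(5, bool), 0, 50, P)
    assert len(win) == 1
    assert win["p"].iloc[0] == 1.0
    assert not win["passing"].iloc[0]


def test_window_all_methylated_closed_form():
    win = acc.scan_windows(np.arange(5) * 10, np.ones(5, bool), 0, 50, P)
    expected = 0.03**5
    assert win["p"].iloc[0] == pytest.approx(expected, rel=1e-12)
    assert win["p"].iloc[0] == pytest.approx(binom_tail_enumeration(5, 5, 0.03), rel=1e-12)


def test_window_offsets_200bp_span():
    win = acc.scan_windows(np.arange(0, 200, 10), np.ones(20, bool), 0, 200, P)
    assert list(win["start"]) == list(range(0, 160, 10))
    assert (win["end"] - win["start"] == 50).all()


def test_window_partial_terminal_kept():
    # 195 bp span: one final partial window [150, 195)
    win = acc.scan_windows(np.array([160]), np.array([True]), 0, 195, P)
    assert win["start"].max() == 150
    assert win["end"].max() == 195


def test_unsorted_positions_rejected():
    with pytest.raises(ValueError):
        acc.scan_windows(np.array([30, 10]), np.array([True, True]), 0, 50, P)


@given(
    st.lists(st.integers(0, 199), min_size=1, max_size=30, unique=True),
    st.integers(0, 29),
)
def test_window_p_monotone_in_methylation(positions, flip):
    """Methylating one more site never increases any window's p-value."""
    positions = np.array(sorted(positions))
    meth = np.zeros(len(positions), bool)
    meth[: len(positions) // 2] = True
    more = meth.copy()
    more[flip % len(positions)] = True
    w1 = acc.scan_windows(positions, meth, 0, 200, P)
    w2 = acc.scan_windows(positions, more, 0, 200, P)
    assert (w2["p"].to_numpy() <= w1["p"].to_numpy() + 1e-15).all()


# ---------------------------------------------------------------------------
# region merging

def test_merge_overlapping_windows():
    windows = pd.DataFrame(
        {
            "start": [100, 110],
            "end": [150, 160],
            "n_gpc": [3, 3],
            "n_meth": [3, 3],
            "p": [1e-4, 1e-5],
            "passing": [True, True],
        }
    )
    reg = acc.merge_regions(windows, np.array([110, 120, 130, 140, 150]), P)
    assert len(reg) == 1
    assert (reg.iloc[0]["start"], reg.iloc[0]["end"]) == (100, 160)
    assert reg.iloc[0]["p_min"] == 1e-5
    assert reg.iloc[0]["n_gpc"] == 5


def test_single_gpc_window_excluded():
    windows = pd.DataFrame(
        {"start": [100], "end": [150], "n_gpc": [1], "n_meth": [1], "p": [1e-4], "passing": [True]}
    )
    assert acc.merge_regions(windows, np.array([120]), P).empty


@given(
    st.lists(
        st.tuples(st.integers(0, 100), st.booleans()),
        min_size=1,
        max_size=20,
        unique_by=lambda t: t[0],
    )
)
def test_merge_matches_bitmap_union(entries):
    starts = sorted(s * 10 for s, _ in entries)
    passing = [p for _, p in entries]
    windows = pd.DataFrame(
        {
            "start": starts,
            "end": [s + 50 for s in starts],
            "n_gpc": 3,
            "n_meth": 3,
            "p": 1e-4,
            "passing": passing,
        }
    )
    reg = acc.merge_regions(windows, np.array([], dtype=int), P)
    keep = [(s, s + 50) for s, p in zip(starts, passing) if p]
    expected = [iv for iv in union_bitmap_oracle(keep, 1100) if iv[1] - iv[0] >= 50]
    assert [(r.start, r.end) for r in reg.itertuples(index=False)] == expected


# ---------------------------------------------------------------------------
# denoise

def test_denoise_resets_outside_regions():
    calls = acc.call_sites(
        calls_frame(
            [
                ("r1", "chr1", 5000, "GpC", 3.0),
                ("r1", "chr1", 4950, "GpC", 3.0),
                ("r1", "chr1", 5000, "CpG", 3.0),
            ]
        ),
        P,
    )
    regions = pd.DataFrame(
        [("r1", 0, "chr1", 4900, 4980, 3, 1e-4)],
        columns=["read_id", "read_order", "chrom", "start", "end", "n_gpc", "p_min"],
    )
    out = acc.denoise(calls, regions)
    assert not out.iloc[0]["methylated"] and out.iloc[0]["denoised"]  # outside
    assert out.iloc[1]["methylated"] and not out.iloc[1]["denoised"]  # inside
    assert out.iloc[2]["methylated"]  # CpG untouched


def test_denoise_vacuous_cover():
    calls = acc.call_sites(calls_frame([("r1", "chr1", 10, "GpC", 3.0)]), P)
    out = acc.denoise(calls, pd.DataFrame(columns=["read_id", "read_order", "chrom", "start", "end"]))
    assert not out["methylated"].any()


# ---------------------------------------------------------------------------
# segment classification

def counts_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["read_id", "read_order", "chrom", "start", "end", "n_gpc_total", "n_gpc_meth", "n_cpg_total", "n_cpg_meth"],
    ).assign(
        gpc_ratio=lambda d: d["n_gpc_meth"] / d["n_gpc_total"].replace(0, np.nan),
        cpg_ratio=lambda d: d["n_cpg_meth"] / d["n_cpg_total"].replace(0, np.nan),
    )


def test_accessible_segment_exact_p():
    out = acc.classify_segments(counts_frame([("r1", 0, "c", 0, 500, 20, 10, 5, 2)]), P)
    expected = binom_tail_oracle(10, 20, 0.03)
    assert out.iloc[0]["p_acc"] == pytest.approx(expected, rel=1e-12)
    assert out.iloc[0]["state"] == "accessible"


def test_zero_sites_undetermined():
    out = acc.classify_segments(counts_frame([("r1", 0, "c", 0, 500, 0, 0, 0, 0)]), P)
    assert out.iloc[0]["state"] == "undetermined"


def test_fully_unmethylated_inaccessible_closed_form():
    out = acc.classify_segments(counts_frame([("r1", 0, "c", 0, 500, 20, 0, 5, 2)]), P)
    row = out.iloc[0]
    assert row["state"] == "inaccessible"
    assert row["p_inacc"] == pytest.approx(0.3**20, rel=1e-12)
    assert np.isnan(row["p_acc"])  # failed the accessible-test precondition


def test_classification_is_partition(small_result):
    labels = small_result.segment_labels
    assert set(labels["state"]) <= {"accessible", "inaccessible", "undetermined"}
    acc_rows = labels[labels["state"] == "accessible"]
    assert (acc_rows["n_gpc_meth"] >= 4).all()
    # one state per segment, all segments labeled
    assert len(labels) == len(small_result.concatemers)


# ---------------------------------------------------------------------------
# labeling efficiency

def ctcf_frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand", "bound"])


def test_efficiency_arithmetic():
    rows = []
    for i in range(100):
        # all segments overlap the single CTCF bin; 15 look unlabeled
        gpc_meth = 0 if i < 15 else 50
        rows.append((f"r{i}", 0, "c", 800, 1200, 100, gpc_meth, 50, 5))
    est = acc.estimate_labeling_efficiency(counts_frame(rows), ctcf_frame([("c", 1000, "+", True)]))
    assert est.n_qualifying == 100 and est.n_unlabeled == 15
    assert est.efficiency == pytest.approx(0.85)


def test_efficiency_strict_boundaries():
    # CpG ratio exactly 0.25 -> not qualifying; GpC ratio exactly 0.1 -> labeled
    rows = [
        ("r0", 0, "c", 800, 1200, 100, 5, 100, 25),  # cpg = 0.25 exactly
        ("r1", 0, "c", 800, 1200, 100, 10, 100, 5),  # gpc = 0.10 exactly -> labeled
    ]
    est = acc.estimate_labeling_efficiency(counts_frame(rows), ctcf_frame([("c", 1000, "+", True)]))
    assert est.n_qualifying == 1
    assert est.n_unlabeled == 0


def test_efficiency_undefined_without_segments():
    est = acc.estimate_labeling_efficiency(
        counts_frame([("r0", 0, "c", 5000, 5400, 100, 5, 100, 80)]),
        ctcf_frame([("c", 1000, "+", True)]),
    )
    assert est.n_qualifying == 0 and est.efficiency is None
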