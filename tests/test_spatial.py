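"""Concatemer classes, CTCF footprints, E-P typing, CGI classes, tethering."""

import numpy as np
import pandas as pd
import pytest

from spacc import spatial
from spacc.io import SEGMENT_COLUMNS
from spacc.pipeline import run_pipeline
from spacc.simulate import SimConfig


def labels_frame(entries):
    """entries: (read_id, read_order, state)"""
    return pd.DataFrame(
        {
            "read_id": [e[0] for e in entries],
            "read_order": [e[1] for e in entries],
            "state": [e[2] for e in entries],
        }
    )


def test_fraction_and_class_arithmetic():
    out = spatial.concatemer_fraction(
        labels_frame(
            [("r1", 0, "accessible"), ("r1", 1, "inaccessible"), ("r1", 2, "undetermined"), ("r1", 3, "accessible")]
        )
    )
    row = out.iloc[0]
    assert row["fraction"] == pytest.approx(2 / 3)
    assert row["class"] == "hybrid"


def test_low_fraction_is_inaccessible_class():
    entries = [("r1", i, "accessible" if i == 0 else "inaccessible") for i in range(20)]
    out = spatial.concatemer_fraction(labels_frame(entries))
    assert out.iloc[0]["fraction"] == pytest.approx(0.05)
    assert out.iloc[0]["class"] == "inaccessible"


def test_all_undetermined_unclassifiable():
    out = spatial.concatemer_fraction(labels_frame([("r1", 0, "undetermined")]))
    assert out.iloc[0]["class"] == "unclassifiable"
    assert np.isnan(out.iloc[0]["fraction"])


def test_class_partition_on_simulated_data(small_result):
    classes = small_result.concatemer_classes
    assert set(classes["class"]) <= {"accessible", "inaccessible", "hybrid", "unclassifiable"}
    defined = classes[classes["class"] != "unclassifiable"]
    assert defined["fraction"].between(0, 1).all()
    assert (classes["class"].value_counts().sum()) == len(classes)


# ---------------------------------------------------------------------------
# footprints

def segments_frame(rows):
    df = pd.DataFrame(rows, columns=["read_id", "chrom", "start", "end", "strand", "mapq", "read_order"])
    df["fragment_id"] = pd.array([pd.NA] * len(df), dtype="Int64")
    return df[SEGMENT_COLUMNS]


def regions_frame(rows):
    return pd.DataFrame(rows, columns=["read_id", "read_order", "chrom", "start", "end"])


CTCF = pd.DataFrame({"chrom": ["chr1"], "pos": [1000], "strand": ["+"], "bound": [True]})


def test_flanked_protected_center_is_footprint():
    segs = segments_frame([("r1", "chr1", 700, 1300, "+", 60, 0)])
    regs = regions_frame([("r1", 0, "chr1", 900, 960), ("r1", 0, "chr1", 1040, 1100)])
    out = spatial.detect_footprints(segs, regs, CTCF)
    assert list(out["status"]) == ["footprint"]


def test_region_spanning_center_is_no_footprint():
    segs = segments_frame([("r1", "chr1", 700, 1300, "+", 60, 0)])
    regs = regions_frame([("r1", 0, "chr1", 950, 1050)])
    out = spatial.detect_footprints(segs, regs, CTCF)
    assert list(out["status"]) == ["no_footprint"]


def test_insufficient_margin_is_uninformative():
    segs = segments_frame([("r1", "chr1", 990, 1200, "+", 60, 0)])
    out = spatial.detect_footprints(segs, regions_frame([]), CTCF)
    assert list(out["status"]) == ["uninformative"]


def test_flank_enlargement_never_creates_footprint():
    """Growing the flank requirement can only lose footprints, never gain."""
    segs = segments_frame([("r1", "chr1", 500, 1500, "+", 60, 0)])
    for regs in (
        regions_frame([("r1", 0, "chr1", 900, 960), ("r1", 0, "chr1", 1040, 1100)]),
        regions_frame([("r1", 0, "chr1", 950, 1050)]),
        regions_frame([("r1", 0, "chr1", 850, 930)]),
    ):
        small = spatial.detect_footprints(segs, regs, CTCF, spatial.FootprintParams(flank=80))
        large = spatial.detect_footprints(segs, regs, CTCF, spatial.FootprintParams(flank=200))
        s = dict(zip(small["ctcf_pos"], small["status"]))
        l = dict(zip(large["ctcf_pos"], large["status"]))
        for posn, status in l.items():
            if status == "footprint":
                assert s.get(posn) == "footprint"


def test_stratified_stats_identical_classes_p_one():
    segs = segments_frame(
        [("r1", "chr1", 0, 100, "+", 60, 0), ("r1", "chr1", 200, 300, "+", 60, 1),
         ("r2", "chr1", 0, 100, "+", 60, 0), ("r2", "chr1", 200, 300, "+", 60, 1)]
    )
    fps = pd.DataFrame(
        {"read_id": ["r1", "r2"], "read_order": [0, 0], "chrom": "chr1", "ctcf_pos": 50,
         "status": ["footprint", "no_footprint"]}
    )
    pairs = pd.DataFrame({"read_id": ["r1", "r2"], "cis": True, "distance": [200.0, 200.0]})
    out = spatial.footprint_stratified_stats(segs, fps, pairs)
    assert out["cardinality_p"] is None  # classes of size 1: undefined, no crash
    fps2 = pd.concat([fps, fps.assign(read_id=["r3", "r4"])])
    segs2 = pd.concat([segs, segs.assign(read_id=segs["read_id"].map({"r1": "r3", "r2": "r4"}))])
    pairs2 = pd.concat([pairs, pairs.assign(read_id=["r3", "r4"])])
    out2 = spatial.footprint_stratified_stats(segs2, fps2, pairs2)
    assert out2["cardinality_p"] == pytest.approx(1.0)


def test_planted_cardinality_effect_detected():
    """Bound-CTCF concatemers drawn with extra segments separate the classes."""
    cfg = SimConfig(
        seed=21,
        chrom_sizes={"chr1": 1_000_000, "chrM": 16_000},
        n_reads=4_000,
        ctcf_anchor_frac=0.5,
        ctcf_bound_extra_cardinality=2,
    )
    res = run_pipeline(cfg)
    out = spatial.footprint_stratified_stats(res.concatemers, res.footprints, res.pairs)
    assert out["footprint"]["n_concatemers"] >= 50
    assert out["no_footprint"]["n_concatemers"] >= 50
    assert out["cardinality_p"] < 0.01
    assert np.mean(out["footprint"]["cardinality"]) > np.mean(out["no_footprint"]["cardinality"])


# ---------------------------------------------------------------------------
# enhancer-promoter typing

def test_ep_typing_hand_tally():
    enh = pd.DataFrame({"chrom": ["chr1"], "start": [1000], "end": [2000]})
    prom = pd.DataFrame({"chrom": ["chr1"], "start": [8000], "end": [9000]})
    entries, labels = [], []
    expected = {"A-A": 0, "A-I": 0, "I-I": 0}
    states = ["accessible", "inaccessible"]
    n = 0
    rows = []
    for s1 in states + ["undetermined"]:
        for s2 in states:
            rid = f"r{n}"
            rows.append(
                (rid, 0, 1, "chr1", 1100, 1400, "chr1", 8100, 8400, s1, s2)
            )
            if s1 != "undetermined":
                kind = {2: "A-A", 1: "A-I", 0: "I-I"}[(s1 == "accessible") + (s2 == "accessible")]
                expected[kind] += 1
            n += 1
    # plus pairs that touch no enhancer or promoter -> never typed
    rows.append((f"r{n}", 0, 1, "chr1", 3000, 3300, "chr1", 5000, 5300, "accessible", "accessible"))
    pairs = pd.DataFrame(
        rows,
        columns=["read_id", "order1", "order2", "chrom1", "start1", "end1", "chrom2", "start2", "end2", "s1", "s2"],
    )
    pairs["pos1"] = (pairs["start1"] + pairs["end1"]) // 2
    pairs["pos2"] = (pairs["start2"] + pairs["end2"]) // 2
    labels = pd.concat(
        [
            pairs[["read_id", "order1", "s1"]].rename(columns={"order1": "read_order", "s1": "state"}),
            pairs[["read_id", "order2", "s2"]].rename(columns={"order2": "read_order", "s2": "state"}),
        ]
    )
    typed, summary = spatial.classify_ep_contacts(pairs, labels, enh, prom)
    got = typed["type"].value_counts().to_dict()
    assert {k: got.get(k, 0) for k in expected} == expected
    assert summary["n_typed"] == sum(expected.values())
    assert sum(v for v in summary["fractions"].values()) == pytest.approx(1.0)


def test_ep_requires_annotations():
    with pytest.raises(ValueError):
        spatial.classify_ep_contacts(
            pd.DataFrame(), labels_frame([]), pd.DataFrame(columns=["chrom", "start", "end"]), None
        )


# ---------------------------------------------------------------------------
# CGI classes

def bed(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def test_cgi_classification_rules():
    enh = bed([("chr1", 10_000, 10_400)])
    prom = bed([("chr1", 50_000, 50_400)])
    cgis = bed(
        [
            ("chr1", 12_000, 12_600),  # 1600 bp from enhancer, far from promoter -> oCGI
            ("chr1", 50_100, 50_700),  # overlaps promoter -> pCGI
            ("chr1", 10_900, 11_500),  # 500 bp from enhancer -> eCGI
        ]
    )
    out = spatial.classify_cgi(cgis, enh, prom)
    assert list(out["cgi_class"]) == ["oCGI", "pCGI", "eCGI"]


def test_cgi_promoter_precedence_and_partition():
    enh = bed([("chr1", 10_000, 10_400)])
    prom = bed([("chr1", 11_000, 11_400)])
    cgis = bed([("chr1", 10_500, 10_900)])  # within 1 kb of both
    out = spatial.classify_cgi(cgis, enh, prom)
    assert list(out["cgi_class"]) == ["pCGI"]


def test_planted_cgi_kinds_recovered(small_sim):
    truth = small_sim.truth
    out = spatial.classify_cgi(truth.cgis, truth.enhancers, truth.promoters)
    mapping = {"orphan": "oCGI", "enhancer_proximal": "eCGI", "promoter_proximal": "pCGI"}
    assert (out["cgi_class"] == out["planted_kind"].map(mapping)).all()


# ---------------------------------------------------------------------------
# oCGI tethering

def test_tethering_profile_counts():
    segs = segments_frame(
        [
            ("r1", "chr1", 100, 700, "+", 60, 0),  # oCGI
            ("r1", "chr1", 5000, 5400, "+", 60, 1),  # enhancer
            ("r1", "chr1", 7000, 7400, "+", 60, 2),  # enhancer
            ("r1", "chr1", 9000, 9100, "+", 60, 3),  # ctcf
        ]
    )
    cgi_classes = bed([("chr1", 200, 600)]).assign(cgi_class="oCGI")
    ctcf = pd.DataFrame({"chrom": ["chr1"], "pos": [9050], "strand": ["+"], "bound": [True]})
    enh = bed([("chr1", 5100, 5300), ("chr1", 7100, 7300)])
    prom = bed([("chr1", 20_000, 20_400)])
    out = spatial.ocgi_tethering(segs, cgi_classes, ctcf, enh, prom, seed=0)
    profile = out["profile"].iloc[0]
    assert (profile["enhancer"], profile["ctcf"], profile["promoter"]) == (2, 1, 0)
    assert out["tethered_fraction"] == 1.0


def test_tethering_empty_without_ocgi_overlap():
    segs = segments_frame([("r1", "chr1", 100, 200, "+", 60, 0)])
    cgi_classes = bed([("chr1", 5000, 5600)]).assign(cgi_class="oCGI")
    ctcf = pd.DataFrame({"chrom": [], "pos": [], "strand": [], "bound": []})
    out = spatial.ocgi_tethering(segs, cgi_classes, ctcf, bed([]), bed([]), seed=0)
    assert out["n_concatemers"] == 0 and out["tethered_fraction"] is None


def test_ep_anchored_reads_loop_enhancer_to_promoter():
    """Enhancer-promoter looping reads anchor their first two segments."""
    from spacc.simulate import generate_genome, plant_annotations, simulate_concatemers
    from spacc.intervals import merge_intervals, overlaps_any

    cfg = SimConfig(
        seed=11,
        chrom_sizes={"chr1": 500_000, "chrM": 16_000},
        n_reads=300,
        cardinality_weights={2: 1.0},
        ep_anchor_frac=1.0,
        mito_hybrid_rate=0.0,
        frac_fail_filter=0.0,  # truncated low-quality segments would miss the element
    )
    g = generate_genome(cfg)
    truth = plant_annotations(g, cfg)
    segs = simulate_concatemers(g, truth, cfg)
    enh = {c: merge_intervals(s[["start", "end"]].to_numpy()) for c, s in truth.enhancers.groupby("chrom")}
    prom = {c: merge_intervals(s[["start", "end"]].to_numpy()) for c, s in truth.promoters.groupby("chrom")}
    first = segs[segs["read_order"] == 0]
    second = segs[segs["read_order"] == 1]
    hit_e = np.mean(
        [overlaps_any([r.start], [r.end], enh.get(r.chrom, np.empty((0, 2), int)))[0] for r in first.itertuples()]
    )
    hit_p = np.mean(
        [overlaps_any([r.start], [r.end], prom.get(r.chrom, np.empty((0, 2), int)))[0] for r in second.itertuples()]
    )
    assert hit_e == 1.0 and hit_p == 1.0


def test_planted_tethering_enrichment_recovered():
    """3x promoter-vs-enhancer tethering preference is recovered within 30%."""
    cfg = SimConfig(
        seed=31,
        chrom_sizes={"chr1": 1_500_000, "chrM": 16_000},
        n_reads=6_000,
        cardinality_weights={3: 0.5, 4: 0.5},
        ocgi_anchor_frac=0.15,
        tether_weights={"promoter": 3.0, "enhancer": 1.0},
        tether_prob=0.8,
    )
    res = run_pipeline(cfg)
    truth = res.sim.truth
    cgi_classes = spatial.classify_cgi(truth.cgis, truth.enhancers, truth.promoters)
    out = spatial.ocgi_tethering(
        res.concatemers, cgi_classes, truth.ctcf_sites, truth.enhancers, truth.promoters, seed=0
    )
    assert out["n_concatemers"] >= 500
    # per-element contact rate of oCGI concatemers, promoter vs enhancer
    ratio = out["preference"]["promoter"] / out["preference"]["enhancer"]
    assert 3.0 * 0.7 <= ratio <= 3.0 * 1.3
    # control concatemers show no such preference
    ctrl = out["control_preference"]["promoter"] / out["control_preference"]["enhancer"]
    assert ctrl < ratio
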