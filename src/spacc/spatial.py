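"""Spatial accessibility statistics on classified concatemers.

Covers the results-level analyses of the assay: per-concatemer accessible
fractions and classes, CTCF footprint detection from per-molecule accessible
regions, footprint-stratified cardinality/distance comparisons,
enhancer–promoter contact typing, CpG-island classification (orphan /
enhancer-proximal / promoter-proximal) and orphan-CGI tethering profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import gap_distance, merge_intervals, overlaps_any

__all__ = [
    "concatemer_fraction",
    "detect_footprints",
    "footprint_stratified_stats",
    "classify_ep_contacts",
    "classify_cgi",
    "ocgi_tethering",
]


# ---------------------------------------------------------------------------
# concatemer accessibility classes

def concatemer_fraction(labels: pd.DataFrame) -> pd.DataFrame:
    """Accessible-segment fraction and class per concatemer.

    ``labels`` is the per-segment classification (read_id, state).
    Undetermined segments are excluded from numerator and denominator.
    Classes: inaccessible (fraction < 0.1), accessible (> 0.9), hybrid in
    between; unclassifiable when no segment is determined.
    """
    g = labels.groupby("read_id")["state"]
    n_acc = g.apply(lambda s: int((s == "accessible").sum()))
    n_inacc = g.apply(lambda s: int((s == "inaccessible").sum()))
    n_undet = g.apply(lambda s: int((s == "undetermined").sum()))
    denom = n_acc + n_inacc
    with np.errstate(invalid="ignore"):
        frac = np.where(denom > 0, n_acc / denom.replace(0, np.nan), np.nan)
    cls = np.full(len(denom), "hybrid", dtype=object)
    cls[~(denom > 0)] = "unclassifiable"
    ok = denom > 0
    cls[ok.to_numpy() & (frac < 0.1)] = "inaccessible"
    cls[ok.to_numpy() & (frac > 0.9)] = "accessible"
    return pd.DataFrame(
        {
            "read_id": denom.index,
            "n_accessible": n_acc.to_numpy(),
            "n_inaccessible": n_inacc.to_numpy(),
            "n_undetermined": n_undet.to_numpy(),
            "fraction": frac,
            "class": cls,
        }
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# CTCF footprints

@dataclass
class FootprintParams:
    flank: int = 100  # bp of required coverage/accessible-signal margin
    center_halfwidth: int = 20  # protected exclusion around the motif center


def detect_footprints(
    segments: pd.DataFrame,
    regions: pd.DataFrame,
    ctcf_sites: pd.DataFrame,
    params: FootprintParams | None = None,
) -> pd.DataFrame:
    """Per-molecule CTCF footprint calls at covered motifs.

    For each motif center ``c`` covered by a segment with >= ``flank`` bp of
    margin on both sides: *footprint* when the molecule has accessible signal
    in both flanks ``[c-flank, c-hw)`` and ``(c+hw, c+flank]`` but none on
    the protected center ``[c-hw, c+hw]``; *no_footprint* when the motif is
    covered with both flanks observed but the pattern is absent;
    motifs without such coverage are *uninformative* and not reported.

    Returns read_id, read_order, chrom, ctcf_pos, status.
    """
    params = params or FootprintParams()
    fl, hw = params.flank, params.center_halfwidth
    by_chrom = {c: s["pos"].to_numpy() for c, s in ctcf_sites.groupby("chrom")}
    reg_by_mol = {
        key: sub[["start", "end"]].to_numpy()
        for key, sub in regions.groupby(["read_id", "read_order", "chrom"])
    }
    rows = []
    for seg in segments.itertuples(index=False):
        pos = by_chrom.get(seg.chrom)
        if pos is None:
            continue
        cov_lo = np.searchsorted(pos, seg.start, side="left")
        cov_hi = np.searchsorted(pos, seg.end, side="right")
        for c in pos[cov_lo:cov_hi]:
            c = int(c)
            if not (seg.start + fl <= c and c <= seg.end - fl):
                rows.append((seg.read_id, int(seg.read_order), seg.chrom, c, "uninformative"))
                continue
            track = reg_by_mol.get((seg.read_id, seg.read_order, seg.chrom))
            if track is None:
                track = np.empty((0, 2), dtype=np.int64)
            left = overlaps_any([c - fl], [c - hw], track)[0]
            right = overlaps_any([c + hw + 1], [c + fl + 1], track)[0]
            center = overlaps_any([c - hw], [c + hw + 1], track)[0]
            status = "footprint" if (left and right and not center) else "no_footprint"
            rows.append((seg.read_id, int(seg.read_order), seg.chrom, c, status))
    return pd.DataFrame(rows, columns=["read_id", "read_order", "chrom", "ctcf_pos", "status"])


def footprint_stratified_stats(
    segments: pd.DataFrame,
    footprints: pd.DataFrame,
    pairs: pd.DataFrame,
) -> dict:
    """Cardinality and cis-distance distributions by CTCF footprint status.

    Concatemers with >=1 footprint call form the footprint class; concatemers
    whose motifs were all covered without the pattern form the no-footprint
    class. Reports per-class cardinality arrays, cis distances, and Wilcoxon
    rank-sum p-values between the classes (``None`` when a class has <2
    concatemers).
    """
    if footprints.empty:
        return {"footprint": None, "no_footprint": None, "cardinality_p": None, "distance_p": None}
    per = footprints.groupby("read_id")["status"]
    has_fp = per.apply(lambda s: (s == "footprint").any())
    has_nofp = per.apply(lambda s: (s == "no_footprint").any())
    with_fp = set(has_fp[has_fp].index)
    without_fp = set(has_nofp[~has_fp & has_nofp].index)  # informative, pattern absent
    card = segments.groupby("read_id").size()
    d_cis = pairs[pairs["cis"]].groupby("read_id")["distance"]
    out = {}
    for name, reads in (("footprint", with_fp), ("no_footprint", without_fp)):
        ids = sorted(reads)
        cards = card.reindex(ids).dropna().to_numpy()
        dists = np.concatenate(
            [d_cis.get_group(r).to_numpy() for r in ids if r in d_cis.groups] or [np.empty(0)]
        )
        out[name] = {
            "n_concatemers": len(ids),
            "cardinality": cards,
            "distances": dists,
        }
    for key, attr in (("cardinality_p", "cardinality"), ("distance_p", "distances")):
        a = out["footprint"][attr]
        b = out["no_footprint"][attr]
        out[key] = (
            float(stats.ranksums(a, b).pvalue) if len(a) >= 2 and len(b) >= 2 else None
        )
    return out


# ---------------------------------------------------------------------------
# enhancer–promoter contact typing

def classify_ep_contacts(
    pairs: pd.DataFrame,
    labels: pd.DataFrame,
    enhancers: pd.DataFrame,
    promoters: pd.DataFrame,
) -> tuple[pd.DataFrame, dict]:
    """Type enhancer–promoter pairs as A-A / A-I / I-I by endpoint state.

    A pair is kept when one endpoint segment overlaps an enhancer and the
    other a promoter; pairs with an undetermined endpoint are excluded from
    typing. Returns the typed pairs and a summary with the three fractions
    and per-promoter-endpoint accessible-contact counts.
    """
    if enhancers is None or promoters is None or len(enhancers) == 0 or len(promoters) == 0:
        raise ValueError("enhancer and promoter annotations are required")
    enh = {c: merge_intervals(s[["start", "end"]].to_numpy()) for c, s in enhancers.groupby("chrom")}
    prom = {c: merge_intervals(s[["start", "end"]].to_numpy()) for c, s in promoters.groupby("chrom")}
    empty = np.empty((0, 2), dtype=np.int64)
    state = {
        (r.read_id, r.read_order): r.state for r in labels.itertuples(index=False)
    }
    rows = []
    for r in pairs.itertuples(index=False):
        e1 = overlaps_any([r.start1], [r.end1], enh.get(r.chrom1, empty))[0]
        p1 = overlaps_any([r.start1], [r.end1], prom.get(r.chrom1, empty))[0]
        e2 = overlaps_any([r.start2], [r.end2], enh.get(r.chrom2, empty))[0]
        p2 = overlaps_any([r.start2], [r.end2], prom.get(r.chrom2, empty))[0]
        if e1 and p2:
            enh_end, prom_end = 1, 2
        elif e2 and p1:
            enh_end, prom_end = 2, 1
        else:
            continue
        s1 = state.get((r.read_id, r.order1), "undetermined")
        s2 = state.get((r.read_id, r.order2), "undetermined")
        if "undetermined" in (s1, s2):
            continue
        n_acc = (s1 == "accessible") + (s2 == "accessible")
        kind = ("I-I", "A-I", "A-A")[n_acc]
        prom_chrom = r.chrom1 if prom_end == 1 else r.chrom2
        prom_start = r.start1 if prom_end == 1 else r.start2
        prom_end_pos = r.end1 if prom_end == 1 else r.end2
        rows.append(
            (r.read_id, r.order1, r.order2, kind, prom_chrom, prom_start, prom_end_pos, n_acc)
        )
    typed = pd.DataFrame(
        rows,
        columns=[
            "read_id",
            "order1",
            "order2",
            "type",
            "prom_chrom",
            "prom_start",
            "prom_end",
            "n_accessible_ends",
        ],
    )
    n = len(typed)
    fractions = {
        kind: (float((typed["type"] == kind).sum()) / n if n else None) for kind in ("A-A", "A-I", "I-I")
    }
    per_promoter = (
        typed.groupby(["prom_chrom", "prom_start", "prom_end"])["n_accessible_ends"]
        .agg(n_contacts="size", n_accessible_contacts=lambda s: int((s == 2).sum()))
        .reset_index()
        if n
        else pd.DataFrame(columns=["prom_chrom", "prom_start", "prom_end", "n_contacts", "n_accessible_contacts"])
    )
    return typed, {"n_typed": n, "fractions": fractions, "per_promoter": per_promoter}


# ---------------------------------------------------------------------------
# CpG island classes and orphan-CGI tethering

def classify_cgi(
    cgis: pd.DataFrame,
    enhancers: pd.DataFrame,
    promoters: pd.DataFrame,
    min_dist: int = 1000,
) -> pd.DataFrame:
    """Classify CpG islands by distance to regulatory elements.

    pCGI: overlaps or lies within ``min_dist`` bp of a promoter (promoter
    precedence); else eCGI by the same rule for enhancers; else orphan
    (oCGI, at least ``min_dist`` bp from both). Gap distances are half-open.
    """
    enh = {c: merge_intervals(s[["start", "end"]].to_numpy()) for c, s in enhancers.groupby("chrom")}
    prom = {c: merge_intervals(s[["start", "end"]].to_numpy()) for c, s in promoters.groupby("chrom")}
    empty = np.empty((0, 2), dtype=np.int64)
    out = cgis.copy().reset_index(drop=True)
    classes = []
    for r in out.itertuples(index=False):
        dp = gap_distance(int(r.start), int(r.end), prom.get(r.chrom, empty))
        de = gap_distance(int(r.start), int(r.end), enh.get(r.chrom, empty))
        if dp is not None and dp < min_dist:
            classes.append("pCGI")
        elif de is not None and de < min_dist:
            classes.append("eCGI")
        else:
            classes.append("oCGI")
    out["cgi_class"] = classes
    return out


def ocgi_tethering(
    segments: pd.DataFrame,
    cgi_classes: pd.DataFrame,
    ctcf_sites: pd.DataFrame,
    enhancers: pd.DataFrame,
    promoters: pd.DataFrame,
    seed: int = 0,
) -> dict:
    """Element composition of concatemers touching orphan CpG islands.

    For each concatemer with >=1 segment overlapping an oCGI, counts distinct
    segments overlapping CTCF motifs, enhancers and promoters. Aggregate
    contact preference per element class is normalized by that class's total
    genomic element count, and compared against a cardinality-matched random
    sample of concatemers (seeded control).
    """
    rng = np.random.default_rng(seed)
    ocgi = cgi_classes[cgi_classes["cgi_class"] == "oCGI"]
    tracks = {
        "ctcf": {
            c: merge_intervals(np.stack([s["pos"].to_numpy() - 10, s["pos"].to_numpy() + 10], axis=1))
            for c, s in ctcf_sites.groupby("chrom")
        },
        "enhancer": {c: merge_intervals(s[["start", "end"]].to_numpy()) for c, s in enhancers.groupby("chrom")},
        "promoter": {c: merge_intervals(s[["start", "end"]].to_numpy()) for c, s in promoters.groupby("chrom")},
    }
    n_elements = {
        "ctcf": len(ctcf_sites),
        "enhancer": len(enhancers),
        "promoter": len(promoters),
    }
    ocgi_track = {c: merge_intervals(s[["start", "end"]].to_numpy()) for c, s in ocgi.groupby("chrom")}
    empty = np.empty((0, 2), dtype=np.int64)

    df = segments.reset_index(drop=True)
    hits = {}
    for name, per_chrom in tracks.items():
        flag = np.zeros(len(df), dtype=bool)
        for chrom, sub in df.groupby("chrom"):
            flag[sub.index.to_numpy()] = overlaps_any(
                sub["start"].to_numpy(), sub["end"].to_numpy(), per_chrom.get(chrom, empty)
            )
        hits[name] = flag
    in_ocgi = np.zeros(len(df), dtype=bool)
    for chrom, sub in df.groupby("chrom"):
        in_ocgi[sub.index.to_numpy()] = overlaps_any(
            sub["start"].to_numpy(), sub["end"].to_numpy(), ocgi_track.get(chrom, empty)
        )
    per_read = pd.DataFrame(
        {
            "read_id": df["read_id"],
            "ocgi": in_ocgi,
            "ctcf": hits["ctcf"],
            "enhancer": hits["enhancer"],
            "promoter": hits["promoter"],
        }
    ).groupby("read_id").sum()
    per_read["cardinality"] = df.groupby("read_id").size()

    touching = per_read[per_read["ocgi"] > 0]
    if touching.empty:
        return {
            "profile": touching,
            "n_concatemers": 0,
            "preference": {},
            "control_preference": {},
            "tethered_fraction": None,
        }
    # cardinality-matched random control
    by_card = {c: sub for c, sub in per_read.groupby("cardinality")}
    control_rows = []
    for c, count in touching["cardinality"].value_counts().items():
        pool = by_card.get(c, per_read)
        take = rng.integers(0, len(pool), size=int(count))
        control_rows.append(pool.iloc[take])
    control = pd.concat(control_rows)

    def preference(tbl):
        return {
            k: float(tbl[k].sum()) / (n_elements[k] * len(tbl)) if n_elements[k] and len(tbl) else None
            for k in ("ctcf", "enhancer", "promoter")
        }

    tethered = (touching[["ctcf", "enhancer", "promoter"]].sum(axis=1) > 0).mean()
    return {
        "profile": touching.reset_index(),
        "n_concatemers": int(len(touching)),
        "preference": preference(touching),
        "control_preference": preference(control),
        "tethered_fraction": float(tethered),
    }
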