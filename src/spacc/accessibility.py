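"""Per-molecule chromatin accessibility from GpC methylation calls.

Stages, mirroring the assay's analysis model:

1. **Site calling** — threshold the caller's log-likelihood ratios (GpC > 1,
   CpG > 1.5, strict) into binary methylation states.
2. **GCG masking** — GpC and CpG calls in GCG trinucleotide context are
   ambiguous between the accessibility and native signals and are excluded
   from every numerator and denominator.
3. **Sliding-window detection** — 50-bp windows at 10-bp steps across each
   segment; a right-tailed exact binomial test of methylated vs total GpC
   against the background rate (0.03); passing windows with >=2 GpC sites are
   unioned into per-molecule accessible regions.
4. **Denoising** — methylated GpC calls outside every accessible region of
   the molecule are reset to unmethylated.
5. **Trinary segment classification** — segments with >=4 methylated GpCs
   are tested accessible against the background rate; among the remainder the
   unmethylated count is tested against the spike-in unlabeled rate (0.3);
   both tests are BH-adjusted (< 0.05), accessible takes precedence, and
   everything else is undetermined.
6. **Labeling-efficiency estimation** — among segments overlapping 1000-bp
   CTCF-motif bins with low native CpG methylation (< 0.25), those with GpC
   ratio < 0.1 are counted as labeling failures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import bh_adjust, binom_right_tail
from .simulate import SiteMaps

__all__ = [
    "AccessibilityParams",
    "EfficiencyEstimate",
    "call_sites",
    "mask_gcg",
    "assign_calls_to_segments",
    "scan_windows",
    "merge_regions",
    "call_accessible_regions",
    "denoise",
    "segment_counts",
    "classify_segments",
    "estimate_labeling_efficiency",
]


@dataclass
class AccessibilityParams:
    """Tunable thresholds of the accessibility caller (assay defaults)."""

    gpc_llr: float = 1.0  # methylated GpC iff llr > 1
    cpg_llr: float = 1.5  # methylated CpG iff llr > 1.5
    p_background: float = 0.03  # GpC rate on unlabeled chromatin
    p_unlabeled: float = 0.3  # unmethylated-GpC rate on labeled spike-in
    window: int = 50
    step: int = 10
    window_alpha: float = 0.05  # uncorrected, window level
    segment_alpha: float = 0.05  # BH-adjusted, segment level
    min_meth_for_test: int = 4  # accessible test needs >=4 methylated GpCs
    min_gpc_per_window: int = 2  # merged windows must contain >=2 GpC sites
    min_region_width: int = 50

    def validate(self) -> None:
        for name in ("p_background", "p_unlabeled", "window_alpha", "segment_alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name}={v} outside (0, 1)")
        if self.window <= 0 or self.step <= 0:
            raise ValueError("window and step must be positive")


def call_sites(calls: pd.DataFrame, params: AccessibilityParams | None = None) -> pd.DataFrame:
    """Resolve binary methylation status from LLRs (strict inequalities)."""
    params = params or AccessibilityParams()
    out = calls.copy()
    is_gpc = out["context"].to_numpy() == "GpC"
    llr = out["llr"].to_numpy()
    out["methylated"] = np.where(is_gpc, llr > params.gpc_llr, llr > params.cpg_llr)
    return out


def mask_gcg(calls: pd.DataFrame, sites: SiteMaps) -> pd.DataFrame:
    """Flag calls in GCG trinucleotide context; verify reference agreement.

    Raises ``KeyError`` when a call position is absent from the site map of
    its context (reference mismatch).
    """
    out = calls.copy()
    masked = np.zeros(len(out), dtype=bool)
    chroms = out["chrom"].to_numpy()
    pos = out["pos"].to_numpy()
    ctx = out["context"].to_numpy()
    for chrom in pd.unique(chroms):
        for context, site_map, gcg_map in (
            ("GpC", sites.gpc, sites.gcg_gpc),
            ("CpG", sites.cpg, sites.gcg_cpg),
        ):
            sel = (chroms == chrom) & (ctx == context)
            if not sel.any():
                continue
            if chrom not in site_map:
                raise KeyError(f"no {context} site map for chromosome {chrom!r}")
            p = pos[sel]
            smap = site_map[chrom]
            idx = np.searchsorted(smap, p)
            ok = (idx < len(smap)) & (smap[np.minimum(idx, len(smap) - 1)] == p)
            if not ok.all():
                bad = p[~ok][0]
                raise KeyError(
                    f"{context} call at {chrom}:{bad} not in the reference site map"
                )
            gm = gcg_map[chrom]
            gidx = np.searchsorted(gm, p)
            masked[sel] = (gidx < len(gm)) & (gm[np.minimum(gidx, len(gm) - 1)] == p)
    out["gcg_masked"] = masked
    return out


def assign_calls_to_segments(calls: pd.DataFrame, segments: pd.DataFrame) -> pd.DataFrame:
    """Attach each call to the covering segment of its read (``read_order``).

    Calls not covered by any segment of the read (e.g. from filtered-out
    alignments) are dropped. A call covered by several overlapping segments
    of the same read is assigned to the lowest ``read_order``.
    """
    calls = calls.reset_index(drop=True)
    order = np.full(len(calls), -1, dtype=np.int64)
    pos_all = calls["pos"].to_numpy()
    chrom_all = calls["chrom"].to_numpy()
    seg_groups = {
        rid: sub.sort_values("read_order")
        for rid, sub in segments[["read_id", "chrom", "start", "end", "read_order"]].groupby("read_id", sort=False)
    }
    for rid, idx in calls.groupby("read_id", sort=False).indices.items():
        segs = seg_groups.get(rid)
        if segs is None:
            continue
        pos = pos_all[idx]
        chrom = chrom_all[idx]
        assigned = np.full(len(idx), -1, dtype=np.int64)
        for seg in segs.itertuples(index=False):
            m = (assigned == -1) & (chrom == seg.chrom) & (pos >= seg.start) & (pos < seg.end)
            assigned[m] = seg.read_order
        order[idx] = assigned
    keep = order >= 0
    out = calls[keep].copy()
    out["read_order"] = order[keep]
    return out.reset_index(drop=True)


def _window_offsets(span: int, window: int, step: int) -> np.ndarray:
    """Window start offsets tiling ``[0, span)``; final partial window kept."""
    if span <= window:
        return np.array([0], dtype=np.int64)
    n = int(np.ceil((span - window) / step)) + 1
    return np.arange(n, dtype=np.int64) * step


def scan_windows(
    positions: np.ndarray,
    methylated: np.ndarray,
    span_start: int,
    span_end: int,
    params: AccessibilityParams | None = None,
) -> pd.DataFrame:
    """Sliding-window right-tailed binomial test over one segment.

    ``positions`` are (masked, sorted) GpC site coordinates within
    ``[span_start, span_end)``. Windows are anchored at the segment start.
    Windows with no GpC observation are skipped; ``passing`` means
    p < window_alpha (uncorrected).
    """
    params = params or AccessibilityParams()
    params.validate()
    positions = np.asarray(positions, dtype=np.int64)
    methylated = np.asarray(methylated, dtype=bool)
    if len(positions) > 1 and (np.diff(positions) < 0).any():
        raise ValueError("site positions must be sorted")
    offs = _window_offsets(span_end - span_start, params.window, params.step)
    starts = span_start + offs
    ends = np.minimum(starts + params.window, span_end)
    meth_cum = np.concatenate([[0], np.cumsum(methylated)])
    lo = np.searchsorted(positions, starts)
    hi = np.searchsorted(positions, ends)
    n_gpc = hi - lo
    n_meth = meth_cum[hi] - meth_cum[lo]
    keep = n_gpc >= 1
    p = np.ones(len(starts))
    p[keep] = binom_right_tail(n_meth[keep], n_gpc[keep], params.p_background)
    df = pd.DataFrame(
        {
            "start": starts[keep],
            "end": ends[keep],
            "n_gpc": n_gpc[keep],
            "n_meth": n_meth[keep],
            "p": p[keep],
        }
    )
    df["passing"] = df["p"] < params.window_alpha
    return df


def merge_regions(
    windows: pd.DataFrame,
    positions: np.ndarray,
    params: AccessibilityParams | None = None,
) -> pd.DataFrame:
    """Union overlapping/abutting passing windows (>=2 GpC sites) into regions.

    Returns columns start, end, n_gpc, p_min. Regions narrower than the
    window floor are discarded (a lone partial terminal window cannot form a
    region).
    """
    params = params or AccessibilityParams()
    ok = windows[windows["passing"] & (windows["n_gpc"] >= params.min_gpc_per_window)]
    if ok.empty:
        return pd.DataFrame(columns=["start", "end", "n_gpc", "p_min"])
    ivals = ok[["start", "end"]].to_numpy()
    order = np.argsort(ivals[:, 0], kind="stable")
    ivals = ivals[order]
    pvals = ok["p"].to_numpy()[order]
    out = []
    cs, ce, cp = int(ivals[0, 0]), int(ivals[0, 1]), float(pvals[0])
    for (s, e), p in zip(ivals[1:], pvals[1:]):
        if s <= ce:  # overlapping or abutting
            ce = max(ce, int(e))
            cp = min(cp, float(p))
        else:
            out.append((cs, ce, cp))
            cs, ce, cp = int(s), int(e), float(p)
    out.append((cs, ce, cp))
    positions = np.asarray(positions, dtype=np.int64)
    rows = []
    for s, e, p in out:
        if e - s < params.min_region_width:
            continue
        n = int(np.searchsorted(positions, e) - np.searchsorted(positions, s))
        rows.append((s, e, n, p))
    return pd.DataFrame(rows, columns=["start", "end", "n_gpc", "p_min"])


def call_accessible_regions(
    calls: pd.DataFrame,
    segments: pd.DataFrame,
    params: AccessibilityParams | None = None,
) -> pd.DataFrame:
    """Per-molecule accessible regions for every segment of every read.

    ``calls`` must carry ``methylated``, ``gcg_masked`` and ``read_order``
    (see :func:`call_sites`, :func:`mask_gcg`,
    :func:`assign_calls_to_segments`); windows are anchored at each
    segment's genomic start. Returns read_id, read_order, chrom, start, end,
    n_gpc, p_min, sorted and non-overlapping per molecule.
    """
    params = params or AccessibilityParams()
    spans = {
        (r.read_id, r.read_order): (int(r.start), int(r.end))
        for r in segments[["read_id", "read_order", "start", "end"]].itertuples(index=False)
    }
    gpc = calls[(calls["context"] == "GpC") & ~calls["gcg_masked"]]
    rows = []
    for (read_id, order, chrom), sub in gpc.groupby(["read_id", "read_order", "chrom"], sort=True):
        sub = sub.sort_values("pos")
        pos = sub["pos"].to_numpy()
        meth = sub["methylated"].to_numpy()
        span_start, span_end = spans.get((read_id, order), (int(pos[0]), int(pos[-1]) + 1))
        win = scan_windows(pos, meth, span_start, span_end, params)
        reg = merge_regions(win, pos, params)
        for r in reg.itertuples(index=False):
            rows.append((read_id, order, chrom, int(r.start), int(r.end), int(r.n_gpc), float(r.p_min)))
    return pd.DataFrame(
        rows, columns=["read_id", "read_order", "chrom", "start", "end", "n_gpc", "p_min"]
    )


def denoise(calls: pd.DataFrame, regions: pd.DataFrame) -> pd.DataFrame:
    """Reset methylated GpC calls outside every accessible region of the read.

    CpG calls are untouched. Adds a ``denoised`` flag on reset calls.
    """
    out = calls.copy()
    out["denoised"] = False
    gpc_meth = (out["context"] == "GpC") & out["methylated"]
    by_read = regions.groupby(["read_id", "chrom"])
    tracks = {key: sub[["start", "end"]].to_numpy() for key, sub in by_read}
    idx = out.index[gpc_meth]
    pos = out.loc[idx, "pos"].to_numpy()
    keys = list(zip(out.loc[idx, "read_id"], out.loc[idx, "chrom"]))
    inside = np.zeros(len(idx), dtype=bool)
    for i, (key, p) in enumerate(zip(keys, pos)):
        track = tracks.get(key)
        if track is None or len(track) == 0:
            continue
        j = np.searchsorted(track[:, 0], p, side="right") - 1
        inside[i] = j >= 0 and p < track[j, 1]
    reset = idx[~inside]
    out.loc[reset, "methylated"] = False
    out.loc[reset, "denoised"] = True
    return out


def segment_counts(calls: pd.DataFrame, segments: pd.DataFrame) -> pd.DataFrame:
    """Per-segment methylated/total counts of GCG-masked site calls.

    Uses pre-denoise calls (the segment-level binomial analysis is kept
    independent of the window-level one). Returns one row per segment with
    GpC and CpG counts and ratios.
    """
    usable = calls[~calls["gcg_masked"]]
    base = segments[["read_id", "read_order", "chrom", "start", "end"]].copy()
    rows = []
    grouped = usable.groupby(["read_id", "read_order", "context"])
    agg = grouped["methylated"].agg(["size", "sum"])
    for row in base.itertuples(index=False):
        counts = {}
        for context, pre in (("GpC", "gpc"), ("CpG", "cpg")):
            key = (row.read_id, row.read_order, context)
            if key in agg.index:
                n, m = agg.loc[key]
                counts[f"n_{pre}_total"], counts[f"n_{pre}_meth"] = int(n), int(m)
            else:
                counts[f"n_{pre}_total"] = counts[f"n_{pre}_meth"] = 0
        rows.append(
            (
                row.read_id,
                row.read_order,
                row.chrom,
                row.start,
                row.end,
                counts["n_gpc_total"],
                counts["n_gpc_meth"],
                counts["n_cpg_total"],
                counts["n_cpg_meth"],
            )
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "read_id",
            "read_order",
            "chrom",
            "start",
            "end",
            "n_gpc_total",
            "n_gpc_meth",
            "n_cpg_total",
            "n_cpg_meth",
        ],
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        out["gpc_ratio"] = np.where(
            out["n_gpc_total"] > 0, out["n_gpc_meth"] / out["n_gpc_total"], np.nan
        )
        out["cpg_ratio"] = np.where(
            out["n_cpg_total"] > 0, out["n_cpg_meth"] / out["n_cpg_total"], np.nan
        )
    return out


def classify_segments(
    counts: pd.DataFrame, params: AccessibilityParams | None = None
) -> pd.DataFrame:
    """Trinary segment state from two BH-adjusted exact binomial tests.

    Accessible first: segments with >= ``min_meth_for_test`` methylated GpCs
    are tested right-tailed against ``p_background``; BH across tested
    segments, adjusted p < alpha => accessible. Among the rest, the
    unmethylated count is tested right-tailed against ``p_unlabeled``; BH
    across that set, adjusted p < alpha => inaccessible. Everything else is
    undetermined (never an error, including zero-GpC segments).
    """
    params = params or AccessibilityParams()
    out = counts.copy()
    n = out["n_gpc_total"].to_numpy()
    m = out["n_gpc_meth"].to_numpy()
    state = np.full(len(out), "undetermined", dtype=object)
    p_acc = np.full(len(out), np.nan)
    p_adj_acc = np.full(len(out), np.nan)
    p_inacc = np.full(len(out), np.nan)
    p_adj_inacc = np.full(len(out), np.nan)

    test_acc = m >= params.min_meth_for_test
    if test_acc.any():
        p = binom_right_tail(m[test_acc], n[test_acc], params.p_background)
        padj = bh_adjust(p)
        p_acc[test_acc] = p
        p_adj_acc[test_acc] = padj
        acc = np.zeros(len(out), dtype=bool)
        acc[test_acc] = padj < params.segment_alpha
        state[acc] = "accessible"
    else:
        acc = np.zeros(len(out), dtype=bool)

    rest = ~acc & (n > 0)
    if rest.any():
        u = n[rest] - m[rest]
        p = binom_right_tail(u, n[rest], params.p_unlabeled)
        padj = bh_adjust(p)
        p_inacc[rest] = p
        p_adj_inacc[rest] = padj
        inacc = np.zeros(len(out), dtype=bool)
        inacc[rest] = padj < params.segment_alpha
        state[inacc] = "inaccessible"

    out["state"] = state
    out["p_acc"] = p_acc
    out["p_adj_acc"] = p_adj_acc
    out["p_inacc"] = p_inacc
    out["p_adj_inacc"] = p_adj_inacc
    return out


@dataclass
class EfficiencyEstimate:
    n_unlabeled: int
    n_qualifying: int

    @property
    def efficiency(self) -> float | None:
        if self.n_qualifying == 0:
            return None
        return 1.0 - self.n_unlabeled / self.n_qualifying


def estimate_labeling_efficiency(
    counts: pd.DataFrame,
    ctcf_sites: pd.DataFrame,
    bin_halfwidth: int = 500,
    max_cpg_ratio: float = 0.25,
    max_gpc_ratio: float = 0.1,
) -> EfficiencyEstimate:
    """Enzyme labeling efficiency from CTCF-motif bins.

    Restricts to segments overlapping 1000-bp bins centered on CTCF motifs
    whose native CpG methylation is low (ratio < 0.25, strict) — the set
    expected to be accessible in vivo. Among those, segments with GpC ratio
    < 0.1 (strict) count as labeling failures; efficiency is 1 minus the
    failure fraction. Undefined (``efficiency None``) with no qualifying
    segments.
    """
    from .intervals import merge_intervals, overlaps_any

    counts = counts.reset_index(drop=True)
    bins = {
        chrom: merge_intervals(
            np.stack([sub["pos"].to_numpy() - bin_halfwidth, sub["pos"].to_numpy() + bin_halfwidth], axis=1)
        )
        for chrom, sub in ctcf_sites.groupby("chrom")
    }
    near = np.zeros(len(counts), dtype=bool)
    for chrom, sub in counts.groupby("chrom"):
        track = bins.get(chrom)
        if track is None:
            continue
        near[sub.index] = overlaps_any(sub["start"].to_numpy(), sub["end"].to_numpy(), track)
    with np.errstate(invalid="ignore"):
        qualifying = (
            near
            & (counts["n_cpg_total"].to_numpy() > 0)
            & (counts["n_gpc_total"].to_numpy() > 0)
            & (counts["cpg_ratio"].to_numpy() < max_cpg_ratio)
        )
        unlabeled = qualifying & (counts["gpc_ratio"].to_numpy() < max_gpc_ratio)
    return EfficiencyEstimate(n_unlabeled=int(unlabeled.sum()), n_qualifying=int(qualifying.sum()))
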