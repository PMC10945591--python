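"""Population-level accessibility peaks from pooled GpC calls.

Pooled (pre-denoise, GCG-masked) site calls are tallied into 200-bp windows
on a fixed 20-bp grid. Windows whose methylation ratio strictly exceeds the
99th percentile of window ratios are candidates; each candidate gets a
one-tailed exact binomial test against the global methylation ratio,
BH-adjusted; passing windows are merged, and merged peaks are kept when the
minimum constituent adjusted p-value is < 0.001 and the width is > 50 bp.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from ._stats import bh_adjust, binom_right_tail
from .intervals import merge_intervals, overlaps_any

__all__ = [
    "PeakParams",
    "accessibility_track",
    "call_peaks",
    "evaluate_peaks",
    "track_to_bedgraph",
]


@dataclass
class PeakParams:
    window: int = 200
    step: int = 20
    percentile: float = 99.0
    alpha: float = 0.001  # BH-adjusted
    min_width: int = 50  # peaks must be strictly wider


def accessibility_track(calls: pd.DataFrame, params: PeakParams | None = None) -> pd.DataFrame:
    """Pooled per-window methylated/unmethylated GpC counts.

    ``calls`` must carry ``methylated`` and ``gcg_masked``. Windows with no
    GpC observation are omitted. Returns chrom, start, end, n_meth,
    n_unmeth, ratio on the fixed ``step`` grid.
    """
    params = params or PeakParams()
    w, st = params.window, params.step
    per_win = w // st  # windows containing a given position
    gpc = calls[(calls["context"] == "GpC") & ~calls["gcg_masked"]]
    rows = []
    for chrom, sub in gpc.groupby("chrom", sort=True):
        pos = sub["pos"].to_numpy(dtype=np.int64)
        meth = sub["methylated"].to_numpy()
        base = pos // st  # index of the last grid window starting at/before pos
        nwin = int(base.max()) + 1 if len(base) else 0
        n_meth = np.zeros(nwin, dtype=np.int64)
        n_tot = np.zeros(nwin, dtype=np.int64)
        for k in range(per_win):
            idx = base - k
            ok = idx >= 0
            np.add.at(n_tot, idx[ok], 1)
            np.add.at(n_meth, idx[ok], meth[ok].astype(np.int64))
        occupied = np.flatnonzero(n_tot > 0)
        for i in occupied:
            rows.append((chrom, int(i) * st, int(i) * st + w, int(n_meth[i]), int(n_tot[i] - n_meth[i])))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_meth", "n_unmeth"])
    tot = df["n_meth"] + df["n_unmeth"]
    df["ratio"] = np.where(tot > 0, df["n_meth"] / tot, np.nan)
    return df


def call_peaks(track: pd.DataFrame, params: PeakParams | None = None) -> pd.DataFrame:
    """Peaks from a pooled window track (see module docstring).

    Returns chrom, start, end, ratio (pooled over the peak), p_adj
    (minimum constituent window adjusted p-value).
    """
    params = params or PeakParams()
    if track.empty:
        return pd.DataFrame(columns=["chrom", "start", "end", "ratio", "p_adj"])
    track = track.reset_index(drop=True)
    ratios = track["ratio"].to_numpy()
    n = (track["n_meth"] + track["n_unmeth"]).to_numpy()
    global_ratio = float(track["n_meth"].sum() / n.sum())
    cut = float(np.percentile(ratios, params.percentile))  # linear interpolation
    cand = ratios > cut  # strictly greater
    if not cand.any():
        return pd.DataFrame(columns=["chrom", "start", "end", "ratio", "p_adj"])
    p = binom_right_tail(track.loc[cand, "n_meth"].to_numpy(), n[cand], global_ratio)
    p_adj = bh_adjust(p)
    passing = track.loc[cand].assign(p_adj=p_adj)[p_adj < params.alpha]
    rows = []
    for chrom, sub in passing.groupby("chrom", sort=True):
        sub = sub.sort_values("start")
        cur = None
        for r in sub.itertuples(index=False):
            if cur is not None and r.start <= cur["end"]:
                cur["end"] = max(cur["end"], r.end)
                cur["n_meth"] += r.n_meth
                cur["n_unmeth"] += r.n_unmeth
                cur["p_adj"] = min(cur["p_adj"], r.p_adj)
            else:
                if cur is not None:
                    rows.append(cur)
                cur = {
                    "chrom": chrom,
                    "start": int(r.start),
                    "end": int(r.end),
                    "n_meth": int(r.n_meth),
                    "n_unmeth": int(r.n_unmeth),
                    "p_adj": float(r.p_adj),
                }
        if cur is not None:
            rows.append(cur)
    peaks = pd.DataFrame(rows)
    if peaks.empty:
        return pd.DataFrame(columns=["chrom", "start", "end", "ratio", "p_adj"])
    peaks = peaks[(peaks["end"] - peaks["start"]) > params.min_width]
    peaks = peaks[peaks["p_adj"] < params.alpha]
    tot = peaks["n_meth"] + peaks["n_unmeth"]
    peaks["ratio"] = peaks["n_meth"] / tot
    return peaks[["chrom", "start", "end", "ratio", "p_adj"]].reset_index(drop=True)


def evaluate_peaks(
    peaks: pd.DataFrame,
    truth_a: pd.DataFrame,
    truth_b: pd.DataFrame,
    chrom_sizes: Mapping[str, int],
    bin_size: int = 200,
) -> dict:
    """Overlap evaluation of called peaks against two reference peak sets.

    * ``peak_overlap_fraction``: fraction of called peaks overlapping (>=1 bp)
      either reference set.
    * bin-level ``sensitivity`` / ``specificity`` on fixed genomic bins:
      positives are bins overlapping the intersection of the two references;
      negatives are bins overlapping neither; a bin counts as called when it
      overlaps a peak.

    Metrics are ``None`` when their denominator is empty.
    """
    a = {c: merge_intervals(s[["start", "end"]].to_numpy()) for c, s in truth_a.groupby("chrom")}
    b = {c: merge_intervals(s[["start", "end"]].to_numpy()) for c, s in truth_b.groupby("chrom")}
    pk = {c: merge_intervals(s[["start", "end"]].to_numpy()) for c, s in peaks.groupby("chrom")}
    empty = np.empty((0, 2), dtype=np.int64)

    n_peaks = len(peaks)
    n_overlap = 0
    for r in peaks.itertuples(index=False):
        hit_a = overlaps_any([r.start], [r.end], a.get(r.chrom, empty))[0]
        hit_b = overlaps_any([r.start], [r.end], b.get(r.chrom, empty))[0]
        n_overlap += bool(hit_a or hit_b)

    tp = fn = tn = fp = 0
    for chrom, size in chrom_sizes.items():
        starts = np.arange(0, size, bin_size, dtype=np.int64)
        ends = np.minimum(starts + bin_size, size)
        in_a = overlaps_any(starts, ends, a.get(chrom, empty))
        in_b = overlaps_any(starts, ends, b.get(chrom, empty))
        called = overlaps_any(starts, ends, pk.get(chrom, empty))
        pos = in_a & in_b
        neg = ~in_a & ~in_b
        tp += int((pos & called).sum())
        fn += int((pos & ~called).sum())
        tn += int((neg & ~called).sum())
        fp += int((neg & called).sum())

    return {
        "n_peaks": n_peaks,
        "peak_overlap_fraction": (n_overlap / n_peaks) if n_peaks else None,
        "sensitivity": (tp / (tp + fn)) if (tp + fn) else None,
        "specificity": (tn / (tn + fp)) if (tn + fp) else None,
    }


def track_to_bedgraph(track: pd.DataFrame, step: int = 20) -> pd.DataFrame:
    """Non-overlapping ``step``-wide ratio track for bedGraph export."""
    out = track[["chrom", "start"]].copy()
    out["end"] = out["start"] + step
    out["value"] = track["ratio"].to_numpy()
    return out
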