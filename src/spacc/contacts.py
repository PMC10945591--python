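"""Multiway concatemers to weighted virtual pairwise contacts.

Every unordered pair of segments in a concatemer becomes a virtual
paired-end tag. With ``k`` segments strictly between the two mates in read
order, the pair carries weight ``1/2**k`` (adjacent mates weigh 1), which
down-weights the over-representation that plain all-pairs decomposition
would introduce relative to two-locus assays. Pair coordinates are the
midpoints of the assigned restriction fragments.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .assembly import FragmentMap

__all__ = [
    "decompose",
    "decompose_all",
    "bin_contacts",
    "distance_distribution",
    "estimate_false_positive",
    "DISTANCE_BINS",
]

# cis-distance reporting bins (bp), half-open [low, high)
DISTANCE_BINS = ((0, 150), (150, 1_000), (1_000, 200_000), (200_000, None))

PAIR_COLUMNS = [
    "read_id",
    "chrom1",
    "pos1",
    "strand1",
    "order1",
    "start1",
    "end1",
    "chrom2",
    "pos2",
    "strand2",
    "order2",
    "start2",
    "end2",
    "k",
    "weight",
    "cis",
    "distance",
]


def _endpoint(seg, fragment_map: FragmentMap | None) -> int:
    if fragment_map is not None and not pd.isna(seg.fragment_id):
        return fragment_map.midpoint(int(seg.fragment_id))[1]
    return (int(seg.start) + int(seg.end)) // 2


def decompose(concatemer: pd.DataFrame, fragment_map: FragmentMap | None = None) -> pd.DataFrame:
    """All C(n,2) weighted pairs of one concatemer (ordered by read_order).

    Singletons give an empty frame. Endpoint coordinates are assigned
    fragment midpoints (segment midpoints when no fragment map is given).
    """
    segs = concatemer.sort_values("read_order").reset_index(drop=True)
    n = len(segs)
    rows = []
    pos = [_endpoint(s, fragment_map) for s in segs.itertuples(index=False)]
    for i in range(n):
        a = segs.iloc[i]
        for j in range(i + 1, n):
            b = segs.iloc[j]
            k = j - i - 1
            cis = a["chrom"] == b["chrom"]
            rows.append(
                (
                    a["read_id"],
                    a["chrom"],
                    pos[i],
                    a["strand"],
                    int(a["read_order"]),
                    int(a["start"]),
                    int(a["end"]),
                    b["chrom"],
                    pos[j],
                    b["strand"],
                    int(b["read_order"]),
                    int(b["start"]),
                    int(b["end"]),
                    k,
                    2.0 ** (-k),
                    bool(cis),
                    abs(pos[j] - pos[i]) if cis else np.nan,
                )
            )
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


def _fragment_midpoints(fragment_map: FragmentMap) -> np.ndarray:
    mids = [
        (fragment_map.bounds[c][:-1] + fragment_map.bounds[c][1:]) // 2
        for c in fragment_map.chrom_order
    ]
    return np.concatenate(mids)


def decompose_all(segments: pd.DataFrame, fragment_map: FragmentMap | None = None) -> pd.DataFrame:
    """Decompose every non-singleton read of a segment table (vectorized)."""
    df = segments.sort_values(["read_id", "read_order"], kind="mergesort").reset_index(drop=True)
    if df.empty:
        return pd.DataFrame(columns=PAIR_COLUMNS)
    pos = ((df["start"].to_numpy() + df["end"].to_numpy()) // 2).astype(np.int64)
    if fragment_map is not None and df["fragment_id"].notna().all():
        pos = _fragment_midpoints(fragment_map)[df["fragment_id"].to_numpy(dtype=np.int64)]
    sizes = df.groupby("read_id", sort=False).size().to_numpy()
    starts = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    ii, jj = [], []
    for s, n in zip(starts, sizes):
        if n < 2:
            continue
        a, b = np.triu_indices(n, k=1)
        ii.append(a + s)
        jj.append(b + s)
    if not ii:
        return pd.DataFrame(columns=PAIR_COLUMNS)
    i = np.concatenate(ii)
    j = np.concatenate(jj)
    chrom = df["chrom"].to_numpy()
    cis = chrom[i] == chrom[j]
    k = (df["read_order"].to_numpy()[j] - df["read_order"].to_numpy()[i] - 1).astype(np.int64)
    out = pd.DataFrame(
        {
            "read_id": df["read_id"].to_numpy()[i],
            "chrom1": chrom[i],
            "pos1": pos[i],
            "strand1": df["strand"].to_numpy()[i],
            "order1": df["read_order"].to_numpy()[i],
            "start1": df["start"].to_numpy()[i],
            "end1": df["end"].to_numpy()[i],
            "chrom2": chrom[j],
            "pos2": pos[j],
            "strand2": df["strand"].to_numpy()[j],
            "order2": df["read_order"].to_numpy()[j],
            "start2": df["start"].to_numpy()[j],
            "end2": df["end"].to_numpy()[j],
            "k": k,
            "weight": 2.0 ** (-k.astype(float)),
            "cis": cis,
            "distance": np.where(cis, np.abs(pos[j] - pos[i]), np.nan),
        }
    )
    return out[PAIR_COLUMNS]


def bin_contacts(
    pairs: pd.DataFrame, resolution: int, chrom_order: list[str] | None = None
) -> pd.DataFrame:
    """Sum pair weights into upper-triangular bins at ``resolution`` bp.

    Bins are ``floor(pos / resolution)`` per chromosome; (chrom, bin) pairs
    are canonicalized to the upper triangle under ``chrom_order`` (order of
    first appearance by default). Total binned weight equals the input
    weight sum exactly (to float addition).
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    if pairs.empty:
        return pd.DataFrame(columns=["chrom1", "bin1", "chrom2", "bin2", "weight"])
    if chrom_order is None:
        chrom_order = list(dict.fromkeys(pd.concat([pairs["chrom1"], pairs["chrom2"]])))
    rank = {c: i for i, c in enumerate(chrom_order)}
    c1 = pairs["chrom1"].map(rank).to_numpy()
    c2 = pairs["chrom2"].map(rank).to_numpy()
    b1 = (pairs["pos1"].to_numpy() // resolution).astype(np.int64)
    b2 = (pairs["pos2"].to_numpy() // resolution).astype(np.int64)
    swap = (c1 > c2) | ((c1 == c2) & (b1 > b2))
    c1s = np.where(swap, c2, c1)
    c2s = np.where(swap, c1, c2)
    b1s = np.where(swap, b2, b1)
    b2s = np.where(swap, b1, b2)
    df = pd.DataFrame(
        {
            "chrom1": np.asarray(chrom_order, dtype=object)[c1s],
            "bin1": b1s,
            "chrom2": np.asarray(chrom_order, dtype=object)[c2s],
            "bin2": b2s,
            "weight": pairs["weight"].to_numpy(),
        }
    )
    out = (
        df.groupby(["chrom1", "bin1", "chrom2", "bin2"], as_index=False, sort=True)["weight"]
        .sum()
    )
    return out


def distance_distribution(pairs: pd.DataFrame) -> dict[str, float] | None:
    """Fractions of cis pairs in the contact-distance reporting bins.

    Bins are half-open [low, high); ``None`` when there are no cis pairs.
    """
    d = pairs.loc[pairs["cis"], "distance"].to_numpy()
    if len(d) == 0:
        return None
    out = {}
    for lo, hi in DISTANCE_BINS:
        label = f"<{lo if lo else 150}" if lo == 0 else (f">={lo}" if hi is None else f"{lo}-{hi}")
        sel = (d >= lo) & (d < hi) if hi is not None else d >= lo
        out[label] = float(sel.sum() / len(d))
    return out


def estimate_false_positive(pairs: pd.DataFrame, contaminant_chrom: str = "chrM") -> dict:
    """Hybrid-PET rate: pairs joining the contaminant chromosome to the rest.

    The contaminant (mitochondrial) genome cannot share true spatial contacts
    with nuclear chromatin, so hybrid pairs estimate the random-ligation
    false-positive rate. Returns numerator, denominator and fraction (0 with
    no pairs touching the contaminant).
    """
    is1 = pairs["chrom1"] == contaminant_chrom
    is2 = pairs["chrom2"] == contaminant_chrom
    hybrid = int((is1 ^ is2).sum())
    total = int(len(pairs))
    return {
        "n_hybrid": hybrid,
        "n_pairs": total,
        "rate": (hybrid / total) if total else 0.0,
    }
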