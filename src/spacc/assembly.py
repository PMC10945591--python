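"""From filtered alignment segments to restriction-assigned concatemers.

The reference is digested in silico at the restriction motif (GATC for
DpnII, which cleaves 5' of its site; the motif is its own reverse complement
so a single forward scan suffices). Each aligned segment is assigned to the
fragment containing its alignment midpoint; consecutive-in-read segments on
the same or genomically abutting fragments (cognate-end religation or
incomplete digestion) are collapsed; the remaining ordered segments of one
read form a concatemer.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .io import SEGMENT_COLUMNS, read_fasta

__all__ = [
    "FragmentMap",
    "digest_reference",
    "filter_alignments",
    "assign_fragments",
    "deduplicate_cognate",
    "build_concatemers",
    "cardinality_histogram",
]

log = logging.getLogger(__name__)


@dataclass
class FragmentMap:
    """In-silico restriction fragments tiling each chromosome.

    ``bounds[chrom]`` holds ``[0, cut_1, ..., cut_k, chrom_len]``; fragment
    ``i`` of a chromosome is ``[bounds[i], bounds[i+1])``. Global fragment ids
    increase along the genome in chromosome order.
    """

    chrom_order: list[str]
    bounds: dict[str, np.ndarray]
    offsets: dict[str, int]

    @property
    def n_fragments(self) -> int:
        return sum(len(b) - 1 for b in self.bounds.values())

    def cuts(self, chrom: str) -> np.ndarray:
        return self.bounds[chrom][1:-1]

    def assign(self, chrom: str, position: int) -> int:
        """Global id of the fragment containing ``position``.

        A position exactly on a cut belongs to the fragment starting there.
        """
        if chrom not in self.bounds:
            raise KeyError(f"chromosome {chrom!r} absent from fragment map")
        b = self.bounds[chrom]
        idx = int(np.searchsorted(b, position, side="right")) - 1
        idx = min(max(idx, 0), len(b) - 2)
        return self.offsets[chrom] + idx

    def fragment_interval(self, fragment_id: int) -> tuple[str, int, int]:
        for chrom in self.chrom_order:
            off = self.offsets[chrom]
            n = len(self.bounds[chrom]) - 1
            if off <= fragment_id < off + n:
                i = fragment_id - off
                return chrom, int(self.bounds[chrom][i]), int(self.bounds[chrom][i + 1])
        raise KeyError(f"fragment id {fragment_id} out of range")

    def midpoint(self, fragment_id: int) -> tuple[str, int]:
        chrom, s, e = self.fragment_interval(fragment_id)
        return chrom, (s + e) // 2

    def to_bed(self) -> pd.DataFrame:
        rows = []
        for chrom in self.chrom_order:
            b = self.bounds[chrom]
            off = self.offsets[chrom]
            for i in range(len(b) - 1):
                rows.append((chrom, int(b[i]), int(b[i + 1]), off + i))
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def digest_reference(reference, motif: str = "GATC") -> FragmentMap:
    """In-silico digest: cut at the first base of every motif occurrence.

    ``reference`` is a {chrom: sequence} mapping or a FASTA path.
    """
    seqs = reference if isinstance(reference, Mapping) else read_fasta(reference)
    if not seqs:
        raise ValueError("empty reference")
    pat = re.compile(f"(?={re.escape(motif.upper())})")
    bounds: dict[str, np.ndarray] = {}
    offsets: dict[str, int] = {}
    off = 0
    for chrom, seq in seqs.items():
        if len(seq) == 0:
            raise ValueError(f"empty sequence for {chrom}")
        cuts = np.fromiter((m.start() for m in pat.finditer(seq.upper())), dtype=np.int64)
        cuts = cuts[(cuts > 0) & (cuts < len(seq))]
        bounds[chrom] = np.concatenate([[0], cuts, [len(seq)]]).astype(np.int64)
        offsets[chrom] = off
        off += len(bounds[chrom]) - 1
    return FragmentMap(chrom_order=list(seqs), bounds=bounds, offsets=offsets)


def filter_alignments(
    segments: pd.DataFrame, min_mapq: int = 30, min_len: int = 50
) -> pd.DataFrame:
    """Keep segments with mapq >= min_mapq and length >= min_len."""
    length = segments["end"] - segments["start"]
    keep = (segments["mapq"] >= min_mapq) & (length >= min_len)
    dropped = int((~keep).sum())
    if dropped:
        log.info(
            "filter_alignments: dropped %d/%d segments (mapq<%d: %d, len<%d: %d)",
            dropped,
            len(segments),
            min_mapq,
            int((segments["mapq"] < min_mapq).sum()),
            min_len,
            int((length < min_len).sum()),
        )
    return segments[keep].reset_index(drop=True)


def assign_fragments(segments: pd.DataFrame, fragment_map: FragmentMap) -> pd.DataFrame:
    """Assign each segment to the fragment containing its alignment midpoint."""
    out = segments.copy()
    frag = np.empty(len(out), dtype=np.int64)
    mid = ((out["start"].to_numpy() + out["end"].to_numpy()) // 2).astype(np.int64)
    chroms = out["chrom"].to_numpy()
    for chrom in pd.unique(chroms):
        if chrom not in fragment_map.bounds:
            raise KeyError(f"chromosome {chrom!r} absent from fragment map")
        sel = chroms == chrom
        b = fragment_map.bounds[chrom]
        idx = np.searchsorted(b, mid[sel], side="right") - 1
        idx = np.clip(idx, 0, len(b) - 2)
        frag[sel] = fragment_map.offsets[chrom] + idx
    out["fragment_id"] = pd.array(frag, dtype="Int64")
    return out


def _compatible_cognate(a, b, fragment_map: FragmentMap) -> bool:
    """True when two consecutive-in-read segments look religated/undigested."""
    if a.chrom != b.chrom:
        return False
    fa, fb = int(a.fragment_id), int(b.fragment_id)
    if fa == fb:
        return True
    if abs(fa - fb) != 1:
        return False
    left, right = (a, b) if fa < fb else (b, a)
    shared_cut = int(fragment_map.bounds[a.chrom][int(right.fragment_id) - fragment_map.offsets[a.chrom]])
    return int(left.end) == shared_cut == int(right.start)


def deduplicate_cognate(segments: pd.DataFrame, fragment_map: FragmentMap) -> pd.DataFrame:
    """Collapse consecutive-in-read segments on the same or religated fragments.

    Same-fragment neighbours always merge; neighbours on genomically adjacent
    fragments merge only when their ends abut exactly at the shared cut site
    (re-ligated cognate free ends / incomplete digestion). Non-consecutive
    revisits of a fragment are biological signal and kept. Read order is
    preserved; merged segments are re-assigned by midpoint.
    """
    if segments["fragment_id"].isna().any():
        raise ValueError("fragments must be assigned before cognate collapse")
    out_rows = []
    df = segments.sort_values(["read_id", "read_order"], kind="mergesort")
    for _, group in df.groupby("read_id", sort=False):
        merged = [group.iloc[0].copy()]
        for _, seg in list(group.iterrows())[1:]:
            prev = merged[-1]
            if _compatible_cognate(prev, seg, fragment_map):
                prev["start"] = min(int(prev["start"]), int(seg["start"]))
                prev["end"] = max(int(prev["end"]), int(seg["end"]))
                prev["mapq"] = max(int(prev["mapq"]), int(seg["mapq"]))
                prev["fragment_id"] = fragment_map.assign(
                    prev["chrom"], (int(prev["start"]) + int(prev["end"])) // 2
                )
            else:
                merged.append(seg.copy())
        for new_order, seg in enumerate(merged):
            seg["read_order"] = new_order
            out_rows.append(seg)
    out = pd.DataFrame(out_rows).reset_index(drop=True)
    out = out[SEGMENT_COLUMNS]
    out["fragment_id"] = out["fragment_id"].astype("Int64")
    return out


def build_concatemers(segments: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Attach per-read cardinality and summarize the cardinality histogram.

    Returns the segment table sorted by (read_id, read_order) with a
    ``cardinality`` column, plus a summary with the fraction of reads in the
    reporting bins {1, 2, 3-5, >5}. Singletons are flagged (cardinality 1):
    they are excluded from contact analyses but retained for 1D accessibility.
    """
    if segments.duplicated(subset=["read_id", "read_order"]).any():
        raise ValueError("duplicate (read_id, read_order)")
    df = segments.sort_values(["read_id", "read_order"], kind="mergesort").reset_index(drop=True)
    card = df.groupby("read_id")["read_order"].transform("size")
    df["cardinality"] = card.astype(np.int64)
    per_read = df.drop_duplicates("read_id")["cardinality"]
    summary = {
        "n_reads": int(per_read.size),
        "n_segments": int(len(df)),
        "cardinality_fractions": cardinality_histogram(per_read),
    }
    return df, summary


def cardinality_histogram(cardinalities) -> dict[str, float]:
    """Fractions of reads with cardinality 1, 2, 3-5 and >5."""
    c = np.asarray(cardinalities)
    n = len(c)
    if n == 0:
        return {"1": 0.0, "2": 0.0, "3-5": 0.0, ">5": 0.0}
    return {
        "1": float((c == 1).sum() / n),
        "2": float((c == 2).sum() / n),
        "3-5": float(((c >= 3) & (c <= 5)).sum() / n),
        ">5": float((c > 5).sum() / n),
    }
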