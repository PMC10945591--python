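"""Readers and writers for every on-disk format the pipeline touches.

Dialects (all coordinates 0-based half-open, tab-separated):

* **segment BED** (8 columns): chrom, start, end, read_id, mapq, strand,
  read_order, fragment_id-or-"." — one aligned segment of a chimeric read.
* **methylation TSV** (header + 5 columns): read_id, chrom, pos, context
  (``GpC``/``CpG``), llr — one per-site call, the simplified per-site form of
  a nanopore methylation caller's grouped output (a grouped row maps to one
  record per site in the group). ``pos`` is the forward-strand coordinate of
  the dinucleotide's first base.
* **4DN pairs** with a trailing ``weight`` column, upper-triangle ordered
  under the declared chromosome order.
* **bedGraph** (4 columns) for tiled 1D tracks, and **BED3-6** annotations.

Every writer's output is accepted by its own reader.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "read_segments",
    "write_segments",
    "read_meth_tsv",
    "write_meth_tsv",
    "read_pairs",
    "write_pairs",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
    "read_fasta",
    "write_fasta",
]

SEGMENT_COLUMNS = ["read_id", "chrom", "start", "end", "strand", "mapq", "read_order", "fragment_id"]
METH_COLUMNS = ["read_id", "chrom", "pos", "context", "llr"]
PAIRS_COLUMNS = ["read_id", "chrom1", "pos1", "chrom2", "pos2", "strand1", "strand2", "weight"]


class ParseError(ValueError):
    """Malformed record in an on-disk file; message carries the line number."""


# ---------------------------------------------------------------------------
# segment BED dialect

def _sort_segments(df: pd.DataFrame) -> pd.DataFrame:
    return df.sort_values(["read_id", "chrom", "start"], kind="mergesort").reset_index(drop=True)


def read_segments(path) -> pd.DataFrame:
    """Parse the 8-column segment-BED dialect into a DataFrame."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 8:
                raise ParseError(f"line {lineno}: expected 8 columns, got {len(parts)}")
            chrom, start, end, read_id, mapq, strand, order, frag = parts
            try:
                start, end, mapq, order = int(start), int(end), int(mapq), int(order)
            except ValueError as exc:
                raise ParseError(f"line {lineno}: malformed integer field ({exc})") from None
            if start >= end:
                raise ParseError(f"line {lineno}: start {start} >= end {end}")
            if strand not in "+-":
                raise ParseError(f"line {lineno}: bad strand {strand!r}")
            frag_id = pd.NA if frag == "." else int(frag)
            rows.append((read_id, chrom, start, end, strand, mapq, order, frag_id))
    df = pd.DataFrame(rows, columns=SEGMENT_COLUMNS)
    if df.empty:
        df = _empty_segments()
    df["fragment_id"] = df["fragment_id"].astype("Int64")
    return _sort_segments(df)


def _empty_segments() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "read_id": pd.Series(dtype=str),
            "chrom": pd.Series(dtype=str),
            "start": pd.Series(dtype=np.int64),
            "end": pd.Series(dtype=np.int64),
            "strand": pd.Series(dtype=str),
            "mapq": pd.Series(dtype=np.int64),
            "read_order": pd.Series(dtype=np.int64),
            "fragment_id": pd.Series(dtype="Int64"),
        }
    )


def write_segments(df: pd.DataFrame, path) -> None:
    """Write segments in the 8-column dialect, sorted by read_id then locus."""
    df = _sort_segments(df.copy())
    with open(path, "w") as fh:
        for row in df.itertuples(index=False):
            frag = "." if pd.isna(row.fragment_id) else int(row.fragment_id)
            fh.write(
                f"{row.chrom}\t{int(row.start)}\t{int(row.end)}\t{row.read_id}\t"
                f"{int(row.mapq)}\t{row.strand}\t{int(row.read_order)}\t{frag}\n"
            )


# ---------------------------------------------------------------------------
# methylation-call TSV dialect

def read_meth_tsv(path) -> pd.DataFrame:
    """Parse the 5-column methylation-call TSV (header required)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != METH_COLUMNS:
            raise ParseError(f"line 1: expected header {METH_COLUMNS}, got {header}")
        rows = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise ParseError(f"line {lineno}: expected 5 columns, got {len(parts)}")
            read_id, chrom, pos, context, llr = parts
            if context not in ("GpC", "CpG"):
                raise ParseError(f"line {lineno}: unknown context {context!r}")
            try:
                pos = int(pos)
                llr = float(llr)
            except ValueError as exc:
                raise ParseError(f"line {lineno}: malformed numeric field ({exc})") from None
            rows.append((read_id, chrom, pos, context, llr))
    df = pd.DataFrame(rows, columns=METH_COLUMNS)
    if df.empty:
        df = pd.DataFrame(
            {
                "read_id": pd.Series(dtype=str),
                "chrom": pd.Series(dtype=str),
                "pos": pd.Series(dtype=np.int64),
                "context": pd.Series(dtype=str),
                "llr": pd.Series(dtype=float),
            }
        )
    return df


def write_meth_tsv(df: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(METH_COLUMNS) + "\n")
        for row in df.itertuples(index=False):
            fh.write(f"{row.read_id}\t{row.chrom}\t{int(row.pos)}\t{row.context}\t{row.llr:g}\n")


# ---------------------------------------------------------------------------
# 4DN pairs (+ weight)

def write_pairs(pairs: pd.DataFrame, path, chrom_sizes: Mapping[str, int]) -> None:
    """Write a 4DN ``.pairs`` file with a trailing ``weight`` column.

    ``chrom_sizes`` declares the chromosome order (order of appearance in the
    reference FASTA). Mates are swapped where needed so that
    (chrom1, pos1) <= (chrom2, pos2) under that order.
    """
    order = {c: i for i, c in enumerate(chrom_sizes)}
    df = pairs[PAIRS_COLUMNS].copy() if len(pairs) else pd.DataFrame(columns=PAIRS_COLUMNS)
    for col, pos in (("chrom1", "pos1"), ("chrom2", "pos2")):
        bad = ~df[col].isin(order) if len(df) else pd.Series(dtype=bool)
        if len(df) and bad.any():
            raise ValueError(f"unknown chromosome in pairs: {df.loc[bad, col].iloc[0]!r}")
        if len(df) and (df[pos].to_numpy() > np.array([chrom_sizes[c] for c in df[col]])).any():
            raise ValueError("pair position beyond declared chromosome size")
    if len(df):
        c1 = df["chrom1"].map(order).to_numpy()
        c2 = df["chrom2"].map(order).to_numpy()
        swap = (c1 > c2) | ((c1 == c2) & (df["pos1"].to_numpy() > df["pos2"].to_numpy()))
        for a, b in (("chrom1", "chrom2"), ("pos1", "pos2"), ("strand1", "strand2")):
            av, bv = df[a].to_numpy().copy(), df[b].to_numpy().copy()
            df.loc[swap, a] = bv[swap]
            df.loc[swap, b] = av[swap]
        df["_c1"] = df["chrom1"].map(order)
        df["_c2"] = df["chrom2"].map(order)
        df = df.sort_values(["_c1", "pos1", "_c2", "pos2"], kind="mergesort").drop(columns=["_c1", "_c2"])
    with open(path, "w") as fh:
        fh.write("## pairs format v1.0\n")
        fh.write("#shape: upper triangle\n")
        for chrom, size in chrom_sizes.items():
            fh.write(f"#chromsize: {chrom} {size}\n")
        fh.write("#columns: readID chrom1 pos1 chrom2 pos2 strand1 strand2 weight\n")
        for row in df.itertuples(index=False):
            fh.write(
                f"{row.read_id}\t{row.chrom1}\t{int(row.pos1)}\t{row.chrom2}\t{int(row.pos2)}\t"
                f"{row.strand1}\t{row.strand2}\t{row.weight:.10g}\n"
            )


def read_pairs(path) -> tuple[pd.DataFrame, dict[str, int]]:
    """Read a 4DN pairs file written by :func:`write_pairs`.

    Returns (records, chrom_sizes-in-declared-order).
    """
    chrom_sizes: dict[str, int] = {}
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("#chromsize:"):
                    _, chrom, size = line.split()
                    chrom_sizes[chrom] = int(size)
                continue
            parts = line.split("\t")
            if len(parts) != 8:
                raise ParseError(f"line {lineno}: expected 8 columns, got {len(parts)}")
            rows.append(
                (parts[0], parts[1], int(parts[2]), parts[3], int(parts[4]), parts[5], parts[6], float(parts[7]))
            )
    df = pd.DataFrame(rows, columns=PAIRS_COLUMNS)
    return df, chrom_sizes


# ---------------------------------------------------------------------------
# BED / bedGraph

def read_bed(path) -> pd.DataFrame:
    """Read BED3-6; extra columns beyond 6 are ignored.

    Returns columns chrom, start, end and (when present) name, score, strand.
    """
    rows = []
    ncols = 3
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"line {lineno}: expected >=3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(f"line {lineno}: malformed coordinate ({exc})") from None
            row = [parts[0], start, end] + parts[3:6]
            ncols = max(ncols, 3 + len(parts[3:6]))
            rows.append(row)
    cols = ["chrom", "start", "end", "name", "score", "strand"][:ncols]
    rows = [r + [None] * (ncols - len(r)) for r in rows]
    df = pd.DataFrame(rows, columns=cols)
    if df.empty:
        df = pd.DataFrame({"chrom": pd.Series(dtype=str), "start": pd.Series(dtype=np.int64), "end": pd.Series(dtype=np.int64)})
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    cols = [c for c in ["chrom", "start", "end", "name", "score", "strand"] if c in df.columns]
    with open(path, "w") as fh:
        for row in df[cols].itertuples(index=False):
            fh.write("\t".join(str(v) for v in row) + "\n")


def write_bedgraph(track: pd.DataFrame, path) -> None:
    """Write a 4-column bedGraph; intervals must tile (no overlap per chrom)."""
    df = track.sort_values(["chrom", "start"], kind="mergesort")
    for chrom, sub in df.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        if len(sub) > 1 and (starts[1:] < ends[:-1]).any():
            raise ValueError(f"overlapping bedGraph intervals on {chrom}")
    with open(path, "w") as fh:
        for row in df.itertuples(index=False):
            fh.write(f"{row.chrom}\t{int(row.start)}\t{int(row.end)}\t{row.value:.10g}\n")


def read_bedgraph(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ParseError(f"line {lineno}: expected 4 columns")
            rows.append((parts[0], int(parts[1]), int(parts[2]), float(parts[3])))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> dict[str, str]:
    """Reference sequences as an ordered {name: uppercase sequence} mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(os.fspath(path), "fasta")}


def write_fasta(seqs: Mapping[str, str] | Iterable[tuple[str, str]], path) -> None:
    items = seqs.items() if isinstance(seqs, Mapping) else seqs
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in items]
    SeqIO.write(records, os.fspath(path), "fasta")
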