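"""Synthetic genomes, annotations, concatemers and methylation calls.

The generator emulates a GpC-methyltransferase footprinting + proximity
ligation experiment on a small genome with known ground truth, so every
downstream stage (assembly, single-molecule accessibility calling, bulk peak
calling, contact decomposition, spatial statistics) can be tested without
external data.

Model in brief
--------------
* A random reference (uniform base composition by default) with one
  contaminant chromosome named ``chrM``; GpC/CpG/GCG/GATC site maps are
  scanned directly from the emitted sequence.
* Annotations are planted on a 10-kb slot grid, which guarantees large
  separations between features (orphan CpG islands are automatically >=1 kb
  from enhancers and promoters). Bound CTCF motifs carry two planted
  accessible flanks around a protected core; CpG islands and bound CTCF bins
  are CpG-hypomethylated.
* Reads are multiway concatemers: cardinality is drawn from a configurable
  distribution (defaults shaped to observed pore-C-style splits), segments
  co-occur within a TAD-like block with elevated probability, a configurable
  fraction of segments fails the mapq/length filter, and chrM segments are
  swapped in so that the resulting *pairwise contact* hybrid fraction matches
  ``mito_hybrid_rate``.
* The labeling enzyme acts on each (molecule, accessible region) instance
  with probability ``p_label`` (all-or-none per molecule-region); within a
  labeled region each GpC is methylated with ``p_site_labeled`` (default 1).
  Elsewhere GpC methylation occurs at ``p_background``. Native CpG
  methylation is high outside and low inside CpG islands / bound CTCF bins.
  Emitted log-likelihood ratios are Gaussian around ``llr_meth_mean`` /
  ``llr_unmeth_mean`` so thresholding recovers the binary state >=99% of the
  time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as sio
from .intervals import merge_intervals

__all__ = [
    "SimConfig",
    "ConfigError",
    "Genome",
    "SiteMaps",
    "GroundTruth",
    "SimData",
    "generate_genome",
    "plant_annotations",
    "simulate_concatemers",
    "simulate_meth_calls",
    "simulate_dataset",
    "write_dataset",
]

_SLOT = 10_000  # bp; one planted feature per slot

_DEFAULT_CARDINALITY = {
    1: 0.654,
    2: 0.147,  # printed two-segment share
    3: 0.080,
    4: 0.040,
    5: 0.025,  # 3-5 share = 0.145
    6: 0.022,
    7: 0.013,
    8: 0.008,
    9: 0.006,
    10: 0.005,  # >5 share = 0.054
}


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimConfig:
    """Study conditions for the synthetic experiment.

    Defaults follow the modeled assay: labeling efficiency 0.85 (observed
    range 79-88%), GpC background 0.03, segment length median ~700 bp,
    cardinality split 14.7 / 14.5 / 5.4% for 2 / 3-5 / >5 segments.
    """

    seed: int = 0
    chrom_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"chr1": 2_500_000, "chr2": 2_500_000, "chrM": 20_000}
    )
    contaminant_chrom: str = "chrM"
    # site planting; None -> natural sites of the uniform random sequence
    gpc_density: float | None = None
    cpg_density: float | None = None
    # labeling model
    p_label: float = 0.85
    p_site_labeled: float = 1.0
    p_background: float = 0.03
    cpg_meth_background: float = 0.75
    cpg_meth_active: float = 0.10
    llr_meth_mean: float = 4.0
    llr_unmeth_mean: float = -4.0
    llr_sd: float = 1.0
    # read model
    n_reads: int = 10_000
    cardinality_weights: Mapping[int, float] = field(default_factory=lambda: dict(_DEFAULT_CARDINALITY))
    segment_len_log_mean: float = math.log(700.0)
    segment_len_log_sd: float = 0.45
    segment_len_min: int = 60
    segment_len_max: int = 5_000
    p_intra_block: float = 0.8
    frac_fail_filter: float = 0.05
    mito_hybrid_rate: float = 0.02
    # annotation planting (per Mb of non-contaminant genome)
    ctcf_per_mb: float = 60.0
    ctcf_bound_frac: float = 0.5
    ctcf_protected_halfwidth: int = 50
    ctcf_flank_outer: int = 500
    ctcf_bin_halfwidth: int = 500
    enhancers_per_mb: float = 8.0
    promoters_per_mb: float = 5.0
    element_halfwidth: int = 200
    enhancer_accessible_frac: float = 0.5
    promoter_accessible_frac: float = 0.5
    cgis_per_mb: float = 8.0
    cgi_halfwidth: int = 300
    cgi_class_fracs: tuple[float, float, float] = (0.65, 0.20, 0.15)  # orphan, enhancer-, promoter-proximal
    open_regions_per_mb: float = 6.0
    open_region_len: tuple[int, int] = (100, 1000)
    tad_block_size: int = 500_000
    tad_blocks: Sequence[tuple[str, int, int]] | None = None
    # planted-effect knobs (off by default)
    ocgi_anchor_frac: float = 0.0
    tether_weights: Mapping[str, float] | None = None  # class -> relative weight
    tether_prob: float = 0.8
    ctcf_anchor_frac: float = 0.0
    ctcf_bound_extra_cardinality: int = 0
    ep_anchor_frac: float = 0.0  # reads looping an enhancer to a promoter

    def validate(self) -> None:
        for name in (
            "p_label",
            "p_site_labeled",
            "p_background",
            "cpg_meth_background",
            "cpg_meth_active",
            "p_intra_block",
            "frac_fail_filter",
            "mito_hybrid_rate",
            "ctcf_bound_frac",
            "enhancer_accessible_frac",
            "promoter_accessible_frac",
            "ocgi_anchor_frac",
            "tether_prob",
            "ctcf_anchor_frac",
            "ep_anchor_frac",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if any(size <= 0 for size in self.chrom_sizes.values()):
            raise ConfigError("chromosome sizes must be positive")
        w = np.array(list(self.cardinality_weights.values()), dtype=float)
        if (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
            raise ConfigError("cardinality_weights must be a probability vector")
        for dens in (self.gpc_density, self.cpg_density):
            if dens is not None and not 0.0 <= dens <= 0.2:
                raise ConfigError("site densities must be in [0, 0.2] sites/bp")


@dataclass
class SiteMaps:
    """Per-chromosome dinucleotide/motif positions scanned from the reference.

    Positions are the forward-strand coordinate of the first base. ``gcg_gpc``
    / ``gcg_cpg`` hold the GpC / CpG positions whose trinucleotide context is
    GCG (ambiguous between the two signals; masked downstream).
    """

    gpc: dict[str, np.ndarray]
    cpg: dict[str, np.ndarray]
    gcg_gpc: dict[str, np.ndarray]
    gcg_cpg: dict[str, np.ndarray]
    gatc: dict[str, np.ndarray]


@dataclass
class Genome:
    seqs: dict[str, str]
    sites: SiteMaps

    @property
    def chrom_order(self) -> list[str]:
        return list(self.seqs)

    @property
    def sizes(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.seqs.items()}


@dataclass
class GroundTruth:
    """Planted annotation and accessibility truth."""

    accessible: dict[str, np.ndarray]  # merged (n,2) tracks per chrom
    regions: pd.DataFrame  # chrom, start, end, kind
    ctcf_sites: pd.DataFrame  # chrom, pos, strand, bound
    enhancers: pd.DataFrame  # chrom, start, end
    promoters: pd.DataFrame
    cgis: pd.DataFrame  # chrom, start, end, planted_kind
    low_cpg: dict[str, np.ndarray]
    tad_blocks: list[tuple[str, int, int]]


@dataclass
class SimData:
    config: SimConfig
    genome: Genome
    truth: GroundTruth
    segments: pd.DataFrame  # segment records (pre-filter), io.SEGMENT_COLUMNS order
    calls: pd.DataFrame  # read_id, chrom, pos, context, llr
    call_truth: np.ndarray  # simulated binary state per call row
    segment_truth: pd.DataFrame  # read_id, read_order, accessible


# ---------------------------------------------------------------------------
# genome

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_A, _C, _G, _T = 65, 67, 71, 84


def scan_sites(seqs: Mapping[str, str]) -> SiteMaps:
    """Build GpC/CpG/GCG/GATC site maps directly from sequences."""
    gpc, cpg, gcg_gpc, gcg_cpg, gatc = {}, {}, {}, {}, {}
    for chrom, seq in seqs.items():
        a = np.frombuffer(seq.encode(), dtype=np.uint8)
        gpc[chrom] = np.flatnonzero((a[:-1] == _G) & (a[1:] == _C)).astype(np.int64)
        cpg[chrom] = np.flatnonzero((a[:-1] == _C) & (a[1:] == _G)).astype(np.int64)
        g3 = np.flatnonzero((a[:-2] == _G) & (a[1:-1] == _C) & (a[2:] == _G)).astype(np.int64)
        gcg_gpc[chrom] = g3
        gcg_cpg[chrom] = g3 + 1
        gatc[chrom] = np.flatnonzero(
            (a[:-3] == _G) & (a[1:-2] == _A) & (a[2:-1] == _T) & (a[3:] == _C)
        ).astype(np.int64)
    return SiteMaps(gpc=gpc, cpg=cpg, gcg_gpc=gcg_gpc, gcg_cpg=gcg_cpg, gatc=gatc)


def _scrub_dinucleotides(a: np.ndarray, rng: np.random.Generator) -> None:
    """Remove every GC and CG dinucleotide in place (second base -> A/T)."""
    hits = np.flatnonzero(
        ((a[:-1] == _G) & (a[1:] == _C)) | ((a[:-1] == _C) & (a[1:] == _G))
    )
    if len(hits):
        a[hits + 1] = np.where(rng.random(len(hits)) < 0.5, _A, _T)


def _plant_dinucleotide(a, rng, density, first, second, other):
    """Plant ``first+second`` at ~density sites/bp without creating ``other``."""
    n = int(round(density * len(a)))
    if n == 0:
        return
    cand = rng.choice(np.arange(1, len(a) - 2), size=min(4 * n, len(a) - 3), replace=False)
    cand.sort()
    planted = []
    last = -10
    for i in cand:
        if i - last < 3:
            continue
        if a[i - 1] == other[0] or a[i + 2] == other[1]:
            continue
        planted.append(i)
        last = i
        if len(planted) == n:
            break
    idx = np.asarray(planted, dtype=np.int64)
    a[idx] = first
    a[idx + 1] = second


def generate_genome(config: SimConfig, rng: np.random.Generator | None = None) -> Genome:
    """Emit the reference and its site maps (deterministic for a fixed seed)."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng([config.seed, 0])
    seqs: dict[str, str] = {}
    for chrom, size in config.chrom_sizes.items():
        if size <= 0:
            raise ConfigError(f"zero-length chromosome {chrom}")
        a = _BASES[rng.integers(0, 4, size=size)].copy()
        if config.gpc_density is not None or config.cpg_density is not None:
            _scrub_dinucleotides(a, rng)
            if config.gpc_density:
                # avoid s[i-1]=C (would form CG) and s[i+2]=G (would form CG)
                _plant_dinucleotide(a, rng, config.gpc_density, _G, _C, (_C, _G))
            if config.cpg_density:
                _plant_dinucleotide(a, rng, config.cpg_density, _C, _G, (_G, _C))
        seqs[chrom] = a.tobytes().decode()
    return Genome(seqs=seqs, sites=scan_sites(seqs))


# ---------------------------------------------------------------------------
# annotations

def _n_features(rate_per_mb: float, size: int) -> int:
    return int(round(rate_per_mb * size / 1e6))


def plant_annotations(
    genome: Genome, config: SimConfig, rng: np.random.Generator | None = None
) -> GroundTruth:
    """Plant annotation tracks and accessibility truth on the slot grid."""
    if rng is None:
        rng = np.random.default_rng([config.seed, 1])
    regions = []  # (chrom, start, end, kind, locus_id); CTCF flanks share a locus
    locus_counter = 0
    ctcf_rows, enh_rows, prom_rows, cgi_rows = [], [], [], []
    low_cpg: dict[str, list] = {}
    ph, fo = config.ctcf_protected_halfwidth, config.ctcf_flank_outer
    hw = config.element_halfwidth
    for chrom, size in genome.sizes.items():
        if chrom == config.contaminant_chrom:
            continue
        low_cpg[chrom] = []
        n_slots = size // _SLOT
        counts = {
            "ctcf": _n_features(config.ctcf_per_mb, size),
            "enhancer": _n_features(config.enhancers_per_mb, size),
            "promoter": _n_features(config.promoters_per_mb, size),
            "cgi": _n_features(config.cgis_per_mb, size),
            "open": _n_features(config.open_regions_per_mb, size),
        }
        if sum(counts.values()) > max(0, n_slots - 2):
            raise ConfigError(
                f"{chrom} ({size} bp) too small for requested features ({sum(counts.values())} slots)"
            )
        order = rng.permutation(np.arange(1, n_slots - 1))
        cursor = 0
        for kind, n in counts.items():
            for _ in range(n):
                c = int(order[cursor]) * _SLOT + _SLOT // 2
                cursor += 1
                locus_counter += 1
                if kind == "ctcf":
                    bound = bool(rng.random() < config.ctcf_bound_frac)
                    strand = "+" if rng.random() < 0.5 else "-"
                    ctcf_rows.append((chrom, c, strand, bound))
                    if bound:
                        # one labeling locus: protected core, accessible flanks,
                        # hypomethylated CpGs across the whole bin
                        regions.append((chrom, c - fo, c - ph, "ctcf_flank", locus_counter))
                        regions.append((chrom, c + ph + 1, c + fo + 1, "ctcf_flank", locus_counter))
                        low_cpg[chrom].append((c - config.ctcf_bin_halfwidth, c + config.ctcf_bin_halfwidth))
                elif kind == "enhancer":
                    enh_rows.append((chrom, c - hw, c + hw))
                    if rng.random() < config.enhancer_accessible_frac:
                        regions.append((chrom, c - hw, c + hw, "enhancer", locus_counter))
                elif kind == "promoter":
                    prom_rows.append((chrom, c - hw, c + hw))
                    if rng.random() < config.promoter_accessible_frac:
                        regions.append((chrom, c - hw, c + hw, "promoter", locus_counter))
                elif kind == "cgi":
                    chw = config.cgi_halfwidth
                    k = rng.choice(3, p=np.asarray(config.cgi_class_fracs) / sum(config.cgi_class_fracs))
                    planted_kind = ("orphan", "enhancer_proximal", "promoter_proximal")[int(k)]
                    cgi_rows.append((chrom, c - chw, c + chw, planted_kind))
                    low_cpg[chrom].append((c - chw, c + chw))
                    if planted_kind != "orphan":
                        # companion element 200 bp downstream of the island
                        s = c + chw + 200
                        target = enh_rows if planted_kind == "enhancer_proximal" else prom_rows
                        target.append((chrom, s, s + 2 * hw))
                        frac = (
                            config.enhancer_accessible_frac
                            if planted_kind == "enhancer_proximal"
                            else config.promoter_accessible_frac
                        )
                        if rng.random() < frac:
                            regions.append((chrom, s, s + 2 * hw, planted_kind.split("_")[0], locus_counter))
                else:  # open
                    lo, hi = config.open_region_len
                    length = int(rng.integers(lo, hi + 1))
                    s = c - length // 2
                    regions.append((chrom, s, s + length, "open", locus_counter))
    regions_df = pd.DataFrame(regions, columns=["chrom", "start", "end", "kind", "locus_id"])
    accessible = {
        chrom: merge_intervals(sub[["start", "end"]].to_numpy())
        for chrom, sub in regions_df.groupby("chrom")
    }
    for chrom in genome.chrom_order:
        accessible.setdefault(chrom, np.empty((0, 2), dtype=np.int64))
    blocks = list(config.tad_blocks) if config.tad_blocks is not None else []
    if not blocks:
        for chrom, size in genome.sizes.items():
            if chrom == config.contaminant_chrom:
                continue
            for s in range(0, size, config.tad_block_size):
                blocks.append((chrom, s, min(s + config.tad_block_size, size)))
    return GroundTruth(
        accessible=accessible,
        regions=regions_df.sort_values(["chrom", "start"]).reset_index(drop=True),
        ctcf_sites=pd.DataFrame(ctcf_rows, columns=["chrom", "pos", "strand", "bound"])
        .sort_values(["chrom", "pos"])
        .reset_index(drop=True),
        enhancers=pd.DataFrame(enh_rows, columns=["chrom", "start", "end"])
        .sort_values(["chrom", "start"])
        .reset_index(drop=True),
        promoters=pd.DataFrame(prom_rows, columns=["chrom", "start", "end"])
        .sort_values(["chrom", "start"])
        .reset_index(drop=True),
        cgis=pd.DataFrame(cgi_rows, columns=["chrom", "start", "end", "planted_kind"])
        .sort_values(["chrom", "start"])
        .reset_index(drop=True),
        low_cpg={c: merge_intervals(iv) for c, iv in low_cpg.items()},
        tad_blocks=blocks,
    )


# ---------------------------------------------------------------------------
# concatemers

def _draw_length(rng, config) -> int:
    ln = rng.lognormal(config.segment_len_log_mean, config.segment_len_log_sd)
    return int(np.clip(ln, config.segment_len_min, config.segment_len_max))


def _element_positions(truth: GroundTruth) -> dict[str, pd.DataFrame]:
    els = {
        "ctcf": truth.ctcf_sites.assign(start=lambda d: d["pos"] - 10, end=lambda d: d["pos"] + 10)[
            ["chrom", "start", "end"]
        ],
        "enhancer": truth.enhancers,
        "promoter": truth.promoters,
    }
    return {k: v.reset_index(drop=True) for k, v in els.items()}


def simulate_concatemers(
    genome: Genome,
    truth: GroundTruth,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw multiway reads as ordered genomic segments (alignment-style records).

    Returns a segment-record DataFrame (pre-filter: a configurable fraction of
    segments carries mapq<30 or length<50).
    """
    config.validate()
    if config.n_reads <= 0:
        raise ConfigError("n_reads must be positive")
    if rng is None:
        rng = np.random.default_rng([config.seed, 2])
    cards = np.array(list(config.cardinality_weights), dtype=int)
    probs = np.array(list(config.cardinality_weights.values()), dtype=float)
    card_draw = rng.choice(cards, size=config.n_reads, p=probs)

    blocks = [(c, s, e) for c, s, e in truth.tad_blocks]
    block_len = np.array([e - s for _, s, e in blocks], dtype=float)
    block_p = block_len / block_len.sum() if len(blocks) else None
    nuclear = [c for c in genome.chrom_order if c != config.contaminant_chrom]
    nuc_sizes = np.array([genome.sizes[c] for c in nuclear], dtype=float)
    nuc_p = nuc_sizes / nuc_sizes.sum()

    ocgis = truth.cgis[truth.cgis["planted_kind"] == "orphan"].reset_index(drop=True)
    bound_ctcf = truth.ctcf_sites[truth.ctcf_sites["bound"]].reset_index(drop=True)
    ctcf_any = truth.ctcf_sites.reset_index(drop=True)
    elements = _element_positions(truth)
    tether_classes = list(config.tether_weights) if config.tether_weights else []
    if tether_classes:
        tw = np.array(
            [config.tether_weights[k] * max(len(elements[k]), 1) for k in tether_classes], dtype=float
        )
        tw = tw / tw.sum()

    rows: list[tuple] = []
    for i in range(config.n_reads):
        read_id = f"read{i:06d}"
        card = int(card_draw[i])
        block = None
        anchor = None  # (chrom, center, kind)
        anchor2 = None  # second anchored locus (enhancer-promoter loops)
        if (
            config.ep_anchor_frac
            and card >= 2
            and len(truth.enhancers)
            and len(truth.promoters)
            and rng.random() < config.ep_anchor_frac
        ):
            er = truth.enhancers.iloc[int(rng.integers(len(truth.enhancers)))]
            pr = truth.promoters.iloc[int(rng.integers(len(truth.promoters)))]
            anchor = (er["chrom"], (int(er["start"]) + int(er["end"])) // 2, "ep")
            anchor2 = (pr["chrom"], (int(pr["start"]) + int(pr["end"])) // 2)
        elif config.ocgi_anchor_frac and card >= 2 and len(ocgis) and rng.random() < config.ocgi_anchor_frac:
            r = ocgis.iloc[int(rng.integers(len(ocgis)))]
            anchor = (r["chrom"], (int(r["start"]) + int(r["end"])) // 2, "ocgi")
        elif config.ctcf_anchor_frac and len(ctcf_any) and rng.random() < config.ctcf_anchor_frac:
            r = ctcf_any.iloc[int(rng.integers(len(ctcf_any)))]
            anchor = (r["chrom"], int(r["pos"]), "ctcf")
            if bool(r["bound"]) and config.ctcf_bound_extra_cardinality and card >= 2:
                card += config.ctcf_bound_extra_cardinality
        intra = rng.random() < config.p_intra_block and len(blocks) > 0
        if anchor is not None:
            # anchored reads stay within the anchor's block
            achrom, acenter = anchor[0], anchor[1]
            block = None
            for c, s, e in blocks:
                if c == achrom and s <= acenter < e:
                    block = (c, s, e)
                    break
            intra = block is not None
        elif intra:
            block = blocks[int(rng.choice(len(blocks), p=block_p))]
        for j in range(card):
            length = _draw_length(rng, config)
            if anchor is not None and j == 0:
                chrom, center = anchor[0], anchor[1]
                start = max(0, center - length // 2)
            elif anchor2 is not None and j == 1:
                chrom, center = anchor2
                start = max(0, center - length // 2)
            elif (
                anchor is not None
                and anchor[2] == "ocgi"
                and tether_classes
                and rng.random() < config.tether_prob
            ):
                k = tether_classes[int(rng.choice(len(tether_classes), p=tw))]
                el = elements[k]
                if len(el) == 0:
                    chrom, start = _uniform_segment(rng, blocks, block, intra, nuclear, nuc_p, genome, length)
                else:
                    r = el.iloc[int(rng.integers(len(el)))]
                    chrom = r["chrom"]
                    center = (int(r["start"]) + int(r["end"])) // 2
                    start = max(0, center - length // 2)
            else:
                chrom, start = _uniform_segment(rng, blocks, block if intra else None, intra, nuclear, nuc_p, genome, length)
            size = genome.sizes[chrom]
            start = int(min(start, max(0, size - length)))
            end = min(start + length, size)
            strand = "+" if rng.random() < 0.5 else "-"
            mapq = 60
            if rng.random() < config.frac_fail_filter:
                if rng.random() < 0.5:
                    mapq = int(rng.integers(0, 30))
                else:
                    end = start + int(rng.integers(20, 50))
            rows.append((read_id, chrom, start, end, strand, mapq, j))

    df = pd.DataFrame(rows, columns=["read_id", "chrom", "start", "end", "strand", "mapq", "read_order"])
    df = _insert_mito_hybrids(df, genome, config, rng)
    df["fragment_id"] = pd.array([pd.NA] * len(df), dtype="Int64")
    return df[sio.SEGMENT_COLUMNS]


def _uniform_segment(rng, blocks, block, intra, nuclear, nuc_p, genome, length):
    if intra and block is not None:
        chrom, s, e = block
        start = int(rng.integers(s, max(s + 1, e - length)))
    else:
        chrom = nuclear[int(rng.choice(len(nuclear), p=nuc_p))]
        start = int(rng.integers(0, max(1, genome.sizes[chrom] - length)))
    return chrom, start


def _insert_mito_hybrids(df, genome, config, rng):
    """Swap chrM segments into reads so hybrid pairs ~= rate x total pairs."""
    if config.mito_hybrid_rate == 0:
        return df
    chrom_m = config.contaminant_chrom
    if chrom_m not in genome.sizes:
        raise ConfigError("contaminant chromosome absent from genome")
    keep = (df["mapq"] >= 30) & ((df["end"] - df["start"]) >= 50)
    surv = df[keep].groupby("read_id").size()
    total_pairs = float((surv * (surv - 1) // 2).sum())
    target = int(round(config.mito_hybrid_rate * total_pairs))
    eligible = surv[surv >= 2].index.to_numpy()
    eligible = eligible[rng.permutation(len(eligible))]
    msize = genome.sizes[chrom_m]
    got = 0
    chosen: list[tuple[str, int]] = []  # (read_id, row index to replace)
    surviving_idx = df.index[keep]
    by_read = pd.Series(surviving_idx, index=df.loc[surviving_idx, "read_id"])
    for rid in eligible:
        if got >= target:
            break
        k = int(surv[rid])
        idxs = by_read.loc[[rid]].to_numpy()
        chosen.append((rid, int(idxs[int(rng.integers(len(idxs)))])))
        got += k - 1
    for _, ridx in chosen:
        length = min(_draw_length(rng, config), msize - 1)
        length = max(length, 50)
        start = int(rng.integers(0, max(1, msize - length)))
        df.loc[ridx, ["chrom", "start", "end", "mapq"]] = [chrom_m, start, start + length, 60]
    return df


# ---------------------------------------------------------------------------
# methylation calls

def _point_in_track(pos: np.ndarray, track: np.ndarray) -> np.ndarray:
    if len(track) == 0:
        return np.zeros(len(pos), dtype=bool)
    idx = np.searchsorted(track[:, 0], pos, side="right") - 1
    ok = idx >= 0
    out = np.zeros(len(pos), dtype=bool)
    out[ok] = pos[ok] < track[idx[ok], 1]
    return out


def simulate_meth_calls(
    genome: Genome,
    truth: GroundTruth,
    segments: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, np.ndarray, pd.DataFrame]:
    """Emit per-site methylation calls for every segment.

    Returns ``(calls, call_truth, segment_truth)``: the call records
    (read_id, chrom, pos, context, llr), the simulated binary state per call,
    and the per-segment realized accessibility flag (>=1 enzyme-labeled
    accessible-region overlap containing >=1 GpC site).
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng([config.seed, 3])
    sites = genome.sites
    # per-chrom sorted, non-overlapping truth regions with their locus ids:
    # the enzyme acts (or fails) once per molecule-locus, so regions sharing a
    # locus (the two flanks of a bound CTCF site) share the labeling draw
    reg_by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    if len(truth.regions):
        for chrom, sub in truth.regions.sort_values(["chrom", "start"]).groupby("chrom"):
            reg_by_chrom[chrom] = (
                sub["start"].to_numpy(dtype=np.int64),
                sub["end"].to_numpy(dtype=np.int64),
                sub["locus_id"].to_numpy(dtype=np.int64),
            )
    col_read: list[np.ndarray] = []
    col_chrom: list[np.ndarray] = []
    col_pos: list[np.ndarray] = []
    col_ctx: list[np.ndarray] = []
    col_llr: list[np.ndarray] = []
    truth_bits: list[np.ndarray] = []
    seg_rows = []
    for row in segments.itertuples(index=False):
        chrom = row.chrom
        if chrom not in sites.gpc:
            raise ConfigError(f"missing site map for {chrom}")
        s, e = int(row.start), int(row.end)
        gpc = sites.gpc[chrom]
        lo, hi = np.searchsorted(gpc, (s, e))
        gpos = gpc[lo:hi]
        p_site = np.full(len(gpos), config.p_background)
        accessible = False
        if chrom in reg_by_chrom:
            rs_all, re_all, loci = reg_by_chrom[chrom]
            j0 = np.searchsorted(re_all, s, side="right")
            j1 = np.searchsorted(rs_all, e, side="left")
            labeled_locus: dict[int, bool] = {}
            for j in range(j0, j1):
                locus = int(loci[j])
                if locus not in labeled_locus:
                    labeled_locus[locus] = rng.random() < config.p_label
                if labeled_locus[locus]:
                    inside = (gpos >= rs_all[j]) & (gpos < re_all[j])
                    p_site[inside] = config.p_site_labeled
                    if inside.any():
                        accessible = True
        gmeth = rng.random(len(gpos)) < p_site
        cpg = sites.cpg[chrom]
        lo, hi = np.searchsorted(cpg, (s, e))
        cpos = cpg[lo:hi]
        low = _point_in_track(cpos, truth.low_cpg.get(chrom, np.empty((0, 2), dtype=np.int64)))
        cp = np.where(low, config.cpg_meth_active, config.cpg_meth_background)
        cmeth = rng.random(len(cpos)) < cp
        pos = np.concatenate([gpos, cpos])
        meth = np.concatenate([gmeth, cmeth])
        ctx = np.concatenate([np.repeat("GpC", len(gpos)), np.repeat("CpG", len(cpos))])
        llr = np.where(
            meth,
            rng.normal(config.llr_meth_mean, config.llr_sd, len(pos)),
            rng.normal(config.llr_unmeth_mean, config.llr_sd, len(pos)),
        )
        col_read.append(np.full(len(pos), row.read_id, dtype=object))
        col_chrom.append(np.full(len(pos), chrom, dtype=object))
        col_pos.append(pos)
        col_ctx.append(ctx)
        col_llr.append(llr)
        truth_bits.append(meth)
        seg_rows.append((row.read_id, int(row.read_order), accessible))
    if col_pos:
        calls = pd.DataFrame(
            {
                "read_id": np.concatenate(col_read),
                "chrom": np.concatenate(col_chrom),
                "pos": np.concatenate(col_pos).astype(np.int64),
                "context": np.concatenate(col_ctx),
                "llr": np.concatenate(col_llr),
            }
        )
        call_truth = np.concatenate(truth_bits)
    else:
        calls = pd.DataFrame(columns=["read_id", "chrom", "pos", "context", "llr"])
        call_truth = np.zeros(0, dtype=bool)
    # drop duplicate (read, site, context) rows from genomically overlapping
    # segments of the same read: a caller reports each read-site once
    dup = calls.duplicated(subset=["read_id", "chrom", "pos", "context"])
    if dup.any():
        calls = calls[~dup].reset_index(drop=True)
        call_truth = call_truth[~dup.to_numpy()]
    seg_truth = pd.DataFrame(seg_rows, columns=["read_id", "read_order", "accessible"])
    return calls, call_truth, seg_truth


# ---------------------------------------------------------------------------
# orchestration

def simulate_dataset(config: SimConfig) -> SimData:
    """Run the full generator: genome -> annotations -> reads -> calls."""
    config.validate()
    genome = generate_genome(config)
    truth = plant_annotations(genome, config)
    segments = simulate_concatemers(genome, truth, config)
    calls, call_truth, seg_truth = simulate_meth_calls(genome, truth, segments, config)
    return SimData(
        config=config,
        genome=genome,
        truth=truth,
        segments=segments,
        calls=calls,
        call_truth=call_truth,
        segment_truth=seg_truth,
    )


def write_dataset(sim: SimData, outdir) -> dict[str, Path]:
    """Write the generated inputs and truth tracks as plain-text files."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out / "genome.fa",
        "segments": out / "segments.bed",
        "meth": out / "meth_calls.tsv",
        "accessible": out / "truth_accessible.bed",
        "ctcf": out / "ctcf_sites.bed",
        "enhancers": out / "enhancers.bed",
        "promoters": out / "promoters.bed",
        "cgis": out / "cgis.bed",
    }
    sio.write_fasta(sim.genome.seqs, paths["fasta"])
    sio.write_segments(sim.segments, paths["segments"])
    sio.write_meth_tsv(sim.calls, paths["meth"])
    sio.write_bed(sim.truth.regions.rename(columns={"kind": "name"}), paths["accessible"])
    ctcf = sim.truth.ctcf_sites.assign(
        start=lambda d: d["pos"],
        end=lambda d: d["pos"] + 1,
        name=lambda d: np.where(d["bound"], "bound", "unbound"),
        score=0,
    )[["chrom", "start", "end", "name", "score", "strand"]]
    sio.write_bed(ctcf, paths["ctcf"])
    sio.write_bed(sim.truth.enhancers, paths["enhancers"])
    sio.write_bed(sim.truth.promoters, paths["promoters"])
    sio.write_bed(sim.truth.cgis.rename(columns={"planted_kind": "name"}), paths["cgis"])
    return paths
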