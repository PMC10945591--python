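"""End-to-end driver: synthetic dataset -> every downstream analysis.

Used by the examples, the acceptance script and the determinism checks.
All randomness flows from ``SimConfig.seed`` (simulation) plus the config
seed reused for the seeded tethering control, so a fixed configuration
reproduces byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import accessibility as acc
from . import assembly, contacts, peaks, spatial
from . import io as sio
from .simulate import SimConfig, SimData, simulate_dataset

__all__ = ["PipelineResult", "run_pipeline", "write_outputs"]


@dataclass
class PipelineResult:
    sim: SimData
    fragment_map: assembly.FragmentMap
    concatemers: pd.DataFrame  # filtered, fragment-assigned, cognate-collapsed
    assembly_summary: dict
    calls: pd.DataFrame  # site-called, masked, segment-assigned (pre-denoise)
    regions: pd.DataFrame
    denoised_calls: pd.DataFrame
    segment_labels: pd.DataFrame
    efficiency: acc.EfficiencyEstimate
    pairs: pd.DataFrame
    track: pd.DataFrame
    peaks: pd.DataFrame
    concatemer_classes: pd.DataFrame
    footprints: pd.DataFrame
    extras: dict = field(default_factory=dict)


def run_pipeline(
    config: SimConfig,
    params: acc.AccessibilityParams | None = None,
    peak_params: peaks.PeakParams | None = None,
) -> PipelineResult:
    params = params or acc.AccessibilityParams()
    peak_params = peak_params or peaks.PeakParams()
    sim = simulate_dataset(config)

    fragment_map = assembly.digest_reference(sim.genome.seqs)
    kept = assembly.filter_alignments(sim.segments)
    assigned = assembly.assign_fragments(kept, fragment_map)
    collapsed = assembly.deduplicate_cognate(assigned, fragment_map)
    concatemers, summary = assembly.build_concatemers(collapsed)

    calls = acc.call_sites(sim.calls, params)
    calls = acc.mask_gcg(calls, sim.genome.sites)
    calls = acc.assign_calls_to_segments(calls, concatemers)
    regions = acc.call_accessible_regions(calls, concatemers, params)
    denoised = acc.denoise(calls, regions)
    counts = acc.segment_counts(calls, concatemers)
    labels = acc.classify_segments(counts, params)
    efficiency = acc.estimate_labeling_efficiency(labels, sim.truth.ctcf_sites)

    multi = concatemers[concatemers["cardinality"] >= 2]
    pairs = contacts.decompose_all(multi, fragment_map)

    track = peaks.accessibility_track(calls, peak_params)
    called_peaks = peaks.call_peaks(track, peak_params)

    classes = spatial.concatemer_fraction(labels)
    footprints = spatial.detect_footprints(concatemers, regions, sim.truth.ctcf_sites)

    return PipelineResult(
        sim=sim,
        fragment_map=fragment_map,
        concatemers=concatemers,
        assembly_summary=summary,
        calls=calls,
        regions=regions,
        denoised_calls=denoised,
        segment_labels=labels,
        efficiency=efficiency,
        pairs=pairs,
        track=track,
        peaks=called_peaks,
        concatemer_classes=classes,
        footprints=footprints,
    )


def run_bulk_peaks(
    config: SimConfig,
    params: acc.AccessibilityParams | None = None,
    peak_params: peaks.PeakParams | None = None,
):
    """Lean bulk peak-calling path: simulate -> filter -> pooled track -> peaks.

    Skips the per-molecule stages (regions, labels, contacts) so deep-coverage
    peak-recovery scenarios stay within memory and time budgets. Returns
    (sim, track, peaks).
    """
    params = params or acc.AccessibilityParams()
    peak_params = peak_params or peaks.PeakParams()
    sim = simulate_dataset(config)
    kept = assembly.filter_alignments(sim.segments)
    calls = acc.call_sites(sim.calls, params)
    calls = acc.mask_gcg(calls, sim.genome.sites)
    calls = acc.assign_calls_to_segments(calls, kept)
    track = peaks.accessibility_track(calls, peak_params)
    called = peaks.call_peaks(track, peak_params)
    return sim, track, called


def write_outputs(result: PipelineResult, outdir) -> dict[str, Path]:
    """Write the main pipeline products as plain-text files."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    sizes = result.sim.genome.sizes
    paths = {
        "concatemers": out / "concatemers.bed",
        "regions": out / "accessible_regions.bed",
        "labels": out / "segment_labels.tsv",
        "pairs": out / "contacts.pairs",
        "peaks": out / "peaks.bed",
        "track": out / "accessibility.bedgraph",
        "classes": out / "concatemer_classes.tsv",
        "footprints": out / "ctcf_footprints.tsv",
    }
    sio.write_segments(result.concatemers[sio.SEGMENT_COLUMNS], paths["concatemers"])
    regions = result.regions.assign(name=lambda d: d["read_id"] + ":" + d["read_order"].astype(str))
    sio.write_bed(regions[["chrom", "start", "end", "name"]], paths["regions"])
    result.segment_labels.to_csv(paths["labels"], sep="\t", index=False)
    sio.write_pairs(result.pairs, paths["pairs"], sizes)
    pk = result.peaks.assign(
        name=[f"peak{i}" for i in range(len(result.peaks))],
        score=lambda d: d["ratio"].astype(float).round(4),
    )
    sio.write_bed(pk[["chrom", "start", "end", "name", "score"]], paths["peaks"])
    sio.write_bedgraph(peaks.track_to_bedgraph(result.track), paths["track"])
    result.concatemer_classes.to_csv(paths["classes"], sep="\t", index=False)
    result.footprints.to_csv(paths["footprints"], sep="\t", index=False)
    return paths
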