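# spacc — single-molecule spatial chromatin accessibility

`spacc` analyzes experiments that combine **GpC-methyltransferase
footprinting** with **multiway proximity ligation** (pore-C-style) on
nanopore reads. One chimeric read is a *concatemer*: an ordered list of
genomic segments that were spatially co-located in the nucleus. Because the
methyltransferase (M.CviPI) deposits GpC methylation only on accessible
chromatin before digestion and ligation, every segment simultaneously
carries (i) its locus, (ii) its single-molecule accessibility state and
(iii) its native CpG methylation — so chromatin accessibility can be
resolved *per molecule, in its three-dimensional context*, rather than as a
population average.

The package is the computational half of such an assay:

* **synthetic data** (`spacc.simulate`) — a generator for genomes,
  annotations, concatemers and methylation-caller output with known ground
  truth (planted accessible regions, labeling efficiency, contact
  structure, a `chrM` contaminant);
* **assembly** (`spacc.assembly`) — mapq ≥ 30 / length ≥ 50 filtering,
  in-silico DpnII digest (GATC), midpoint fragment assignment, cognate-end
  collapse, concatemer construction;
* **single-molecule accessibility** (`spacc.accessibility`) — LLR
  thresholding (GpC > 1, CpG > 1.5), GCG-context masking, 50 bp / 10 bp
  sliding-window right-tailed exact binomial detection of accessible
  regions against the 0.03 GpC background, denoising, and trinary segment
  classification (see below);
* **bulk peaks** (`spacc.peaks`) — nanoNOMe-style population peak calling
  (200 bp / 20 bp windows, 99th-percentile candidates, exact binomial vs
  the global ratio, BH, p_adj < 0.001, width > 50 bp) plus overlap
  evaluation against reference peak sets;
* **contacts** (`spacc.contacts`) — decomposition of an *n*-segment
  concatemer into all C(n,2) virtual paired-end tags with weight
  **w = 1/2^k**, where *k* is the number of segments between the two mates
  in read order; binning to a sparse upper-triangular matrix; the
  mitochondrial hybrid-PET false-positive proxy;
* **spatial statistics** (`spacc.spatial`) — per-concatemer accessible
  fraction N_acc/(N_acc+N_inacc) and classes (< 0.1 inaccessible, > 0.9
  accessible, hybrid in between), CTCF footprint calls
  (accessible–protected–accessible), enhancer–promoter contact typing
  (A–A / A–I / I–I), orphan-CGI classification (≥ 1 kb from enhancers and
  promoters) and tethering profiles.

## The segment classification model

Each segment with GpC sites is assigned a trinary state by two one-sided
exact binomial tests. With *n* masked GpC sites, *m* methylated:

1. **accessible** — requires m ≥ 4; test H₀: rate ≤ p₀ = 0.03 (the GpC
   frequency of unlabeled DNA), i.e. p = P(X ≥ m | n, 0.03); BH across all
   tested segments, adjusted p < 0.05;
2. **inaccessible** — among the remainder, test the unmethylated count
   against p₁ = 0.3 (the unlabeled-GpC frequency of the M.CviPI-treated
   spike-in): p = P(X ≥ n−m | n, 0.3); BH, adjusted p < 0.05;
3. otherwise **undetermined**, excluded from downstream fractions.

Labeling efficiency is estimated from 1000 bp bins centered on CTCF motifs:
segments there with low native CpG methylation (ratio < 0.25) are expected
to be accessible in vivo; among them, a GpC ratio < 0.1 marks a labeling
failure, and efficiency = 1 − failures/total.

## Worked example

```python
from spacc import contacts
from spacc.pipeline import run_pipeline
from spacc.simulate import SimConfig

config = SimConfig(
    seed=0,
    chrom_sizes={"chr1": 700_000, "chr2": 300_000, "chrM": 20_000},
    n_reads=4_000,
)
res = run_pipeline(config)
print(res.assembly_summary["cardinality_fractions"])
print(res.segment_labels["state"].value_counts().to_dict())
print(res.efficiency.efficiency)
print(contacts.estimate_false_positive(res.pairs))
```

prints (see `examples/` for the narrated versions):

```
{'1': 0.665, '2': 0.148, '3-5': 0.142, '>5': 0.044}
{'inaccessible': 6556, 'accessible': 392, 'undetermined': 3}
0.8817204301075269
{'n_hybrid': 144, 'n_pairs': 7130, 'rate': 0.0202}
```

Reading: two thirds of reads are singletons and the multiway remainder
splits ≈ 15 / 14 / 4% across cardinalities 2 / 3–5 / >5, matching the
configured mixture; most segments are confidently closed chromatin with a
minority of accessible segments; the labeling-efficiency estimator recovers
the configured 0.85 enzyme efficiency from 93 CTCF-bin segments; and the
chrM hybrid-PET rate reproduces the configured 0.02 random-ligation rate.

A command-line interface mirrors the library
(`spacc simulate | assemble | callacc | peaks | contacts | stats | convert`);
run `spacc --help`.

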