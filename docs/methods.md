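# Methods

This note documents the models, parameters, numerical choices and known
limitations of `spacc`. It is written for users deciding whether the
package's assumptions fit their data and for developers extending it.

## Assay model

A fixed nucleus is treated with the GpC methyltransferase M.CviPI, which
methylates GpC dinucleotides on accessible chromatin only; chromatin is
then digested with DpnII (GATC), spatially proximal fragments are ligated
into chimeric molecules (concatemers), and the molecules are nanopore
sequenced. A methylation caller emits a log-likelihood ratio (LLR) per
GpC/CpG site per read. The package consumes (1) alignment-derived segment
records of the chimeric reads, (2) per-site LLR calls, (3) the reference
FASTA, and (4) annotation BEDs (CTCF motifs, enhancers, promoters, CpG
islands). It does not perform basecalling, alignment, or methylation
calling itself.

Coordinates are 0-based half-open everywhere; dinucleotide calls are
collapsed to the forward-strand coordinate of the first base, matching how
site maps are scanned from the reference.

## Single-molecule accessibility

**Site calling.** Methylated GpC iff LLR > 1; methylated CpG iff
LLR > 1.5; strict inequalities. Both thresholds are configurable
(`AccessibilityParams.gpc_llr`, `cpg_llr`).

**GCG masking.** In GCG trinucleotide context a methylated cytosine cannot
be attributed to the GpC (accessibility) or CpG (endogenous) signal, so
such sites are flagged and excluded from every numerator and denominator.
On a uniform-composition synthetic genome this removes 25% of GpCs and 25%
of CpGs; real genomes, being CpG-depleted, lose less (the GpC loss there is
around 6%).

**Window detection.** Per segment, 50 bp windows at 10 bp steps anchored at
the segment's genomic start (anchoring at the segment start keeps the scan
deterministic and molecule-independent); the final partial window is kept.
Windows with no GpC observation are skipped. Each window gets a
right-tailed exact binomial p-value for its methylated count against the
background rate `p_background = 0.03` (the average GpC frequency of
untreated DNA); a window passes at uncorrected p < 0.05 — correction is
applied at the segment and peak levels, where families of tests are
well-defined, not per window. Passing windows containing ≥ 2 GpC sites are
unioned (overlapping or abutting) into per-molecule accessible regions;
a region narrower than one window (possible only from a partial terminal
window) is discarded. Methylated GpC calls outside every region of the
molecule are then reset ("denoised"); CpG calls are never altered.

**Segment classification.** Counts use masked but *pre-denoise* calls:
denoising is derived from the window test, and reusing it would make the
two binomial analyses circular (configurable). The accessible test
requires ≥ 4 methylated GpCs and tests against 0.03; the inaccessible test,
applied to the remainder, tests the unmethylated count against
`p_unlabeled = 0.3`, the unmethylated-GpC frequency observed on fully
accessible spike-in DNA — i.e. the enzyme's per-site miss rate. (The
related in-vivo inefficiency estimate of 21% is available via
configuration; 0.3 is the default because the test is defined against the
spike-in measurement.) Both stages are BH-corrected at 0.05; accessible
takes precedence; everything else is reported as `undetermined` rather
than dropped so that downstream denominators remain auditable.

**Labeling efficiency.** Segments overlapping 1000 bp bins centered on
CTCF motifs and showing low native CpG methylation (ratio < 0.25) are
taken as expected-accessible in vivo; among them a GpC ratio < 0.1 marks a
molecule the enzyme missed. The denominator is restricted to the low-CpG
subset — without that restriction the estimator would track the fraction
of CTCF motifs actually occupied rather than enzyme efficiency.

## Bulk peak calling

Pooled pre-denoise masked GpC calls are tallied into 200 bp windows on a
20 bp grid. Windows above the 99th percentile of window ratios (linear
interpolation, strictly greater) are candidates; each candidate is tested
one-tailed against the global methylation ratio, BH-corrected; passing
windows are merged and peaks kept at p_adj < 0.001 (minimum constituent
window value — conservative and monotone under merging) and width > 50 bp.

Two regimes of this procedure deserve note. The percentile step assumes
genuinely accessible windows fill roughly the top percentile: when the
accessible fraction is far below 1%, the cut drops into the null
distribution and the selected tail defeats the BH correction
(anti-conservative); when it is far above 1%, true regions are crowded out
of the candidate set and recall falls. At shallow coverage a third
degeneracy appears: many single-observation windows have ratio 1.0, the
99th percentile saturates at 1.0, and the strictly-greater rule yields no
candidates at all. The peak caller is therefore exercised (tests and
acceptance) at deep pooled coverage (~13×) with planted accessible regions
covering ~1% of the genome — the regime the procedure is designed for —
where it recovers planted regions with recall and precision 1.0.

## Contacts

An *n*-segment concatemer yields all C(n,2) unordered pairs; a pair whose
mates have *k* segments between them in read order gets weight 2^(−k), so
adjacent mates weigh 1. This down-weights the quadratic over-representation
that plain decomposition introduces relative to two-locus assays. Pair
coordinates are assigned restriction-fragment midpoints (fragment-level
resolution, ~260 bp on the synthetic genome). Read order, not genomic
order, defines *k*; decomposition is invariant to reversing the read.
Weights are conserved exactly through matrix binning. Pairs are exported
as 4DN `.pairs` (upper triangle under the FASTA chromosome order) with a
trailing `weight` column; compartment/insulation/loop analyses are
delegated to standard contact-matrix tools.

Pairs with exactly one mate on the mitochondrial contaminant estimate the
random-ligation false-positive rate, since chrM cannot share true spatial
contacts with nuclear chromatin.

## Synthetic data generator

The generator emulates the study conditions, not a particular dataset.

* **Genome** — uniform iid bases per chromosome (so GpC/CpG densities are
  ~1/16 sites per bp and GATC occurs every ~256 bp); one contaminant
  chromosome named `chrM`. Optional `gpc_density` / `cpg_density`
  overrides scrub all GC/CG dinucleotides and re-plant them at the
  requested rate.
* **Annotations** — one feature per 10 kb slot (shuffled), which
  guarantees ≥ 8 kb between features; orphan CpG islands are therefore
  ≥ 1 kb from every enhancer/promoter by construction. Defaults per Mb:
  60 CTCF motifs (50% bound), 8 enhancers, 5 promoters, 8 CpG islands
  (65/20/15% orphan / enhancer-proximal / promoter-proximal), 6 open
  regions of 100–1000 bp. The CTCF density is higher than genome-realistic
  so the efficiency estimator sees a few hundred qualifying segments at
  the modeled depth.
* **Accessibility truth** — open regions, half of enhancers/promoters, and
  two 450 bp flanks around each bound CTCF motif separated by a 100 bp
  protected core. The core is wider than the ~50 bp footprint of real
  CTCF so that a 50 bp/10 bp window scan can resolve the
  accessible–protected–accessible pattern; real footprints at the 50 bp
  scale are under-called by this window size (single-molecule footprint
  recall on synthetic bound sites is ~0.5, with zero false footprints at
  unbound sites).
* **CpG methylation** — high background (0.75) with hypomethylation (0.10)
  inside CpG islands and bound-CTCF bins. The assay's source publications
  do not specify a native methylation model; both rates are free
  parameters.
* **Reads** — cardinality drawn from a configurable mixture whose default
  reproduces the observed multiway split (14.7% two-segment, 14.5% with
  3–5, 5.4% with > 5, remainder singletons); segments co-occur within a
  500 kb TAD-like block with probability 0.8; segment lengths are
  log-normal with median 700 bp; 5% of segments are corrupted to fail the
  mapq/length filter. Optional planted effects (all off by default):
  enhancer–promoter looping reads, orphan-CGI anchored reads with
  class-weighted tethering, and extra cardinality on bound-CTCF
  concatemers.
* **Labeling** — the enzyme acts *per molecule-locus*: for each (segment,
  accessibility locus) pair one Bernoulli(p_label = 0.85) draw decides
  whether that locus on that molecule is labeled (the two flanks of one
  CTCF site share the draw); within a labeled locus every GpC is
  methylated (`p_site_labeled = 1.0`, configurable), elsewhere GpCs are
  methylated at `p_background = 0.03`. The all-or-none form mirrors how
  enzyme accessibility fails per molecule and is what makes per-segment
  labeling failures — and hence the efficiency estimator — well-defined;
  the marginal per-site rate in accessible truth is p_label + (1 −
  p_label)·p_background. Convergence tests therefore use cluster-level
  (locus-instance) confidence intervals rather than per-site binomial ones.
* **LLRs** — Gaussian around ±4 with unit scale, giving ≥ 99% concordance
  between thresholded and simulated states.
* **chrM hybrids** — chrM segments are swapped into filter-surviving
  multiway reads until the hybrid *pair* count reaches `mito_hybrid_rate`
  × the total pair count, so the pair-level estimator recovers the
  configured rate by construction.

What the generator does **not** emulate: sequence-composition bias, read
errors and mapping ambiguity, CpG-depleted genome composition,
chromosome-territory or compartment structure beyond uniform TAD-like
blocks, fragment-boundary effects of real digestion, and caller LLR
distributions conditioned on sequence context. Passing tests demonstrate
that the statistical machinery recovers known truth under these idealized
conditions, not that real-data performance matches.

## Problem sizes

The reference conditions are 10,000 reads on a 5 Mb genome (≈ 2.6×
pooled coverage, ≈ 18,000 segments, ≈ 20,000 weighted pairs) for parameter
recovery (efficiency ± 0.05, classification accuracy ≥ 0.95, hybrid rate
within its 95% CI); a 1 Mb genome at the same read count (~13×) with 20
planted regions for bulk-peak recovery; and a 1.5 Mb genome with planted
enhancer–promoter loops and oCGI tethering for the spatial statistics.
These sizes were chosen so each estimator's sampling error is comfortably
inside its acceptance band on a single CPU.

## Numerical choices

Exact binomial tails come from `scipy.stats.binom.sf` (agrees with
exhaustive outcome enumeration to < 1e−12 for n ≤ 12); BH from
`statsmodels.stats.multitest`; percentiles from `numpy.percentile`
(linear interpolation). Interval bookkeeping uses sorted merged arrays
with `searchsorted` queries, property-tested against bitmap oracles. All
comparisons at published cutoffs are strict, matching their quoted forms.
Ties and degenerate inputs: a segment with zero GpC sites is
`undetermined` (never an error); an empty pair set yields a header-only
pairs file; an all-identical ratio track yields no peaks (no window is
strictly above the 99th percentile); a midpoint exactly on a restriction
cut belongs to the fragment starting there; merging of cognate segments
applies only to consecutive-in-read segments abutting at the shared cut —
distal revisits of a fragment are biological signal and kept; whether the
length filter applies before cognate collapse is configurable (default:
before, on raw alignments).

## Known limitations

* The window scan under-calls footprints narrower than the window (see
  above); a haplotype- or HMM-based caller would do better at the 50 bp
  scale.
* The bulk peak caller inherits the percentile-candidate design's
  sensitivity to the true accessible fraction and to coverage depth
  (analysis above); it is not a general-purpose peak caller.
* E–P contact typing uses segment-level annotation overlap; fragment-level
  overlap would be slightly more conservative.
* The efficiency estimator conflates enzyme failure with genuine
  cell-to-cell closure at CTCF sites; on real data it is an upper bound on
  the failure rate.
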