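# Methods

## Coordinate and read model

All coordinates are 0-based half-open (BED convention); GTF input (1-based
inclusive) is converted at the parser boundary. Two intervals overlap when
they share at least one base; abutting intervals do not. A fragment record
is one sequenced pair `(chrom, start, end)` with `end − start ≤ 2000`
(fragments longer than a plausible paired-end insert are rejected at
load). The two mate read intervals are reconstructed from the fragment
ends with a fixed read length (default 75 bp): `[start, min(start+rl, end))`
and `[max(end−rl, start), end)` — mates never extend past the opposite
fragment end. Duplicates are defined by an identical fragment triple;
for proper pairs this coincides with keying on both mates' 5′ positions.
The first record in file order is kept.

## Metric definitions and conventions

* **FRiP** counts mate read intervals (two per pair) against a merged
  reference, after deduplication and removal of mitochondrial reads. A
  documented switch counts whole fragments instead (default off).
* **TSS enrichment** aggregates read-span coverage over a ±2000 bp window
  per TSS. Minus-strand windows are mirrored around the TSS base so
  "upstream" is orientation-consistent, and offset 0 is the TSS base on
  either strand. The aggregate profile is normalized by the mean of the
  100 outermost bases at each end (200 bases total). The score is the
  maximum of the normalized profile at offsets −200…−1. Canonical
  ENCODE-style tooling instead takes the maximum near the window center;
  both conventions are implemented (`window="upstream200"`, the default,
  or `"centered200"`) and differ little on realistic profiles because the
  insertion peak abuts the TSS. A zero flank mean raises an explicit
  undefined-metric error rather than returning 0.
* **Sub-nucleosomal score** uses 1 bp insert-size bins of the
  deduplicated library; 149 bp is "sub", 150 bp is not.
* **%mito** is defined on pre-deduplication read counts, which the
  library object carries through all filtering views.
* **Complexity** is estimated by solving the Lander–Waterman relation
  with Brent's method to 1e-9 relative tolerance, bracketing from the
  unique count upward (the saturation function is strictly increasing in
  the pool size). Units are unique fragments (pairs).

## Peak caller

The caller reproduces the *procedure* of a MACS2
`--nomodel --extsize 200 --shift -100 --keep-dup all` run at desk scale;
bit-exact MACS2 parity is a non-goal and real narrowPeak files are
accepted wherever a peak set is consumed. Each read contributes a 200 bp
window centered on its 5′ start. The per-base pileup is tested against
Poisson(λ) with λ the maximum of the genome-wide window rate and a 10 kb
centered local rate. Per-base p-values are Benjamini–Hochberg adjusted
over every base of the nuclear genome; untested (zero-pileup) bases carry
p = 1 and sort last, so adjusting the tested vector with m = genome
length is exact — this is why the caller uses its own rank-with-m BH
rather than the generic routine. Significant bases (q < 0.05) separated
by ≤ 30 bp fuse into regions; regions shorter than 200 bp (the window
width) are discarded; the summit is the pileup argmax. Regions are built
from disjoint significant runs and are therefore non-overlapping by
construction.

## Cross-condition bookkeeping and enrichment

Per-condition peak calls are concatenated and merged (≥ 1 bp overlap
fuses), each master interval carrying the union of contributing condition
labels. A peak is *reproducible* when detected in ≥ 3 conditions, and
*missing* for condition c when detected in ≥ 3 conditions other than c
but not in c. The missing-peak enrichment against a ChIP peak set is the
hypergeometric upper tail P(X ≥ k) (the `phyper(k−1, …, lower.tail=FALSE)`
convention) with background B = reproducible peaks, K = background ∩ ChIP,
n = missing, k = missing ∩ ChIP; fold = (k/n)/(K/B). BH adjustment is
applied per condition across factors (statsmodels implementation behind
the `adjust_bh` surface). Degenerate inputs (n = 0 or K = 0) yield
untestable results, not p-values.

FRiP-ChIP divides reads overlapping the merged union of all ChIP sets by
all reads; FRiP-TF divides a factor's overlapping reads by the
ChIP-overlapping reads, so factors are comparable across libraries of
different quality. Row-wise z-scores use the sample standard deviation
(ddof = 1); the ±1.5 cap applies to display exports only, never stored
values. MAD is the unscaled median absolute deviation. Segmentation
annotation assigns each read by its single 5′ base and requires the
segmentation to partition the genome; gap reads count in no class.

## Simulation grid

Depth is counted in reads (mates); pairs are never separated. Per-cell
seeds derive deterministically from (master seed, FRiP level, depth,
replicate) through a `SeedSequence`, so replicates differ while the grid
reproduces bit-identically. The default depth grid is desk-scale
(0.2 M / 0.5 M / 1 M reads) with three replicates; the 10 M–50 M grid of a
production-scale study remains available behind a flag (`--paper-scale`)
for users with pools that large. Infeasible cells (pool shortfalls) are
recorded as error rows and the sweep continues.

## Synthetic data generator

The generator's defaults are the study conditions every test runs under:

* **Genome**: two 5 Mb nuclear chromosomes plus a 16.5 kb mitochondrial
  chromosome. 300 disjoint accessibility peaks of width 400–1000 bp
  (≈ 2% of the genome, matching the genome fraction real peak sets
  occupy), 30% of them containing a TSS at their midpoint.
* **Peak strengths** are lognormal (σ = 0.6), giving the heavy-tailed
  coverage distribution that makes peak-detection power genuinely
  depth-dependent while keeping the weakest peaks recoverable at a
  realistic FRiP — the property behind the subsample-FRiP depth
  dependence the simulation reproduces.
* **Library**: fragments are drawn uniformly *with replacement* from a
  finite latent pool (default 1.5 M nuclear molecules), so duplication
  arises exactly as the Lander–Waterman model assumes; the mitochondrial
  pool is sized so a uniform draw lands on chrM with the configured
  probability (default 24%, the median of native preparations; 46%
  emulates fixed nuclei). Pool molecules may collide in coordinates
  (especially inside peaks), shrinking the *effective* distinct pool by a
  few percent — complexity recovery is therefore asserted at 10%
  tolerance.
* **Placement**: signal molecules (probability = target FRiP, default
  0.34) pick a peak proportionally to strength (TSS-proximal peaks get an
  extra multiplier, default 4) and are placed wholly inside it;
  TSS-proximal placements center on the TSS with 100 bp Gaussian jitter.
  Background molecules are placed wholly inside inter-peak gaps. Because
  no fragment straddles a compartment boundary, mate-level
  signal/background classification is exact and the aggregate FRiP of a
  constructed defined-FRiP library equals its target up to rounding; real
  libraries have edge-straddling pairs that blur this by a fraction of a
  percentage point. Inserts longer than the hosting peak (or gap) are
  truncated to it; peaks narrower than the 20 bp minimum insert are a
  configuration error.
* **Insert sizes**: a three-component normal mixture — sub-nucleosomal
  (75 ± 25 bp), mono-nucleosome (200 ± 35 bp), di-nucleosome
  (380 ± 60 bp) with weights 0.50/0.37/0.13. The sub-nucleosomal score is
  controlled indirectly: the histogram-mode ratio is approximately
  (w₁/σ₁)/(w₂/σ₂) ≈ 1.89 at the defaults, near the median of native
  preparations; the mapping is documented rather than inverted exactly.
* **Condition effects**: per-factor-class coverage multipliers rescale
  peak selection weights, emulating a condition that under-covers, e.g.,
  CTCF-class sites. ChIP sets are the class's accessibility peaks plus
  decoy intervals placed outside all accessibility peaks; the 7-class
  segmentation tiles each nuclear chromosome exactly once with random
  2–20 kb blocks.
* **Seeding**: one master seed feeds named substreams (annotation,
  library, panel) via `SeedSequence` spawn keys; regeneration is
  byte-identical, and derived seeds stay below 2³¹.

What passing tests on these libraries do *not* show: the generator has no
sequence content, no Tn5 insertion or GC bias, no chromatin-state
correlation between neighboring peaks, no optical duplicates, and
fragment placement is uniform within compartments. Conclusions about
metric *definitions* and pipeline correctness transfer to real data;
absolute values of, e.g., TSS enrichment do not.

## Problem sizes

The default test suite generates libraries of 20k–300k fragments and one
1.5 M-fragment source library for the simulation-recovery checks
(constructed cells up to 1 M reads); the acceptance script uses a 1.2 M
fragment source. These sizes keep every planted effect several standard
errors wide while the whole suite runs in about a minute and a half.

## Known limitations

* The per-sample table recomputations (grouped medians, per-condition
  tallies) are exercised on synthetic tables in the published layout;
  the deposited supplementary tables themselves are not redistributable
  here, and the two tests asserting the published numbers require them
  under `data/`.
* The peak caller's absolute peak counts are not comparable to MACS2's on
  real data (different q-value machinery and no model building); only the
  qualitative depth/FRiP response is.
* Re-deriving the external-to-aggregate FRiP ratio from the original
  deposited replicates and the ENCODE DHS references is a documented
  workflow (download, align, filter, then `atacqc simulate` with
  `--external-peaks`), not an exercised test.
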