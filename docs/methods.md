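# Methods

## Coordinate model

All internal coordinates are 0-based half-open; conversion happens only
at file boundaries (GFF3 is 1-based closed; BED/bedGraph are already
0-based half-open). The GATC fragment map places a boundary at the
first base of every literal GATC occurrence (case-insensitive; IUPAC
ambiguity codes never match), so the motif's 4 bp belong to the
downstream fragment. The boundary convention is arbitrary — any
consistent choice shifts every signal identically and leaves all
downstream statistics unchanged — so one is fixed for reproducibility.
All inputs to one analysis must share a single genome build; the
package performs no coordinate liftover.

## Occupancy tracks

Counts are scaled to reads per million (RPM) and the occupancy signal
is `log2((RPM_fusion + c) / (RPM_control + c))` with pseudocount
c = 0.5 RPM. The pseudocount regularises low-count fragments; 0.5 RPM
corresponds to roughly half a read at typical library depth, and its
value is recorded in every output header. This RPM-ratio
normalisation deliberately replaces the kernel-density scaling-factor
scheme used by upstream DamID mapping pipelines: every downstream
statistic consumes the ratio track, not raw counts, and the simpler
scheme is fully reproducible from the per-fragment tables alone.
Fragments with zero reads in both samples carry no information and are
flagged missing; missing fragments break candidate runs (no
interpolation) and are excluded from correlations and profiles.
Negative values are expected wherever Dam-only methylation exceeds the
fusion signal (depleted binding at accessible sites) and are retained.

## Peak calling

Candidates are maximal runs of at least `min_fragments = 2`
consecutive, non-missing fragments with occupancy strictly above
`occupancy_threshold = 0 log2 units` (any enrichment of fusion over
control). Runs break at chromosome ends and missing fragments. The
mean occupancy of a candidate is the unweighted mean over member
fragments.

The null model permutes the non-missing values uniformly across the
non-missing positions, preserving the value distribution while
destroying spatial contiguity — exactly the structure a *broadly*
bound region carries. With `n_shuffles = 100` permutations, peaks are
re-detected with identical parameters, and each observed peak with
statistics (n, m) is scored by the joint upper tail
{n_fragments ≥ n AND mean_occupancy ≥ m} (ties count toward the tail,
which is conservative):

    raw(n, m) = mean_shuffle(#null peaks in tail) / #observed peaks in tail

clipped to [0, 1]. The raw ratio estimates the false discovery rate of
the *discovery set* defined by the threshold (n, m). A peak's reported
FDR is the minimum raw estimate over all thresholds whose discovery
set contains the peak (the usual q-value monotonisation). The raw
ratio itself is not monotone in (n, m) — both tails shrink together as
a threshold strengthens — and without monotonisation a weaker peak
could report a smaller value than a stronger one on the same track;
the monotonised estimate restores coherence and is standard practice
for empirical permutation FDRs. Whether the FDR should be computed
per run-length class or jointly over (length, mean) is genuinely open;
the joint tail is adopted because it ranks peaks by both qualities at
once and never splits the null into small-count classes.

Significance is strict: `fdr < 0.0001` (0.01 %); a peak at exactly the
threshold is not significant. Book-ended significant peaks sharing a
fragment boundary are merged. Final peaks are the union spans of
overlap-graph components (≥ 1 bp overlap) containing significant peaks
from **both** replicates; the union span preserves the full extent of
the broadly bound region, and an intersection-span variant is
available behind a flag. Final peaks carry no FDR of their own.

Determinism: one `numpy.random.default_rng(seed)` per FDR estimation;
shuffle *j* consumes exactly one `rng.permutation` call. The seed is
recorded in output headers, and re-running any stage with unchanged
inputs is byte-identical (headers contain no timestamps).

## Peak annotation

A gene is assigned to a peak when their spans overlap (distance 0) or
when the edge-to-edge gap is ≤ 5 kb and no other gene's span lies
entirely inside the open gap. The intervening-gene predicate uses the
strictest reading that keeps overlapping genes assignable: a bystander
that only partially overlaps the gap (for instance one that also
overlaps the peak) does not block. Gene spans, not TSS anchors, are
used for distances; strand matters only for promoter/TTS windows.

Feature classification takes the peak midpoint and applies the
priority promoter-TSS > TTS > exon > intron > intergenic, with a
strand-aware promoter window of (−1000, +100) bp around the TSS and a
±100 bp TTS window. These are common annotation-tool defaults; all
windows are configuration keys. Genes without annotated exons are
treated as single-exon.

## Accessibility and profiles

Accessible regions are runs of ≥ 2 fragments whose Dam-only RPM is at
or above the genome-wide `quantile = 0.95`, and strictly above the
genome median (the median guard only matters for degenerate
mostly-flat tracks; for continuous RPM data the rule equals a strict
quantile cut). An all-equal track is an error: a quantile threshold
cannot separate runs there.

Metaprofiles project the track onto fixed-width bins centred on region
midpoints (`floor((start+end)/2)`); each bin is the length-weighted
mean of overlapping non-missing fragment values, so the irregular GATC
grid maps consistently onto the regular profile grid. Default flanks:
10 kb for CRM/enhancer-style analyses, 2 kb for open-chromatin
analyses; log2 values are averaged directly (no linearisation).
Heatmap row order is descending mean row signal. Binding–accessibility
correlation is Spearman over jointly non-missing fragments, at GATC
resolution. Chromatin-state summaries are overlap-length-weighted
means per labelled state minus the genome-wide length-weighted mean;
state intervals may abut but not overlap.

## Expression integration

DE classification is strict: upregulated iff padj < 0.05 and
log2FC > 1; downregulated iff padj < 0.05 and log2FC < −1; rows with
missing adjusted p are excluded. Overlap tests are one-sided
(enrichment) Fisher's exact tests, i.e. the hypergeometric upper tail
P(X ≥ |A∩B|), with the sample odds ratio reported as infinite when a
zero cell removes the denominator. The universe defaults to all
annotated genes and is configurable. Tissue of origin: a gene is
focal-tissue if the focal FPKM exceeds 2; otherwise non-focal:<argmax
tissue> if any tissue exceeds 2 (ties broken lexicographically);
otherwise not-detected. FPKM exactly 2 is background.

## Synthetic data generator

The generator emulates a desk-scale TaDa study with known ground
truth. Defaults (one choice, then frozen):

| parameter | default | rationale |
|---|---|---|
| chromosome | 1 × 3 Mb | large enough for ~15,000 GATC fragments |
| mean GATC spacing | 200 bp | 4-cutter density of an A/T-rich genome |
| genes | 300 | ~1 gene / 10 kb, lognormal lengths (median 1.5 kb), 1–5 exons |
| coverage | 50 reads/fragment | deep, routine library |
| NB dispersion α | 0.005 | clean, well-correlated biological replicates |
| bound regions | 8 × 3–8 fragments | sparse, unambiguous ground truth |
| effect | +2 log2 | strong, broad binding |
| replicates | 2 | replicate intersection requires two |
| accessibility | floor 0.6 + smoothed lognormal (σ = 1), mean 1 | see below |
| low-accessibility targeting | 0.8 | emulates binding of closed chromatin |

Counts are negative binomial with mean
`coverage × length_factor × accessibility` for the control and
`control mean × 2^effect` for the fusion. The length factor saturates
(`clip(length/mean_length, 0.5, 2)`): DamID libraries are built from
methyl-PCR amplicons whose yield does not scale linearly with fragment
length, and a proportional factor would render sub-50 bp fragments
statistically useless. The accessibility multiplier keeps a basal
floor — closed chromatin still receives untethered-Dam methylation —
with the variance in the smoothed open-chromatin tail; this reproduces
two observed features at once: replicate RPM tracks correlate at
Spearman ≈ 0.9, and occupancy-ratio noise stays near 0.35–0.4 sd so a
3-fragment planted region remains separable from the permutation null.
GATC motifs are planted as a renewal process (4 bp motif + exponential
gap) on a background scrubbed of accidental motifs, so fragment-count
expectations and boundary positions are exact. Sub-streams of the
master seed are derived by labelled splitting (CRC32 spawn keys);
adding a generator never perturbs another's draws.

The DE table samples each significant gene from the bound pool with
probability `target_bound_fraction` (default 0.75), so the expected
realised bound fraction equals the target; non-significant rows get
padj ≥ 0.05 and a small fraction of missing padj, as real DE output
has. The FPKM matrix assigns each gene a focal, non-focal, or silent
expression pattern over six tissues.

**What the generator does not emulate.** Real binding is pervasive:
thousands of regions covering a substantial fraction of the genome,
plus long-range domain structure. The generator plants *sparse* strong
regions so that ground truth is unambiguous; with dense planted signal
the permutation null itself contains planted-level runs and the FDR
becomes conservative — that behaviour is inherent to the
value-permutation null, not a defect of the simulation. Consequently
replicate concordance ≈ 0.9 holds on the RPM tracks (which carry the
shared accessibility and binding structure) but not on the
ratio tracks, whose shared structure the simulation removes by
construction; with pervasive real binding the ratio tracks themselves
correlate. Passing tests therefore demonstrate correctness of the
computations and calibration of the FDR under the stated conditions,
not performance on dense real genomes. Sequencing-level artefacts
(PCR duplicates, mappability, GC bias) are out of scope.

## Numerical and degenerate-input choices

- Quantiles use numpy's default linear interpolation.
- Ties: null-tail counting uses ≥ (conservative); tissue argmax ties
  break lexicographically; equal-rank ties in Spearman use average
  ranks (scipy).
- Empty candidate list → empty scored list (not an error); empty
  region set for a metaprofile → error; degenerate all-equal
  accessibility track → error naming the reason.
- `total_reads` of a simulated count track is `max(sum, 1)` so that a
  zero-coverage track remains representable.
- BED scores for peaks: `-10·log10(max(fdr, 1e-10))` capped at 1000;
  unset FDR writes score 0.

## Validation strategy

Every core computation is pinned by an independent brute-force oracle
(exhaustive motif scan, naive run scan, replayed-permutation FDR,
networkx connected components, all-pairs gene assignment with explicit
intervening check, per-midpoint classification, `math.comb`
hypergeometric sums, hand-rolled average-rank Spearman). Calibration
is checked at scale: on 200 binding-free tracks of 20,000 fragments,
the pooled proportion of candidates called significant at the 0.01 %
threshold stays below 0.01 % (typically ~0.004 %). Planted-region
recovery at the generator defaults achieves sensitivity and precision
≥ 0.9 over 20 seeds, and a zero-region simulation yields a median of
zero final peaks. Problem sizes in the test suite (≤ 20,000 fragments,
≤ 1,000 records, 20–30 seeds) were chosen as the smallest instances
that exercise each property with comfortable statistical margin.

## Known limitations

- The FDR definition (value-permutation null, joint (length, mean)
  tail) is one concrete reading of "assign each potential peak an
  FDR"; per-length-class or count-based variants would differ in
  detail. The oracle tests pin this package's definition.
- Dense binding makes the permutation null conservative (see above).
- No smoothing is applied to ratio tracks; display pipelines sometimes
  smooth before plotting.
- No GC/mappability correction; inputs are assumed pre-filtered.
- Replicate handling is fixed at call-per-replicate-then-intersect;
  averaging before calling is intentionally unsupported.
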