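# Methods

`decidatac` re-implements, as a tested pipeline, the chromatin-accessibility
analysis of decidualizing human endometrial stromal cells (EnSCs): two
conditions (undifferentiated vs. decidualized), ATAC-seq fragment counts in
a fixed peak set, and a cascade of downstream analyses — signed differential
ranking, motif enrichment and footprinting, the ESR→bZIP→Pax triple motif in
Alu elements, transposable-element overlap statistics, cross-species Alu
presence calling, and peak-to-gene expression association. Every stage is
exercised end-to-end on synthetic data with planted ground truth.

## Differential accessibility (`diffacc`)

Fragments are assigned to peaks by ≥1 bp overlap (union-style: a fragment
spanning two peaks increments both); peaks must be disjoint after merging.
The differential test is a transparent negative-binomial Wald test:

- **Size factors** by median-of-ratios against the geometric-mean reference
  (the standard count-normalization for this data type). If no peak has
  all-positive counts the code falls back to total-count scaling.
- **Dispersion** by method of moments on normalized counts
  (`α̂ = (s² − μ̂)/μ̂²` per condition), **pooled across peaks** into a single
  common value, floored at 1e-8. With 3+3 replicates a per-peak moment
  estimate is negative roughly half the time; flooring those peaks to
  near-Poisson variance produces spuriously tiny standard errors, which
  destroys precision and null calibration. Pooling is the smallest
  stabilization that restores both (measured: precision 1.00 / recall ≈ 0.99
  at the default simulation; per-dataset null p-values pass
  Kolmogorov–Smirnov uniformity). The cost is that genuinely heterogeneous
  per-peak dispersions in real data are averaged; a production analysis
  would use DESeq2's trended shrinkage instead, which is exactly why this
  module is labelled a simplified test.
- **Wald statistic** on `log2((μ̂_B + 0.5)/(μ̂_A + 0.5))` (pseudocount 0.5
  avoids infinities on zero rows), with the delta-method variance
  `Var(log2 μ̂) ≈ (μ + αμ²)/(n μ² ln²2)` summed over conditions; two-sided
  normal p; **Bonferroni** adjustment (`min(1, p·m)`). All-zero peaks get
  log2FC 0 and p 1 by convention.

Power at the default conditions (effect log2FC = 2, dispersion 0.05, 3+3,
Bonferroni over 5,000 peaks): SE(log2FC) ≈ 0.29 against a 4.4σ threshold,
i.e. essentially complete recovery. At dispersion 0.1 with 1,000 peaks the
same arithmetic gives ≈ 0.89 sensitivity; the unit tests assert that
analytically derived level, not a rounder aspiration.

**Signed ranking.** Peaks with positive fold change occupy ranks 1..k in
order of ascending p; negative-fold-change peaks occupy the top ranks so the
most significant closing peak is rank m; zero-fold-change peaks sit between,
least significant first. Ties break by input order (stable sort), so ranks
are always a permutation of 1..m. Dynamic states at Bonferroni α = 0.05:
opening (adjusted p < α, log2FC > 0), closing (< 0), else unchanged.

**Annotation** categories use the precedence upstream_10kb > exon > intron >
intergenic, with the 10-kb upstream window taken strand-aware from each TSS.

## PWM calibration and scanning (`motifs`)

Scores are log-odds in bits against the background base composition, with a
pseudocount (default 1e-3) folded into the probabilities at construction.
The null distribution of the score is computed exactly by position-wise
convolution over **floor-discretized** per-position scores (granularity
default 1e-3 bits; the support is merged after every position, so cost is
bounded by score-span/granularity and, for short motifs, by 4^L where the
result is exact). Flooring makes grid sums never exceed true sums, so the
reported threshold — the smallest achievable score with tail probability
≤ α — is conservative, with total discretization error ≤ L·granularity.
For a degenerate motif whose maximal score is more probable than α (e.g. a
uniform matrix), the maximal score is returned. Hit p-values are the tail at
the largest grid score ≤ the observed score, again an upper bound. The test
suite verifies the whole machinery against exhaustive 4^L enumeration.

Scanning evaluates both strands at every offset; windows containing N score
−∞. A minus-strand hit at [p, p+L) means the reverse complement of that
window matches; scanning a reverse-complemented genome therefore mirrors
coordinates and swaps strands, leaving the hit multiset invariant.

**GC/CpG-matched backgrounds.** Background intervals are drawn within
±50 kb of TSSs, width-matched to their input peak, and accepted when they
fall in the same GC-fraction bin (width 0.05) and CpG observed/expected bin
(width 0.1), with CpG o/e = (#CG·len)/(#C·#G). Sampling is without
replacement and seeded; a bin exhausted after 1,000 draws falls back to the
nearest candidate seen, with a warning. Enrichment is the fraction of peaks
featuring ≥1 hit, compared by a two-sided Fisher exact test.

**Triple motif.** The composite scanner reports every same-strand
arrangement in the 5′→3′ order ESR, bZIP, Pax with inter-hit gaps in
0–15 bp (configurable per junction) and total span ≤ 50 bp. These defaults
are one explicit reading of "in close proximity" — the source analysis does
not state its spacings, nor whether order and strand were constrained — and
all are configurable. The join is linear in the number of component hits
(sorted arrays + binary search) and is tested against a cubic brute-force
join. Triple hits are assigned to the repeat containing their midpoint; the
3′ half of a repeat copy is determined strand-aware.

## Footprints (`footprints`)

Each fragment yields a plus-strand cut at start+4 and a minus-strand cut at
end−5 (the community-standard Tn5 dimer offset; the source describes no
offset, so the standard one is applied). Fragments shorter than 10 bp are
skipped. Profiles aggregate stranded cut counts in 200-bp windows centered
on motif hits, flipping windows (and swapping strand labels) for
minus-strand hits, and divide by the number of sites.

The footprint statistic is a transparent depth/asymmetry pair rather than a
re-implementation of a dedicated footprinter:

- depth = log2((flank mean + ε)/(core mean + ε)), ε = 0.5/n_sites, where the
  core is the central motif-width bp and the flanks are 50 bp on each side;
- asymmetry = (P5′ − P3′)/(P5′ + P3′) on plus-strand cuts in the two flanks,
  positive when plus-strand cuts pile up 5′ of the motif — the geometry of a
  bound factor.

Unoccupied planted motifs show |depth| ≲ 0.2; the small negative bias comes
from fragment-placement edge effects concentrating cuts toward peak centers.
No Tn5 sequence-bias correction is applied (none is described in the source
either).

## Repeat statistics (`repeats`)

Family-level enrichment cross-classifies every genomic bp (in-peak × in-
family) and applies a two-sided Fisher exact test, with expected overlap
from the family's bp fraction. Note the p-value treats each bp as
independent; because whole intervals move together it is anti-conservative
under a shuffling null and should be read the way the original genome-scale
analysis reads it — as a direction plus an extreme score, not a calibrated
error rate. The odds ratio is the meaningful effect size at desk scale.

Genomic positions map onto repeat-consensus coordinates by strand-aware
proportional scaling (`round(along/length × consensus_length)`), not
per-instance alignment. For the near-full-length copies the length filters
admit (≥280/300 bp), the approximation is within a few bp; it is exact on
unmutated copies and is flagged here as an approximation.

The 3′-vs-5′ end test marks each copy's strand-aware 50-bp terminal windows
as peak-overlapping or not; copies with exactly one overlapping end are
informative, and the two-sided exact binomial on the 3′-only count (p = ½)
gives the asymmetry p-value. Being exact, this p-value is discrete and
conservative — for an odd informative count the two central outcomes both
return p = 1 — so null calibration is asserted as validity
(P(p ≤ α) ≤ α) plus uniformity of the randomized probability integral
transform of the count, not as raw-p KS uniformity, which no exact test can
satisfy.

Per-position conservation is reported as information content in nats,
ln 4 − H with a pseudocount of 0.25 per base, so fully conserved columns
approach ln 4 ≈ 1.386 and uniform columns 0. (The source's figure calls
this quantity "entropy" while describing high values as high conservation;
this module computes information content and documents the terminology
mismatch rather than guessing a different formula.)

## Cross-species presence calling (`conservation`)

For each Alu copy, two 100-bp queries span the element boundaries (50 bp
inside + 50 bp outside each end, strand-aware, reverse-complemented for
minus-strand copies). Queries map to a target genome through an internal
seed-and-extend aligner — exact 13-mer seeds, ungapped extension along the
diagonal with match +1 / mismatch −2, best local segment by a Kadane sweep —
so the tests need no external aligner; precomputed 12-column blast-style
tabular hits are accepted interchangeably. A query is "mapped" when its
best hit covers ≥40 bp at ≥80% identity and out-scores the second-best
location by ≥5 bits. The 40-bp floor is deliberate: when the element is
absent, a flank query can align only by its outer 50-bp half, so any floor
above 50 bp would make absence undetectable by construction.

The decision rule (the source does not state one): extrapolate each hit's
diagonal to the element-boundary offset (query position 50); the separation
D of the two boundary points is the implied length of sequence between the
flanks — ≈ element length when present, ≈ 0 when absent. Call **present**
when |D − L| ≤ 0.3·L and both junction halves (the inner 50 bp of each
query) align at ≥60% identity; **absent** when |D| ≤ 60 bp; otherwise, or
when either query is unmapped, discordant, or ambiguous, **inconclusive** —
mirroring the exclusion of loci whose orthology cannot be established with
confidence. Junction support can be disabled (`require_junction=False`)
since it is unknowable whether the original analysis required it. All
tolerances are arguments.

## Synthetic data (`simulate`)

The generator emulates the statistical structure the analyses assume, with
the study conditions as defaults: 5,000 peaks, 200 opening / 50 closing at
effect log2FC = 2, NB dispersion 0.05, 3+3 replicates, on a 20-Mb single
chromosome with ~28% planted repeats at human-like relative family
abundances and 300 genes. Choices worth knowing:

- **Geometry.** Every opening/closing peak is coupled to a distinct gene
  (0.5–8 kb upstream, strand-aware); non-differential peaks are placed
  outside the 10-kb TSS neighborhoods. A miniature genome otherwise packs
  peaks near genes at ~100× the density of a full-size genome, flooding the
  peak–gene linkage with spurious pairs no real dataset would show; the
  exclusion is the scaled-down analogue of real sparsity. A configurable
  fraction of Alu copies (default 0.3) carries a peak over its strand-aware
  3′ half, planting the end-asymmetry and per-position geometry.
- **Sequence.** Background is i.i.d. with a per-10-kb GC level drawn from
  0.35–0.55, giving the GC/CpG matcher structure to match. The ~310-bp
  Alu-like consensus carries ESR→bZIP→Pax in its 3′ half (gaps 4 and 5 bp)
  and an A-rich tail; copies diverge by 8% substitutions with the three
  motif sites protected, which both keeps the triple-motif scan exact and
  makes flank queries distinguishable from the repeat body during mapping.
- **Fragments.** Counts per peak and sample are gamma-Poisson (variance
  μ + αμ²); fragment lengths are uniform 60–120 bp (nucleosome-free range),
  unstranded, with cuts derived from the ends. Within occupied motif cores
  the cut-acceptance probability is multiplied by (1 − protection), with a
  (1 + excess) plus-strand boost in the 20 bp 5′ of the motif and the
  mirror-image minus-strand boost 3′ of it; 5% of fragments are genome-wide
  background. The footprint motif consensus is non-palindromic so hit
  strand is unambiguous.
- **Species.** A ladder ("caterpillar") tree of six primate-like species at
  divergences 0.2–2.0 from the reference; each Alu copy receives an
  insertion age uniform over 1.2× the tree depth and is present in a
  species iff older than that species' split; species sequences are the
  reference with absent copies excised and substitutions applied at
  substitution_rate × divergence. Substitutions only — no indels, no
  rearrangements — so flank mapping difficulty comes purely from divergence
  and repeat ambiguity.
- **Expression.** Genes linked (≤10 kb) to opening peaks draw log2FC from
  N(+1, 0.5), closing from N(−1, 0.5), others from N(0, 0.5).

What passing tests do **not** show about real data: no nucleosome
positioning, no sequence-dependent Tn5 bias beyond the planted protection,
no indels or segmental events in species genomes, homogeneous NB dispersion
across peaks, and repeat copies that are honest scaled copies of one
consensus rather than a subfamily hierarchy. The pipeline's behavior under
those violations is untested here by design.

## Problem sizes

The default simulation (20 Mb, 5,000 peaks, ~3.6 M fragments) runs the full
differential stage in well under a minute. The footprint and repeat-geometry
studies use 2-Mb genomes with 600 peaks; the conservation study uses a
200-kb reference (~50 Alu copies) against six species genomes. These sizes
keep the whole suite and the acceptance script to a few minutes while
leaving every measured property far from its decision threshold.

## Known limitations

- The NB test shares one dispersion across peaks (see above).
- Proportional consensus mapping ignores internal indels in repeat copies.
- The presence caller assumes roughly colinear, substitution-dominated
  divergence; real structural variation around a locus will usually land in
  "inconclusive" rather than being resolved.
- The bp-level Fisher p for family enrichment is not a calibrated error
  rate under interval-level nulls.
- `sample_matched_background` is rejection sampling; for inputs whose GC/CpG
  bins are rare near TSSs it degrades to nearest-bin matching (with a
  warning) rather than failing.
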