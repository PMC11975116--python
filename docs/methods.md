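# Methods

## Scope and data model

`vntrspan` analyses spanning-read coverage and repeat-count genotype quality
for VNTR loci (tandem repeats with consensus motif ≥ 6 bp). Coordinates are
BED-style 0-based half-open everywhere internally; 1-based conventions (TRF
`.dat`, SAM) are converted at the I/O boundary. A locus is a
`(chrom, start, end, motif)` record; the reference repeat count is the array
length divided by the motif length.

## Catalog curation

Candidates from TRF `.dat` or BED are filtered in a fixed order — motif
length, LINE/SINE overlap, segmental-duplication overlap, gene proximity,
chromosome — so that each exclusion has exactly one attributable reason and
curation is idempotent. Defaults: motif ≥ 6 bp; any ≥ 1 bp overlap with an
excluded interval removes a locus (full-containment mode is available, since
"within an element" admits both readings); gene proximity means any overlap
with a gene body or a locus start within 500 bp upstream of a transcription
start site, strand-aware (configurable, as the convention is not universal).
Annotation labels follow the precedence exonic > UTR > intronic, with loci
touching both exon and intron labelled `multiple`. GC content is counted
over the locus ± 100 bp flank; N bases are excluded from the denominator and
an all-N window is reported as missing rather than 0, so unplaced reference
gaps do not masquerade as AT-rich sequence.

## Spanning and reliable reads

A read *spans* a locus when its aligned reference span strictly contains the
locus interval (≥ 1 bp flank each side). The definition deliberately puts
the bar at the weakest level that still sees both array boundaries; the
stricter *reliable* predicate — ≥ 10 bp of aligned flank per side, each
flank ≥ 95% identical — is a separate filter, matching the two-tier usage
(coverage statistics use spanning reads; genotype support uses reliable
reads). The identity denominator is the flank window the read actually
covers, capped at 100 bp per side; deleted reference bases count as
mismatches. Note that at exactly 10 bp of flank, 95% forces a perfect flank.
A `short_read_mode` flag restricts the window to exactly 10 bp, the relaxed
criterion appropriate when one side of a comparison is short reads.
Secondary and supplementary alignments are ignored; duplicates are kept
(long-read protocols lack duplicate marking).

Per-locus classification across samples uses the median spanning count
(even cohort size: mean of the central two): 0 → `uncovered`, < 15 → `low`,
≥ 15 → `well_covered`, ≥ 63 → `high`. Cross-sample homogeneity is the
population variance of counts projected down to a cap of 30; 0.2 is the
reporting default for calling a locus homogeneous, not a hard-coded
constant. Raw counts (not per-million-normalised) feed the projection;
per-million normalisation (`spanning × 10⁶ / mapped reads`) is a separate
reporting covariate. Efficiency is the fraction of mapped reads overlapping
any catalog locus.

## Threshold model

`Perr(n) = P(x ≤ 2 or x ≥ n−2)` for `x ~ Binomial(n, p)`, `p = 0.5` by
default (an allele-balance parameter is exposed but the no-dropout
assumption is the model). The union is evaluated over outcome sets, so the
overlapping tails for n ≤ 5 are counted once and Perr = 1 there. All
arithmetic is exact (`fractions.Fraction`, `math.comb`); floats appear only
at the reporting boundary, so large-n evaluation has no accumulation error.
The threshold for a target miscall rate α is the smallest n with
Perr(n) < α (15 for α = 0.01).

## STR-likeness score

The score detects imperfect internal repeat structure in a consensus motif
via circular self-alignment: compare `M` against windows of the doubled
string at offsets 1…n−1 (identity offset skipped). The base score is the
best `(n − Hamming)/n`. Masking handles *imperfect* repeats: up to
`k = ⌈n/10⌉` characters (n ≤ 40; k = 1 for longer motifs, bounding the
search) may be masked, a masked character matching anything in both copies
of the doubled string; if some mask set makes an alignment perfect the motif
scores 1.0. The masking step is a perfect-repeat detector rather than a
general similarity booster: partial masked alignments do not raise the
score. This choice is deliberate — a rule in which masks also upgrade
imperfect alignments lets a single mask repair two comparisons and pushes
ordinary structured motifs (e.g. `GGCCTG`, via its GG/CC doublets) above
the 0.8 cutoff, defeating the filter's purpose of separating such motifs
from true near-repeats like `AAAAGA`. Scores are exact rationals; the
STR-like cutoff comparison is strict (> 0.8). Mask sets are enumerated
exhaustively over the positions that participate in mismatching pairs
(restriction without loss of exactness), with an alternative "inverted"
budget rule selectable. A length-1 motif has no non-trivial offset and
scores 0 by convention.

## Genotype calling and QC

The caller is a deliberately simple length-ratio estimator and is labelled a
stand-in for a full HMM tandem-repeat genotyper: each reliable read's count
is the read segment between the last aligned base before the array and the
first aligned base after it, divided by the motif length, rounded
half-away-from-zero. It is deterministic and indel-tolerant at the read
level, and is exact on the synthetic reads this package generates; it is not
intended for production genotyping of real data. Counts with < 3 reliable
reads are discarded; no survivors → no-call, one → homozygous, otherwise the
two best-supported counts (ties toward the smaller count) form the
heterozygous call.

Cross-read-set consistency: `consistent` = identical sorted pairs;
`partially_consistent` = pairs differ, exactly two unique alleles in the
union, and at least one call heterozygous (equivalently: one call is
homozygous for an allele of the other) — the signature of one allele
lacking spanning reads in one read set; everything else comparable is
`inconsistent` (so (2,2) vs (4,4) is inconsistent). No-calls are
`not_comparable` and excluded from all denominators. The summary also
reports which side of each partial pair was homozygous. Mendelian
consistency asks whether the child's pair admits one-from-each-parent
transmission; the denominator is loci with complete trio calls after
catalog, optional < 150 bp reference-length (short-read mode) and
STR-likeness (≤ 0.8) restriction.

## Synthetic data generator

The generator emulates the study conditions rather than any particular
cohort: one contig with each locus in its own slot (5 kb of flank per side),
the 100 bp adjacent to each array drawn at the locus's target GC so measured
window GC lands on the intended side of the 0.60 knee (half the loci low-GC
0.30–0.55, half high-GC 0.65–0.85); probes 120 bp, 60% overlapping their
locus, the rest offset 50–3000 bp; decoy loci inside segdup/LINE intervals,
outside genes, or with short motifs exercise each curation filter. Defaults:
50 loci, motifs 6–30 bp, repeat counts 3–15, 4 samples, depth 30 spanning
reads per locus per sample, substitution rate 0.002 (HiFi-like; indels off),
read-length medians 4.2 kb (targeted, matching sheared capture libraries)
and 18 kb (WGS), 76% of loci non-polymorphic.

Targeted dropout is `floor + (1−floor)/(1+exp(slope·(x−knee)))` per
covariate (GC knee 0.60, slope 30 per unit GC; distance knee 1000 bp, slope
0.005 per bp; floor 0.05), multiplied — an invented functional form chosen
to reproduce the qualitative quadrant structure and distance decay, with
parameters as configuration, not claims. Reads are emitted pre-aligned at
their true coordinates: flanks copied from the reference, the array
replaced by the haplotype's repeat count with the indel against the
reference placed at the array's 3′ end. Flank lengths are drawn from the
log-normal read-length model and truncated at the slot margin, so WGS reads
are effectively capped near 10 kb; spanning behaviour, which is what the
pipeline measures, is unaffected. Non-spanning reads (ending inside the
array) and off-target reads are planted at configurable rates for negative
tests; a truncated-flank knob plants spanning-but-unreliable reads.

What the generator does *not* model — PCR stutter, chimeras/adapters,
mapping ambiguity (reads are placed at their true locus by construction),
base-quality variation, indel sequencing errors, recombination and real
allele-frequency structure — bounds what passing tests show: they validate
the counting, filtering, calling and consistency logic under known truth,
not genotyping accuracy on real reads.

## Numerical and design choices

* Exact rational arithmetic wherever a comparison against a cutoff matters
  (Perr, motif scores); threshold comparisons are strict as documented.
* Rounding of repeat counts is half-away-from-zero (deterministic across
  platforms, unlike banker's rounding).
* All randomness flows from `numpy.random.default_rng` seeded from the
  configuration; reference, cohort and read generation use seed, seed+1,
  seed+2 so stages can be regenerated independently; every output is
  bit-reproducible.
* Problem sizes in the test suite and demo (50 loci × 4 samples; 30–40 loci
  for replicate studies; 100 count-level replicates for the bias checks;
  10⁶ Monte-Carlo trials for the Perr cross-check) were chosen as the
  smallest sizes at which the binomial/Poisson noise bands in the assertions
  are comfortably powered.
* The probe-distance monotonicity check holds GC fixed and samples a
  distance grid in the decay region, because with free covariates the GC
  effect confounds sparse distance bins; this matches the controlled
  two-locus design used for the GC effect itself.

## Known limitations

The genotype caller ignores motif-sequence variation (pure length
estimator) and cannot detect alleles differing only in internal sequence;
half-integer length ratios are resolved by rounding, so alleles whose
lengths differ by less than half a motif are not separable. Curation
assumes annotation intervals share the catalog's assembly. The capture
model's logistic parameters are not fitted to any dataset and should be
treated as qualitative.
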