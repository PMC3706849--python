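# Methods

## Problem

When one genome is sequenced several times — different instruments, different
depths — the resulting variant call sets disagree in instructive ways. Three
recurring mechanisms drive the disagreements this package models:

1. **Threshold misses.** A heterozygous site sampled at depth *d* yields a
   Binomial(*d*, ½) number of variant reads. With a caller that requires a
   variant fraction above 0.20, a true heterozygote at depth 15 is missed with
   probability P(VR ≤ 2) = 121/32768 ≈ 0.37% — rare, but expected, and purely
   stochastic.
2. **Paralog mismapping.** A segment duplicated elsewhere in the genome at
   ~95% identity sheds reads that align equally well to the source locus.
   Mismapped reads carry the copy's divergent bases (paralogous sequence
   variants, PSVs), which then masquerade as low-fraction heterozygous calls
   at the functional locus. Their giveaway is mapping quality: an aligner
   assigns ambiguous placements MAPQ at or near 0.
3. **Depth-driven genotype conflicts.** A 2-read observation can legitimately
   print a homozygous genotype that 65 reads later contradict. Consensus must
   prefer depth, not majority-of-runs.

## Pileup caller

The caller counts filtered bases per site. A read contributes a base when it
is not duplicate-flagged, its MAPQ ≥ `min_mapq` (default 1), the base quality
≥ `min_base_quality` (default 20), and the base lies more than `end_trim`
(default 5) positions from either read end — the read-margin and quality
trimming that "unreliable read portions" filtering amounts to here. All
overlapping reads are additionally tallied unfiltered ("raw"), because
mapping-quality evidence lives exactly in the reads the filters discard.

A site is called when filtered depth ≥ `min_coverage` (10) and
vf = VR/(RR+VR) ≥ `min_maf` (0.05); the high-confidence tier requires 30x and
vf ≥ 0.1. The vf denominator is RR+VR rather than total depth: the published
per-instrument read ratios (e.g. 48/(58+48) = 0.45 where total depth is 108)
are only consistent with that convention. Printed ratios round half-up to two
decimals; internally vf is kept at full precision.

Genotype comes from a vf band: heterozygous in [0.20, 0.80], homozygous-variant
above, `below_het` otherwise. Only the lower bound (the >20% filter cutoff) is
documented by the source pipelines; the 0.80 upper bound is the symmetric
choice and is configurable. Alternate-allele ties break to the
lexicographically smallest base for determinism.

Strand bias is a two-sided Fisher exact test on the ref/alt × strand table
(α = 0.05) plus a per-strand minimum of one alternate read. The statistic is
this package's choice; the upstream pipelines name the filter but not its
test. A `LOW_MAPQ_SUPPORT` flag marks calls where more than half the raw
variant-supporting reads have MAPQ < 20.

Duplicate marking supports the two platform conventions: `start_only`
(start-coordinate grouping) and `start_plus_end` (start, fragment end and
strand — the flow-position convention approximated by the fragment end). The
kept read is the one with the highest summed base quality; ties break to the
lexicographically smallest sequence, then input order.

## Concordance and discordance

Variant identity is the full (chrom, pos, ref, alt) key; multiallelic records
decompose. No single concordance denominator is standard, so pairwise results
carry three: the key union and each run as reference (shared / |reference
run|). Coding-region restriction is realized by intersecting keys with target
BED intervals. Private calls (present in one run, absent from all others) are
profiled in the vf × coverage plane; the headline summaries are the share with
vf < 0.20 and the share with vf > 0.20 but coverage < 10.

Why a call in run A is missing from run B is decided by a fixed cascade,
first match wins: raw depth 0 → `NOT_COVERED`; filtered depth < 10 →
`LOW_COVERAGE`; alternate support present but strand-biased → `STRAND_BIAS`;
vf below 0.05 or below the 0.20 band → `LOW_VARIANT_RATIO`; otherwise
`LOW_QUALITY` (support eaten by base/mapping-quality filters). The cascade is
an operationalization — the source material ranks these causes by frequency
but does not state decision rules — and it shares every threshold with the
caller. The coverage split into two causes is kept for diagnostics.

## Mismapping resolution

A candidate site is assessed on four pieces of evidence: the share of
variant-supporting raw reads with MAPQ < 20 (the "low-MAPQ share"), overlap
with an annotated duplication and its percent identity, the count of distinct
variant-read start positions (reported as evidence only), and a hemizygosity
check (a heterozygous genotype on the single X of a male cannot be real;
pseudoautosomal regions are not modelled). Verdicts:

- `LIKELY_PARALOG_ARTIFACT` — low-MAPQ share ≥ 0.9 AND (duplication overlap
  at ≥ 90% identity OR hemizygosity conflict);
- `TRUE_VARIANT` — low-MAPQ share ≤ 0.1 and no hemizygosity conflict;
- `AMBIGUOUS` — anything between.

The verdict is monotone in the low-MAPQ share by construction. Because the
simulator gives mismapped reads MAPQ 0 while the caller's default floor is 1,
a default-threshold caller never surfaces these artifacts; `screen_run`
therefore performs a *discovery pass* with the floor dropped to 0 — the
permissive behavior of the upstream pipeline that produced such calls in the
first place — and assesses every emitted candidate. Segment identity is
computed by position-wise comparison of equal-length intervals (no alignment):
the simulator's copies are substitution-only, and identity figures for a fixed
segment are percentages over its length.

## Consensus genotyping

Per site, runs with zero depth are ignored. Runs with depth ≥ 10 (the
caller's coverage floor, reused deliberately) are *adequate*. If all adequate
runs agree the consensus is `unanimous` (`depth_preferred` when shallower
runs had to be set aside — the 2-read vs 65-read resolution). If adequate
runs disagree, a single high-confidence run wins the tie; otherwise their
(RR, VR) counts are pooled and the genotype band re-applied
(`pooled_recall`). Whether any shallow count should be allowed to veto a deep
call is genuinely open; the depth-preferred rule is this package's documented
choice.

## Synthetic data generator

The generator is first-class, tested code; it defines the study conditions.

**Genome.** Uniform-random chromosomes (default: two autosomes of 25 kb and
20 kb plus a 15 kb X). A 2 kb segment of the X is copied four times onto the
autosomes, each copy substituted independently at divergence 0.05 — the
reported regime of a ~9.7 kb segment in four extra copies at ~95% identity,
scaled down ~5× so that every stage runs in seconds. Realized per-copy
identity is recorded in the duplication BED (fourth column).

**Sample.** A male by default. Heterozygous variants go on one haplotype,
homozygous on both, hemizygous on the single X; a heterozygous spec on the
male X is rejected. Paralog-only variants are fixed differences of one
duplication copy; their alternate allele is chosen to differ from both the
copy base and the homologous source base, otherwise the artifact would be
invisible at the source locus.

**Reads.** Uniformly placed over all haplotype copies, so an autosomal site
sees the configured `mean_depth` and the male X half of it. Substitution-only
errors at `error_rate`; constant base quality (Q30); no indels, no paired-end
insert modelling, no flow-space error spectra (all out of scope). Reads are
reference-oriented; the strand flag feeds the strand-bias test only.

**Mismapping.** Alignment is generative, not performed: a fraction
`mismap_rate` of reads fully contained in a duplication copy is reported at
the homologous source coordinates with MAPQ `low_mapq_value` (default 0);
correctly placed reads get MAPQ 60. The default `mismap_rate` = 0.2 is a free
parameter chosen from the one quantitative anchor available: with four
diploid autosomal copies shedding reads onto a hemizygous X source, the
apparent variant fraction at a PSV is m/(½ + 4m) = 0.154 at m = 0.2, matching
the reported 35-of-232 read ratio at the X-linked locus that motivated the
method. Expected artifact vf is available in closed form
(`expected_artifact_vf`) and the simulator is tested against it.

**Duplicates.** Exact copies of existing reads (same start, same sequence)
injected so that the injected fraction of final reads equals
`duplicate_rate`. Every read carries a truth-origin tag (true coordinates,
haplotype, mismapped/duplicate flags), written to the SAM `XO` tag.

**Run profiles.** Six default runs echo the reported depth spread: four
Illumina-like runs at 138/137/170/169×, error 0.001, duplicate rates
0.04–0.06; two ion-chip-like runs at 65× (200 bp reads) and 93×, error 0.01,
duplicate rates 0.25 and 0.19. Per-run seeds derive deterministically from
the master seed; identical seeds give byte-identical FASTA/SAM/BED/TSV.

**What the generator does not emulate.** Real capture bias, GC effects,
indels, platform error spectra, alignment ambiguity beyond the single
copy→source mechanism, and genome-scale key spaces. The last matters for
duplicate marking: on a 60 kb genome at 170×, distinct reads coincide on
(start, end, strand) by chance far more often than on a 3 Gb genome, so
flagged-duplicate fractions at high depth exceed the injected rate. Tests of
the duplicate-rate calibration therefore run at low depth, and passing tests
say nothing about capture-chemistry duplicate rates in real data.

## Coordinates and formats

0-based half-open internally and in BED; 1-based in VCF and the truth table.
SAM carries strand in FLAG 0x10, duplicate marking in 0x400, run id in `RG`,
truth origin in `XO`. VCF records carry `RR`, `VR`, `TR`, `VF`, `TIER`,
`GT_LABEL` and `FLAGS` INFO fields and round-trip losslessly for those
fields. Run metrics (coverage tiers, mean/median target coverage) use the
caller's read view — non-duplicate, MAPQ-passing — with raw totals and the
duplicate fraction reported separately; medians are over target bases.

## Problem sizes and verification scale

The bundled default configuration (60 kb genome, one 170× run) drives the
artifact-resolution checks: twelve planted paralog-only loci, eleven planted
functional variants, ~400 candidate sites screened, a few seconds end to end.
The stochastic miss-rate check samples 10⁵ heterozygous sites at depth 15 and
compares against the exact binomial tail. The caller is checked exhaustively
against a literal transcription of its thresholds over all read-count pairs
with RR+VR ≤ 60. Published cohort-scale quantities (run-level capture
metrics, the 96–98% intra-platform concordances, genome-wide concordant-SNP
counts) require the original read archives and are represented only by
qualitative simulation analogues: replicate high-confidence concordance above
90%, n-way intersections containing all planted homozygotes, monotone
coverage-tier fractions.

## Known limitations

- Substitution-only model end to end; indel calling and indel concordance
  normalization are out of scope.
- The strand-bias statistic and the discordance cascade are reasonable
  reconstructions, not published algorithms; both are configurable.
- The mismapping model routes reads only from copy to source, not between
  copies or source to copy.
- `AMBIGUOUS` verdicts are expected at sites where filtered and raw evidence
  straddle a cutoff; the resolver deliberately refuses to force them.
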