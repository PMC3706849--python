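# concordx

Multi-run SNV concordance analysis and pseudogene-mismapping resolution, with
a deterministic synthetic-genome simulator that makes the whole pipeline
testable without any sequence downloads.

When the same genome is sequenced repeatedly — different instruments,
different depths — the call sets disagree. Some disagreements are stochastic
(a heterozygote at depth 15 drawing ≤ 2 variant reads slips under a 20%
variant-fraction filter with probability 121/32768 ≈ 0.37%), some are
systematic (reads from a ~95%-identity segmental duplication mismap to the
functional locus and masquerade as heterozygous calls), and some are
depth-driven genotype conflicts (2 reads said homozygous, 65 reads say
heterozygous). `concordx` implements the pieces needed to produce, compare,
explain and resolve such call sets:

- **`simulate`** — a toy diploid genome with a segmental-duplication family
  (default: a 2 kb X-linked segment in 4 extra autosomal copies at ~95%
  identity), planted het/hom/hemizygous and paralog-only variants, and
  multi-run read simulation with a generative mismapping model (mismapped
  reads get MAPQ 0 and carry the copy's divergent bases), duplicates, and
  sequencing error. Fully determined by a seed.
- **`caller`** — a pileup SNV caller: duplicate marking (start-only or
  start-plus-end conventions), base/mapping-quality and end-trim filtering,
  calls at ≥ 10× coverage and variant fraction vf = VR/(RR+VR) ≥ 0.05, a
  high-confidence tier at ≥ 30× and vf ≥ 0.1, genotype from the vf band
  (het in [0.20, 0.80]), Fisher-exact strand-bias flagging.
- **`concordance`** — pairwise and n-way variant-key overlap with explicit
  denominators, private-call extraction and vf × coverage profiling.
- **`discordance`** — a total decision cascade explaining every missed call:
  NOT_COVERED → LOW_COVERAGE → STRAND_BIAS → LOW_VARIANT_RATIO → LOW_QUALITY.
- **`mismap`** — is a candidate a paralog artifact? Evidence: low-MAPQ share
  of variant reads, duplication-annotation overlap (≥ 90% identity),
  male-X hemizygosity conflicts.
- **`genotypes`** — consensus genotyping across runs, preferring adequate
  depth and pooling read counts on disagreement.

See `docs/methods.md` for the model details and the design choices.

## Worked example

`examples/03_pseudogene_resolution.py` simulates the default genome, runs a
permissive discovery pass (mapping-quality floor 0, the behavior that lets
mismapped reads produce calls), and screens every candidate:

```
406 candidate sites screened
verdicts: {'TRUE_VARIANT': 25, 'AMBIGUOUS': 2, 'LIKELY_PARALOG_ARTIFACT': 379}

planted paralog-only variants, seen at their homologous source locus:
  chrX:4151 C>A vf=0.246 low-MAPQ share 1.00 dup 94.8% hemi-conflict=True -> LIKELY_PARALOG_ARTIFACT
  chrX:4701 T>A vf=0.175 low-MAPQ share 1.00 dup 94.8% hemi-conflict=False -> LIKELY_PARALOG_ARTIFACT
  ...
planted functional variants:
  chr1:2001 G>T vf=0.391 -> TRUE_VARIANT
  chr1:3001 G>T vf=1.000 -> TRUE_VARIANT
  ...
```

Every planted paralog-only locus surfaces at its homologous source position
with an apparent variant fraction near the closed-form expectation
m/(½ + 4m) = 0.154 (mismap rate m = 0.2, hemizygous X source, four diploid
copies), supported exclusively by MAPQ-0 reads inside the annotated
duplication — and is flagged as an artifact. Every planted functional variant
keeps well-mapped support and is confirmed. Het-looking candidates on the
male X additionally carry a hemizygosity conflict: a true genotype there
cannot be heterozygous.

`examples/04_genotype_consensus.py` shows depth resolving conflicting
genotypes:

```
CYP2C9 p.Arg144Cys
  WGS-SOLiD  rr=0   vr=2   depth=2   -> hom_var
  ES-HiSeq   rr=32  vr=33  depth=65  -> het
  consensus: het via depth_preferred (runs: ES-HiSeq; pooled rr:vr = 32:33)
```

The other examples cover simulation + calling (`01`) and run-set concordance
with private-call profiling (`02`). A thin CLI wraps the same stages:

```bash
concordx simulate --outdir demo --seed 1
concordx call --sam demo/hiseq_1.sam --ref demo/reference.fasta --out demo/hiseq_1.vcf
concordx compare --vcf demo/hiseq_1.vcf --vcf demo/gaii_1.vcf --targets demo/targets.bed --out report.tsv
concordx resolve --sam demo/hiseq_1.sam --ref demo/reference.fasta \
    --dup-bed demo/duplications.bed --sex male --out assessments.tsv
```

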