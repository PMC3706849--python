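"""Deciding whether a candidate variant is a paralog/pseudogene mismapping artifact.

A variant whose supporting reads almost all carry low mapping qualities, at a
site lying inside an annotated high-identity segmental duplication — or whose
apparent genotype is heterozygous on the single X of a male — is far more
likely to be reads from a homologous copy reported at the wrong locus than a
real sample variant. This module scores that evidence per site.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .caller import (
    GT_HET,
    CallerThresholds,
    DEFAULT_THRESHOLDS,
    VariantCall,
    assign_genotype,
    call_variants,
)
from .reads import AlignedRead, ReadIndex, Reference

VERDICT_TRUE = "TRUE_VARIANT"
VERDICT_ARTIFACT = "LIKELY_PARALOG_ARTIFACT"
VERDICT_AMBIGUOUS = "AMBIGUOUS"


@dataclass(frozen=True)
class DupInterval:
    """One member of a duplication family; 0-based half-open, identity in percent."""

    chrom: str
    start: int
    end: int
    identity: float
    partner: str = ""
    is_source: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.identity <= 100:
            raise ValueError("identity must lie in [0, 100]")
        if self.end <= self.start:
            raise ValueError("empty interval")


class DuplicationAnnotation:
    """A set of duplication intervals with point-overlap queries."""

    def __init__(self, intervals: Iterable[DupInterval] = ()):
        self.intervals = list(intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def source(self) -> Optional[DupInterval]:
        for iv in self.intervals:
            if iv.is_source:
                return iv
        return None

    @property
    def copies(self) -> list[DupInterval]:
        return [iv for iv in self.intervals if not iv.is_source]

    def overlapping(self, chrom: str, pos0: int) -> Optional[DupInterval]:
        for iv in self.intervals:
            if iv.chrom == chrom and iv.start <= pos0 < iv.end:
                return iv
        return None


@dataclass(frozen=True)
class MismapCutoffs:
    """Evidence cutoffs for the artifact verdict."""

    low_mapq_cutoff: int = 20  # mapq below this counts as a low-quality placement
    artifact_fraction_cutoff: float = 0.9  # low-mapq share of variant reads implying artifact
    clean_fraction_cutoff: float = 0.1  # low-mapq share compatible with a true variant
    min_identity: float = 90.0  # duplication identity needed to implicate mismapping


DEFAULT_CUTOFFS = MismapCutoffs()


@dataclass
class MismapAssessment:
    """Per-site verdict with the evidence it rests on."""

    key: tuple[str, int, str, str]
    total_reads: int
    variant_reads: int
    low_mapq_fraction: float
    distinct_starts: int
    overlaps_duplication: bool
    duplication_identity: Optional[float]
    hemizygosity_conflict: bool
    verdict: str

    def __post_init__(self) -> None:
        if self.variant_reads > self.total_reads:
            raise ValueError("variant reads exceed total reads")


def hemizygosity_check(
    key: tuple[str, int, str, str],
    genotype: str,
    sample_sex: str,
    chrom_model: Mapping[str, bool],
) -> bool:
    """True iff the call is heterozygous on the single X of a male.

    ``chrom_model`` maps contig name -> is-X; an unknown contig is an error.
    Pseudoautosomal regions are not modelled.
    """
    chrom = key[0]
    if chrom not in chrom_model:
        raise KeyError(f"unknown contig {chrom!r} in chromosome model")
    return sample_sex == "male" and chrom_model[chrom] and genotype == GT_HET


def assess_site(
    key: tuple[str, int, str, str],
    reads_at_site: Sequence[AlignedRead],
    annotation: Optional[DuplicationAnnotation],
    sample_sex: str,
    cutoffs: MismapCutoffs = DEFAULT_CUTOFFS,
    *,
    chrom_model: Mapping[str, bool],
    thresholds: CallerThresholds = DEFAULT_THRESHOLDS,
    genotype: Optional[str] = None,
) -> MismapAssessment:
    """Score one candidate variant site for paralog-mismapping evidence.

    ``genotype`` lets the caller's own call label drive the hemizygosity
    check; when omitted it is derived from the raw ref/alt read counts.

    The verdict is LIKELY_PARALOG_ARTIFACT when the low-mapq share of
    variant-supporting reads reaches ``artifact_fraction_cutoff`` AND the site
    either lies in an annotated duplication of sufficient identity or shows a
    hemizygosity conflict; TRUE_VARIANT when that share is at most
    ``clean_fraction_cutoff`` with no hemizygosity conflict; else AMBIGUOUS.
    Counts come from raw overlapping reads (duplicate-flagged reads excluded,
    no quality filters), because mapping quality of the *discarded* support is
    the whole point.
    """
    chrom, pos, ref, alt = key
    pos0 = pos - 1
    reads = [r for r in reads_at_site if r.overlaps(chrom, pos0) and not r.duplicate_flag]
    if not reads:
        raise ValueError(f"no reads cover site {chrom}:{pos}")
    var_reads = [r for r in reads if r.base_at(pos0) == alt]
    ref_reads = [r for r in reads if r.base_at(pos0) == ref]
    n_var = len(var_reads)
    low_frac = (
        float(np.mean([r.mapq < cutoffs.low_mapq_cutoff for r in var_reads])) if n_var else 0.0
    )
    iv = annotation.overlapping(chrom, pos0) if annotation is not None else None
    dup_ok = iv is not None and iv.identity >= cutoffs.min_identity

    conflict = False
    if genotype is None and n_var > 0:
        genotype = assign_genotype(len(ref_reads), n_var, thresholds)
    if genotype is not None:
        conflict = hemizygosity_check(key, genotype, sample_sex, chrom_model)

    if n_var == 0:
        verdict = VERDICT_AMBIGUOUS
    elif low_frac >= cutoffs.artifact_fraction_cutoff and (dup_ok or conflict):
        verdict = VERDICT_ARTIFACT
    elif low_frac <= cutoffs.clean_fraction_cutoff and not conflict:
        verdict = VERDICT_TRUE
    else:
        verdict = VERDICT_AMBIGUOUS

    return MismapAssessment(
        key=key,
        total_reads=len(reads),
        variant_reads=n_var,
        low_mapq_fraction=low_frac,
        distinct_starts=len({r.start for r in var_reads}),
        overlaps_duplication=iv is not None,
        duplication_identity=iv.identity if iv is not None else None,
        hemizygosity_conflict=conflict,
        verdict=verdict,
    )


def screen_run(
    reads: Sequence[AlignedRead],
    reference: Reference,
    annotation: Optional[DuplicationAnnotation],
    sample_sex: str,
    cutoffs: MismapCutoffs = DEFAULT_CUTOFFS,
    thresholds: CallerThresholds = DEFAULT_THRESHOLDS,
    regions: Optional[Sequence[tuple[str, Optional[int], Optional[int]]]] = None,
) -> list[tuple[VariantCall, MismapAssessment]]:
    """Discovery pass plus per-site mismapping assessment for one run.

    Discovery deliberately drops the caller's mapping-quality floor to zero so
    that candidate variants supported only by ambiguous placements are surfaced
    — the situation a permissive upstream pipeline creates — and every emitted
    candidate is then assessed against the duplication annotation and the
    sample's sex.
    """
    discovery = dataclasses.replace(thresholds, min_mapq=0)
    calls = call_variants(reads, regions, discovery, reference=reference)
    index = ReadIndex(reads)
    model = reference.chrom_model
    return [
        (
            call,
            assess_site(
                call.key,
                index.at(call.chrom, call.pos - 1),
                annotation,
                sample_sex,
                cutoffs,
                chrom_model=model,
                thresholds=thresholds,
                genotype=call.genotype,
            ),
        )
        for call in calls
    ]


def segment_identity(
    reference: Reference,
    interval_a: tuple[str, int, int],
    interval_b: tuple[str, int, int],
) -> float:
    """Percent identity of two equal-length intervals by position-wise comparison."""
    ca, sa, ea = interval_a
    cb, sb, eb = interval_b
    if ea - sa != eb - sb:
        raise ValueError("intervals must have equal length")
    a = reference.codes(ca)[sa:ea]
    b = reference.codes(cb)[sb:eb]
    return 100.0 * float(np.mean(a == b))
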