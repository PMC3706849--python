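"""Pileup-based SNV calling with explicit coverage and allele-fraction thresholds.

The caller counts filtered read bases per site, emits a call whenever the
filtered depth reaches ``min_coverage`` and the variant allele fraction
vf = vr/(rr+vr) reaches ``min_maf`` (defaults 10x / 0.05), promotes calls to
a high-confidence tier at 30x / 0.1, and assigns a genotype from the vf band
(het within [0.20, 0.80], hom_var above). Duplicate marking supports the two
platform conventions: start-coordinate only, or start plus fragment end.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .reads import BASES, AlignedRead, Reference, encode_bases

GT_HET = "het"
GT_HOM_VAR = "hom_var"
GT_BELOW_HET = "below_het"

TIER_CANDIDATE = "candidate"
TIER_HIGH_CONFIDENCE = "high_confidence"

FLAG_STRAND_BIAS = "STRAND_BIAS"
FLAG_LOW_MAPQ_SUPPORT = "LOW_MAPQ_SUPPORT"

DUP_MODE_START_ONLY = "start_only"
DUP_MODE_START_PLUS_END = "start_plus_end"


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up, the convention used for printed read ratios."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CallerThresholds:
    """Tunable thresholds of the caller; defaults follow the study pipeline."""

    min_coverage: int = 10
    min_maf: float = 0.05
    hc_min_coverage: int = 30
    hc_min_maf: float = 0.10
    het_lower_vf: float = 0.20
    het_upper_vf: float = 0.80
    min_base_quality: int = 20
    min_mapq: int = 1
    end_trim: int = 5
    strand_bias_alpha: float = 0.05
    min_alt_per_strand: int = 1
    low_support_mapq: int = 20  # mapq below this counts as "low" for support flags

    def __post_init__(self) -> None:
        if not 0 <= self.min_maf <= self.hc_min_maf <= 1:
            raise ValueError("need 0 <= min_maf <= hc_min_maf <= 1")
        if not self.het_lower_vf < self.het_upper_vf:
            raise ValueError("need het_lower_vf < het_upper_vf")


DEFAULT_THRESHOLDS = CallerThresholds()


@dataclass
class PileupColumn:
    """Per-site allele counts, strand-stratified after read/base filtering.

    ``counts`` is a (4 alleles x 2 strands) array over filtered bases;
    ``raw_*`` fields summarise every overlapping read regardless of filters,
    which is what mapping-quality evidence is drawn from.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    counts: np.ndarray  # (4, 2): [allele, strand]; strand 0 = '+', 1 = '-'
    raw_depth: int
    raw_allele_counts: np.ndarray  # (4,)
    raw_mapq_sums: np.ndarray  # (4,)
    raw_low_mapq: np.ndarray  # (4,) raw supporting reads with low mapq

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (4, 2):
            raise ValueError("counts must be a (4, 2) allele x strand array")
        if self.filtered_depth > self.raw_depth:
            raise ValueError("filtered depth exceeds raw depth")

    @classmethod
    def from_counts(
        cls,
        chrom: str,
        pos: int,
        ref: str,
        strand_counts: dict[str, tuple[int, int]],
        raw_extra: int = 0,
        low_mapq: Optional[dict[str, int]] = None,
        mapq: int = 60,
    ) -> "PileupColumn":
        """Convenience constructor from {allele: (fwd, rev)} filtered counts."""
        counts = np.zeros((4, 2), dtype=np.int64)
        for allele, (fwd, rev) in strand_counts.items():
            counts[BASES.index(allele)] = (fwd, rev)
        raw_allele = counts.sum(axis=1)
        raw_low = np.zeros(4, dtype=np.int64)
        for allele, n in (low_mapq or {}).items():
            raw_low[BASES.index(allele)] = n
        return cls(
            chrom=chrom,
            pos=pos,
            ref=ref,
            counts=counts,
            raw_depth=int(raw_allele.sum()) + raw_extra,
            raw_allele_counts=raw_allele,
            raw_mapq_sums=raw_allele * mapq,
            raw_low_mapq=raw_low,
        )

    @property
    def filtered_depth(self) -> int:
        return int(self.counts.sum())

    def count(self, allele: str, strand: Optional[str] = None) -> int:
        i = BASES.index(allele)
        if strand is None:
            return int(self.counts[i].sum())
        return int(self.counts[i, 0 if strand == "+" else 1])

    def mean_raw_mapq(self, allele: str) -> float:
        i = BASES.index(allele)
        n = int(self.raw_allele_counts[i])
        return float(self.raw_mapq_sums[i]) / n if n else float("nan")

    def low_mapq_fraction(self, allele: str) -> float:
        i = BASES.index(allele)
        n = int(self.raw_allele_counts[i])
        return float(self.raw_low_mapq[i]) / n if n else 0.0


@dataclass
class VariantCall:
    """A called site with supporting read counts and confidence annotations."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    rr: int  # reference-supporting filtered reads
    vr: int  # variant-supporting filtered reads
    tr: int  # total filtered reads at the site
    vf: float  # vr / (rr + vr), full precision
    ref_fwd: int
    ref_rev: int
    alt_fwd: int
    alt_rev: int
    tier: str
    genotype: str
    flags: frozenset[str] = field(default_factory=frozenset)
    strand_p: float = float("nan")

    def __post_init__(self) -> None:
        if self.rr + self.vr > self.tr:
            raise ValueError("rr + vr exceeds total reads")
        if not 0.0 <= self.vf <= 1.0:
            raise ValueError("vf outside [0, 1]")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def printed_ratio(self) -> float:
        """vf rounded half-up to 2 decimals, the printed-report convention."""
        return round_half_up(self.vf, 2)


class RegionPileup(Sequence):
    """Pileup columns over one contiguous region, backed by dense count arrays."""

    def __init__(
        self,
        chrom: str,
        start: int,
        ref_codes: np.ndarray,
        filt: np.ndarray,
        raw_allele: np.ndarray,
        raw_mapq_sums: np.ndarray,
        raw_low_mapq: np.ndarray,
        raw_depth: np.ndarray,
    ):
        self.chrom = chrom
        self.start = start
        self._ref_codes = ref_codes
        self._filt = filt
        self._raw_allele = raw_allele
        self._raw_mapq = raw_mapq_sums
        self._raw_low = raw_low_mapq
        self._raw_depth = raw_depth

    def __len__(self) -> int:
        return len(self._ref_codes)

    @property
    def end(self) -> int:
        return self.start + len(self)

    def __getitem__(self, i: int) -> PileupColumn:
        if not 0 <= i < len(self):
            raise IndexError(i)
        code = int(self._ref_codes[i])
        return PileupColumn(
            chrom=self.chrom,
            pos=self.start + i + 1,
            ref=BASES[code] if code < 4 else "N",
            counts=self._filt[i],
            raw_depth=int(self._raw_depth[i]),
            raw_allele_counts=self._raw_allele[i],
            raw_mapq_sums=self._raw_mapq[i],
            raw_low_mapq=self._raw_low[i],
        )

    def column_at(self, pos0: int) -> PileupColumn:
        """Column at absolute 0-based reference position ``pos0``."""
        return self[pos0 - self.start]

    def candidate_sites(self) -> np.ndarray:
        """Absolute 0-based positions holding any filtered non-reference support."""
        allele_tot = self._filt.sum(axis=2)  # (L, 4)
        nonref = allele_tot.sum(axis=1) - np.take_along_axis(
            allele_tot, np.minimum(self._ref_codes, 3).astype(np.int64)[:, None], axis=1
        ).ravel()
        has_ref_base = self._ref_codes < 4
        return self.start + np.flatnonzero((nonref > 0) & has_ref_base)


def _normalize_region(
    region: tuple[str, Optional[int], Optional[int]], reference: Reference
) -> tuple[str, int, int]:
    chrom, start, end = region
    if chrom not in reference:
        raise ValueError(f"region contig {chrom!r} not in reference")
    length = reference.lengths[chrom]
    start = 0 if start is None else start
    end = length if end is None else end
    if not (0 <= start < end <= length):
        raise ValueError(f"region {chrom}:{start}-{end} outside reference (len {length})")
    return chrom, start, end


def build_pileup(
    reads: Iterable[AlignedRead],
    region: tuple[str, Optional[int], Optional[int]],
    thresholds: CallerThresholds = DEFAULT_THRESHOLDS,
    *,
    reference: Reference,
) -> RegionPileup:
    """Count filtered bases per site over ``region`` (chrom, start, end), 0-based half-open.

    Filtered counts exclude duplicate-flagged reads, reads below ``min_mapq``,
    bases below ``min_base_quality`` and bases within ``end_trim`` of either
    read end. Raw counts include every overlapping read.
    """
    chrom, start, end = _normalize_region(region, reference)
    L = end - start
    filt = np.zeros((L, 4, 2), dtype=np.int64)
    raw_allele = np.zeros((L, 4), dtype=np.int64)
    raw_mapq = np.zeros((L, 4), dtype=np.int64)
    raw_low = np.zeros((L, 4), dtype=np.int64)
    raw_depth = np.zeros(L, dtype=np.int64)

    by_len: dict[int, list[AlignedRead]] = {}
    for r in reads:
        if r.chrom == chrom and r.start < end and r.end > start:
            by_len.setdefault(len(r.sequence), []).append(r)

    for rl, grp in sorted(by_len.items()):
        n = len(grp)
        starts = np.fromiter((r.start for r in grp), dtype=np.int64, count=n)
        seq = np.stack([encode_bases(r.sequence) for r in grp])
        quals = np.stack([r.base_qualities for r in grp]).astype(np.int16)
        mapq = np.fromiter((r.mapq for r in grp), dtype=np.int16, count=n)
        dup = np.fromiter((r.duplicate_flag for r in grp), dtype=bool, count=n)
        rev = np.fromiter((r.strand == "-" for r in grp), dtype=np.int8, count=n)

        pos = starts[:, None] + np.arange(rl)
        inwin = (pos >= start) & (pos < end)
        off = pos - start
        base_ok = seq < 4
        m_raw = inwin & base_ok

        np.add.at(raw_depth, off[inwin], 1)
        np.add.at(raw_allele, (off[m_raw], seq[m_raw]), 1)
        mq_mat = np.broadcast_to(mapq[:, None], (n, rl))
        np.add.at(raw_mapq, (off[m_raw], seq[m_raw]), mq_mat[m_raw])
        m_low = m_raw & (mq_mat < thresholds.low_support_mapq)
        np.add.at(raw_low, (off[m_low], seq[m_low]), 1)

        j = np.arange(rl)
        trim_ok = (j >= thresholds.end_trim) & (j < rl - thresholds.end_trim)
        read_ok = ~dup & (mapq >= thresholds.min_mapq)
        m_f = m_raw & trim_ok[None, :] & (quals >= thresholds.min_base_quality) & read_ok[:, None]
        strand_mat = np.broadcast_to(rev[:, None], (n, rl))
        np.add.at(filt, (off[m_f], seq[m_f], strand_mat[m_f]), 1)

    return RegionPileup(chrom, start, reference.codes(chrom)[start:end], filt, raw_allele, raw_mapq, raw_low, raw_depth)


def assign_genotype(rr: int, vr: int, thresholds: CallerThresholds = DEFAULT_THRESHOLDS) -> str:
    """Genotype from the variant-fraction band: het in [lower, upper], hom above."""
    if rr + vr == 0:
        raise ValueError("cannot assign a genotype with zero informative reads")
    vf = vr / (rr + vr)
    if thresholds.het_lower_vf <= vf <= thresholds.het_upper_vf:
        return GT_HET
    if vf > thresholds.het_upper_vf:
        return GT_HOM_VAR
    return GT_BELOW_HET


def classify_counts(
    rr: int, vr: int, thresholds: CallerThresholds = DEFAULT_THRESHOLDS
) -> tuple[bool, Optional[str], Optional[str]]:
    """Pure threshold arithmetic on an (rr, vr) pair: (called, tier, genotype).

    Assumes the site carries only reference and one alternate allele, so the
    filtered depth equals rr + vr.
    """
    tr = rr + vr
    if tr == 0:
        return False, None, None
    vf = vr / tr
    if tr < thresholds.min_coverage or vf < thresholds.min_maf:
        return False, None, None
    tier = (
        TIER_HIGH_CONFIDENCE
        if tr >= thresholds.hc_min_coverage and vf >= thresholds.hc_min_maf
        else TIER_CANDIDATE
    )
    return True, tier, assign_genotype(rr, vr, thresholds)


def strand_bias(
    column: PileupColumn, alt: str, thresholds: CallerThresholds = DEFAULT_THRESHOLDS
) -> tuple[float, bool]:
    """Two-sided Fisher exact test on the ref/alt x strand table.

    Biased when p < alpha, or when alt support on either strand falls below
    ``min_alt_per_strand``.
    """
    ref_f, ref_r = (int(x) for x in column.counts[BASES.index(column.ref)])
    alt_f, alt_r = (int(x) for x in column.counts[BASES.index(alt)])
    _, p = stats.fisher_exact([[ref_f, ref_r], [alt_f, alt_r]], alternative="two-sided")
    biased = p < thresholds.strand_bias_alpha or min(alt_f, alt_r) < thresholds.min_alt_per_strand
    return float(p), biased


def call_site(
    column: PileupColumn, thresholds: CallerThresholds = DEFAULT_THRESHOLDS
) -> Optional[VariantCall]:
    """Call one pileup column; returns None for a no-call (never an error).

    The alternate allele is the non-reference allele with the highest filtered
    count (ties to the lexicographically smallest base). A call is emitted iff
    filtered depth >= min_coverage and vf >= min_maf.
    """
    if column.raw_depth == 0 or column.ref not in BASES:
        return None
    allele_tot = column.counts.sum(axis=1)
    ref_i = BASES.index(column.ref)
    best_i, best_n = -1, 0
    for i in range(4):
        if i == ref_i:
            continue
        if allele_tot[i] > best_n:  # strict '>' keeps the smallest base on ties
            best_i, best_n = i, int(allele_tot[i])
    if best_n == 0:
        return None
    alt = BASES[best_i]
    rr, vr = int(allele_tot[ref_i]), best_n
    tr = column.filtered_depth
    vf = vr / (rr + vr)
    if tr < thresholds.min_coverage or vf < thresholds.min_maf:
        return None
    tier = (
        TIER_HIGH_CONFIDENCE
        if tr >= thresholds.hc_min_coverage and vf >= thresholds.hc_min_maf
        else TIER_CANDIDATE
    )
    flags = set()
    p, biased = strand_bias(column, alt, thresholds)
    if biased:
        flags.add(FLAG_STRAND_BIAS)
    if column.low_mapq_fraction(alt) > 0.5:
        flags.add(FLAG_LOW_MAPQ_SUPPORT)
    return VariantCall(
        chrom=column.chrom,
        pos=column.pos,
        ref=column.ref,
        alt=alt,
        rr=rr,
        vr=vr,
        tr=tr,
        vf=vf,
        ref_fwd=int(column.counts[ref_i, 0]),
        ref_rev=int(column.counts[ref_i, 1]),
        alt_fwd=int(column.counts[best_i, 0]),
        alt_rev=int(column.counts[best_i, 1]),
        tier=tier,
        genotype=assign_genotype(rr, vr, thresholds),
        flags=frozenset(flags),
        strand_p=p,
    )


def call_variants(
    reads: Iterable[AlignedRead],
    regions: Optional[Iterable[tuple[str, Optional[int], Optional[int]]]] = None,
    thresholds: CallerThresholds = DEFAULT_THRESHOLDS,
    *,
    reference: Reference,
) -> list[VariantCall]:
    """Run the caller over ``regions`` (default: every contig) and sort calls.

    Ordering is deterministic: reference contig order, then position.
    """
    reads = list(reads)
    if regions is None:
        regions = [(name, None, None) for name in reference.names]
    calls: list[VariantCall] = []
    for region in regions:
        pileup = build_pileup(reads, region, thresholds, reference=reference)
        for pos0 in pileup.candidate_sites():
            call = call_site(pileup.column_at(int(pos0)), thresholds)
            if call is not None:
                calls.append(call)
    order = {name: i for i, name in enumerate(reference.names)}
    calls.sort(key=lambda c: (order[c.chrom], c.pos, c.alt))
    return calls


def mark_duplicates(
    reads: Sequence[AlignedRead], mode: str = DUP_MODE_START_PLUS_END
) -> list[AlignedRead]:
    """Flag duplicate reads, keeping exactly one read per duplicate group.

    ``start_only`` groups by (chrom, start) — the start-position convention;
    ``start_plus_end`` additionally requires matching end and strand — the
    start-plus-fragment-end convention. The retained read is the one with the
    highest summed base quality (ties: lexicographically smallest sequence,
    then input order). Input order is preserved in the result.
    """
    if mode not in (DUP_MODE_START_ONLY, DUP_MODE_START_PLUS_END):
        raise ValueError(f"unknown duplicate-marking mode {mode!r}")
    groups: dict[tuple, list[int]] = {}
    for i, r in enumerate(reads):
        if mode == DUP_MODE_START_ONLY:
            key = (r.chrom, r.start)
        else:
            key = (r.chrom, r.start, r.end, r.strand)
        groups.setdefault(key, []).append(i)
    flag = [False] * len(reads)
    for members in groups.values():
        if len(members) == 1:
            continue
        keep = min(members, key=lambda i: (-int(reads[i].base_qualities.sum()), reads[i].sequence, i))
        for i in members:
            flag[i] = i != keep
    return [replace(r, duplicate_flag=f) if r.duplicate_flag != f else r for r, f in zip(reads, flag)]
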