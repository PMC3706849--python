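"""Synthetic genome and multi-run read simulation with paralog mismapping.

The generator builds a small diploid genome containing a segmental
duplication family — one source segment copied several times at ~95%
identity — plants heterozygous / homozygous / hemizygous sample variants and
paralog-only differences, and simulates alignment tables for several
sequencing runs at differing depths. Alignment is generative, not performed:
a configurable fraction of reads that truly originate inside a duplication
copy is reported at the homologous source coordinates with a low mapping
quality, carrying the copy's divergent bases, which is exactly how paralogous
sequence variants (PSVs) masquerade as sample variants downstream.

All outputs are fully determined by the configured seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .mismap import DuplicationAnnotation, DupInterval
from .reads import BASES, AlignedRead, ReadOrigin, Reference, decode_bases

ZYG_HET = "het"
ZYG_HOM = "hom"
ZYG_HEMI = "hemizygous"

CLASS_FUNCTIONAL = "functional"
CLASS_PARALOG_ONLY = "paralog_only"


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclass(frozen=True)
class ChromosomeSpec:
    name: str
    length: int
    is_x: bool = False


@dataclass(frozen=True)
class DupSegmentSpec:
    """Source interval plus how it is copied around the genome.

    ``copy_sites`` pins copy placements explicitly; when omitted, copies are
    packed deterministically onto autosomes left to right with a fixed gap.
    """

    chrom: str
    start: int  # 0-based half-open source interval
    end: int
    copy_count: int = 4
    divergence: float = 0.05  # per-base substitution rate in each copy
    copy_sites: Optional[tuple[tuple[str, int], ...]] = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ConfigurationError("duplication segment must have positive length")
        if self.copy_count < 0:
            raise ConfigurationError("copy_count must be >= 0")
        if not 0 <= self.divergence <= 1:
            raise ConfigurationError("divergence must lie in [0, 1]")
        if self.copy_sites is not None and len(self.copy_sites) != self.copy_count:
            raise ConfigurationError("copy_sites length must equal copy_count")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class PlantedVariant:
    """One sample variant to plant. Positions are 1-based.

    Paralog-only variants may be given relative to a duplication copy
    (``copy_index`` + ``segment_offset``) because copy placements are part of
    reference construction; they are resolved to absolute coordinates during
    planting. ``ref``/``alt`` of None are filled from the reference (alt is
    the next base cyclically — deterministic).
    """

    zygosity: str
    chrom: Optional[str] = None
    pos: Optional[int] = None
    ref: Optional[str] = None
    alt: Optional[str] = None
    locus_class: str = CLASS_FUNCTIONAL
    copy_index: Optional[int] = None
    segment_offset: Optional[int] = None

    def __post_init__(self) -> None:
        if self.zygosity not in (ZYG_HET, ZYG_HOM, ZYG_HEMI):
            raise ConfigurationError(f"unknown zygosity {self.zygosity!r}")
        if self.locus_class not in (CLASS_FUNCTIONAL, CLASS_PARALOG_ONLY):
            raise ConfigurationError(f"unknown locus_class {self.locus_class!r}")
        positioned = self.chrom is not None and self.pos is not None
        relative = self.copy_index is not None and self.segment_offset is not None
        if positioned == relative:
            raise ConfigurationError("give either (chrom, pos) or (copy_index, segment_offset)")


@dataclass(frozen=True)
class RunProfile:
    """Per-run sequencing model: depth, read length, error/duplicate/mismap rates."""

    run_id: str
    platform: str
    mean_depth: float  # fold-coverage of a diploid autosomal site
    read_length: int = 100
    error_rate: float = 0.001  # substitution-only
    duplicate_rate: float = 0.0  # target fraction of final reads that are injected copies
    mismap_rate: float = 0.2  # fraction of copy-origin reads reported at the source
    low_mapq_value: int = 0  # MAPQ assigned to mismapped (ambiguous) placements
    base_quality: int = 30

    def __post_init__(self) -> None:
        for name in ("error_rate", "duplicate_rate", "mismap_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        if self.mean_depth <= 0:
            raise ConfigurationError("mean_depth must be positive")
        if self.read_length <= 0:
            raise ConfigurationError("read_length must be positive")


@dataclass
class SimulationConfig:
    chromosomes: list[ChromosomeSpec]
    dup_segment: Optional[DupSegmentSpec]
    sample_sex: str
    variant_specs: list[PlantedVariant]
    run_profiles: list[RunProfile]
    seed: int = 1

    def __post_init__(self) -> None:
        if self.sample_sex not in ("male", "female"):
            raise ConfigurationError("sample_sex must be 'male' or 'female'")
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate chromosome names")
        ids = [p.run_id for p in self.run_profiles]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("duplicate run ids")

    @property
    def genome_length(self) -> int:
        return sum(c.length for c in self.chromosomes)

    @property
    def x_chroms(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.chromosomes if c.is_x)


@dataclass
class SampleGenome:
    """Two haplotypes per autosome (one X for a male) with variants applied."""

    reference: Reference
    sex: str
    haplotypes: dict[str, list[np.ndarray]]
    variants: list[PlantedVariant]  # fully resolved
    duplications: Optional[DuplicationAnnotation] = None

    def ploidy(self, chrom: str) -> int:
        return len(self.haplotypes[chrom])


def _auto_place_copies(config_chroms: list[ChromosomeSpec], spec: DupSegmentSpec) -> list[tuple[str, int]]:
    """Deterministic left-to-right packing of copies onto autosomes."""
    gap = max(500, spec.length // 4)
    occupied: dict[str, list[tuple[int, int]]] = {spec.chrom: [(spec.start, spec.end)]}
    sites: list[tuple[str, int]] = []
    for _ in range(spec.copy_count):
        placed = False
        for c in config_chroms:
            if c.is_x:
                continue
            cursor = gap
            for s, e in sorted(occupied.get(c.name, [])):
                if s - cursor >= spec.length + gap:
                    break
                cursor = max(cursor, e + gap)
            if cursor + spec.length + gap <= c.length:
                sites.append((c.name, cursor))
                occupied.setdefault(c.name, []).append((cursor, cursor + spec.length))
                placed = True
                break
        if not placed:
            raise ConfigurationError("no room to place all duplication copies")
    return sites


def build_reference(config: SimulationConfig) -> tuple[Reference, DuplicationAnnotation]:
    """Random genome plus the duplication family carved into it.

    Each copy differs from the source by independent substitutions at rate
    ``divergence``; the annotation records every member of the family (the
    source with identity 100, each copy with its realized percent identity).
    """
    rng = np.random.default_rng(config.seed)
    seqs = {c.name: rng.integers(0, 4, c.length, dtype=np.uint8) for c in config.chromosomes}
    lengths = {c.name: c.length for c in config.chromosomes}
    intervals: list[DupInterval] = []
    spec = config.dup_segment
    if spec is not None:
        if spec.chrom not in seqs or spec.end > lengths[spec.chrom]:
            raise ConfigurationError("duplication segment does not fit its host chromosome")
        sites = list(spec.copy_sites) if spec.copy_sites is not None else _auto_place_copies(config.chromosomes, spec)
        src = seqs[spec.chrom][spec.start : spec.end].copy()
        placed = [(spec.chrom, spec.start, spec.end)]
        source_locus = f"{spec.chrom}:{spec.start}-{spec.end}"
        for chrom, start in sites:
            end = start + spec.length
            if chrom not in seqs or end > lengths[chrom]:
                raise ConfigurationError(f"copy at {chrom}:{start} does not fit its chromosome")
            for pchrom, ps, pe in placed:
                if chrom == pchrom and start < pe and end > ps:
                    raise ConfigurationError(f"copy at {chrom}:{start} overlaps another family member")
            copy = src.copy()
            m = rng.random(spec.length) < spec.divergence
            n_sub = int(m.sum())
            if n_sub:
                copy[m] = (copy[m] + rng.integers(1, 4, n_sub, dtype=np.uint8)) % 4
            seqs[chrom][start:end] = copy
            identity = 100.0 * float(np.mean(copy == src))
            intervals.append(DupInterval(chrom, start, end, identity, partner=source_locus, is_source=False))
            placed.append((chrom, start, end))
        mean_identity = float(np.mean([iv.identity for iv in intervals])) if intervals else 100.0
        intervals.insert(0, DupInterval(spec.chrom, spec.start, spec.end, mean_identity, partner="source", is_source=True))
    reference = Reference(seqs, x_chroms=[c.name for c in config.chromosomes if c.is_x])
    return reference, DuplicationAnnotation(intervals)


class VariantSpecError(ValueError):
    """A planted-variant spec conflicts with the reference or the sample sex."""


def _resolve_spec(
    spec: PlantedVariant, reference: Reference, duplications: Optional[DuplicationAnnotation]
) -> PlantedVariant:
    chrom, pos = spec.chrom, spec.pos
    if chrom is None:
        if duplications is None:
            raise VariantSpecError("copy-relative variant spec needs a duplication annotation")
        copies = duplications.copies
        if not 0 <= spec.copy_index < len(copies):
            raise VariantSpecError(f"copy_index {spec.copy_index} out of range")
        iv = copies[spec.copy_index]
        if not 0 <= spec.segment_offset < iv.end - iv.start:
            raise VariantSpecError("segment_offset outside the duplication copy")
        chrom, pos = iv.chrom, iv.start + spec.segment_offset + 1
    code = int(reference.codes(chrom)[pos - 1])
    ref = BASES[code]
    if spec.ref is not None and spec.ref != ref:
        raise VariantSpecError(f"spec ref {spec.ref} != reference base {ref} at {chrom}:{pos}")
    if spec.alt is not None:
        alt = spec.alt
    elif spec.locus_class == CLASS_PARALOG_ONLY and duplications is not None:
        # keep the paralog allele distinct from the homologous source base,
        # otherwise the mismapping artifact would be invisible at the source
        iv = duplications.overlapping(chrom, pos - 1)
        src = duplications.source
        forbidden = {ref}
        if iv is not None and src is not None and not iv.is_source:
            forbidden.add(BASES[int(reference.codes(src.chrom)[src.start + (pos - 1 - iv.start)])])
        alt = next(b for b in BASES if b not in forbidden)
    else:
        alt = BASES[(code + 1) % 4]
    if alt == ref:
        raise VariantSpecError(f"alt equals reference base at {chrom}:{pos}")
    return replace(spec, chrom=chrom, pos=pos, ref=ref, alt=alt, copy_index=None, segment_offset=None)


def plant_variants(
    reference: Reference,
    specs: Iterable[PlantedVariant],
    sex: str,
    duplications: Optional[DuplicationAnnotation] = None,
) -> SampleGenome:
    """Apply variant specs to haplotype copies of the reference.

    Rules: het on one haplotype, hom on both, hemizygous on the single male X;
    a het spec on the male X is an error (the true genotype there cannot be
    heterozygous). Paralog-only variants must fall inside a duplication copy
    (never the source) and are applied as fixed differences of that copy.
    """
    haplotypes = {
        name: [reference.codes(name).copy() for _ in range(1 if (sex == "male" and reference.is_x(name)) else 2)]
        for name in reference.names
    }
    resolved: list[PlantedVariant] = []
    for spec in specs:
        v = _resolve_spec(spec, reference, duplications)
        on_x = reference.is_x(v.chrom)
        if v.locus_class == CLASS_PARALOG_ONLY:
            iv = duplications.overlapping(v.chrom, v.pos - 1) if duplications else None
            if iv is None or iv.is_source:
                raise VariantSpecError(
                    f"paralog_only variant at {v.chrom}:{v.pos} must lie inside a duplication copy"
                )
            targets = haplotypes[v.chrom]  # fixed difference of the copy: all haplotypes
        elif v.zygosity == ZYG_HEMI:
            if not (on_x and sex == "male"):
                raise VariantSpecError("hemizygous spec requires a male X site")
            targets = haplotypes[v.chrom]
        elif v.zygosity == ZYG_HET:
            if on_x and sex == "male":
                raise VariantSpecError(
                    f"het spec on the male X at {v.chrom}:{v.pos} (must be hemizygous)"
                )
            targets = haplotypes[v.chrom][:1]
        else:  # hom
            targets = haplotypes[v.chrom]
        alt_code = BASES.index(v.alt)
        for hap in targets:
            hap[v.pos - 1] = alt_code
        resolved.append(v)
    return SampleGenome(reference, sex, haplotypes, resolved, duplications)


def simulate_run(sample: SampleGenome, profile: RunProfile, seed: int) -> list[AlignedRead]:
    """Simulate one run's alignment table for ``sample``.

    Reads are placed uniformly over all haplotype copies, so an autosomal site
    sees ``mean_depth`` and the single male X half of it. Substitution errors
    occur at ``error_rate`` per base. A fraction ``mismap_rate`` of reads fully
    contained in a duplication copy is reported at the homologous source
    coordinates with MAPQ ``low_mapq_value`` (correctly placed reads get MAPQ
    60). Exact-copy duplicate reads are injected at ``duplicate_rate``. Every
    read records its true origin.
    """
    rng = np.random.default_rng(seed)
    rl = profile.read_length
    ref = sample.reference
    chromatids = [
        (chrom, h, arr)
        for chrom in ref.names
        for h, arr in enumerate(sample.haplotypes[chrom])
        if len(arr) >= rl
    ]
    if not chromatids:
        return []
    total_bases = sum(len(arr) for _, _, arr in chromatids)
    n_reads = int(round(profile.mean_depth * total_bases / (2.0 * rl)))
    if n_reads == 0:
        return []
    n_starts = np.array([len(arr) - rl + 1 for _, _, arr in chromatids], dtype=np.float64)
    counts = rng.multinomial(n_reads, n_starts / n_starts.sum())

    source = None
    copies_by_chrom: dict[str, list[DupInterval]] = {}
    if sample.duplications is not None and sample.duplications.source is not None:
        source = sample.duplications.source
        for iv in sample.duplications.copies:
            copies_by_chrom.setdefault(iv.chrom, []).append(iv)

    qual_template = np.full(rl, profile.base_quality, dtype=np.uint8)
    qual_template.setflags(write=False)
    reads: list[AlignedRead] = []
    for (chrom, hap, arr), k in zip(chromatids, counts):
        if k == 0:
            continue
        starts = np.sort(rng.integers(0, len(arr) - rl + 1, size=k))
        seq = sliding_window_view(arr, rl)[starts].copy()
        err = rng.random((k, rl)) < profile.error_rate
        n_err = int(err.sum())
        if n_err:
            seq[err] = (seq[err] + rng.integers(1, 4, n_err, dtype=np.uint8)) % 4
        rev = rng.random(k) < 0.5
        mism = np.zeros(k, dtype=bool)
        rep_start = starts.copy()
        for iv in copies_by_chrom.get(chrom, []):
            inside = (starts >= iv.start) & (starts + rl <= iv.end)
            take = inside & (rng.random(k) < profile.mismap_rate)
            mism |= take
            rep_start[take] = source.start + (starts[take] - iv.start)
        for i in range(k):
            mm = bool(mism[i])
            reads.append(
                AlignedRead(
                    run_id=profile.run_id,
                    chrom=source.chrom if mm else chrom,
                    start=int(rep_start[i]),
                    strand="-" if rev[i] else "+",
                    mapq=profile.low_mapq_value if mm else 60,
                    sequence=decode_bases(seq[i]),
                    base_qualities=qual_template,
                    truth_origin=ReadOrigin(chrom, int(starts[i]), hap, mismapped=mm),
                )
            )
    if profile.duplicate_rate > 0 and reads:
        n = len(reads)
        k_dup = int(round(n * profile.duplicate_rate / (1.0 - profile.duplicate_rate)))
        for i in np.sort(rng.integers(0, n, size=k_dup)):
            t = reads[int(i)]
            reads.append(
                AlignedRead(
                    run_id=t.run_id,
                    chrom=t.chrom,
                    start=t.start,
                    strand=t.strand,
                    mapq=t.mapq,
                    sequence=t.sequence,
                    base_qualities=t.base_qualities,
                    truth_origin=replace(t.truth_origin, duplicate=True),
                )
            )
    order = {name: i for i, name in enumerate(ref.names)}
    reads.sort(key=lambda r: (order[r.chrom], r.start))
    return reads


def run_seed(config_seed: int, run_id: str) -> int:
    """Deterministic per-run child seed (stays below 2**31)."""
    return (config_seed * 1_000_003 + zlib.crc32(run_id.encode())) % (2**31 - 1)


def expected_artifact_vf(mismap_rate: float, copy_count: int, source_ploidy: int, carriers: int = 1) -> float:
    """Closed-form apparent variant fraction at the source locus of a PSV.

    Depth at the source is D*p/2 from correct reads plus D*m per copy of
    mismapped reads; a PSV carried by ``carriers`` copies therefore shows
    vf = carriers*m / (p/2 + copy_count*m).
    """
    return carriers * mismap_rate / (source_ploidy / 2.0 + copy_count * mismap_rate)


def truth_table(sample: SampleGenome, mismap_rate: float) -> pd.DataFrame:
    """One row per planted variant, with the expected apparent variant fraction.

    For paralog-only variants the row also carries the homologous source-locus
    coordinates where the mismapping artifact is expected to appear; the
    expected vf there uses the closed form of :func:`expected_artifact_vf`.
    """
    rows = []
    dup = sample.duplications
    for v in sample.variants:
        src_chrom = src_pos = None
        if v.zygosity == ZYG_HET:
            evf = 0.5
        else:
            evf = 1.0
        if v.locus_class == CLASS_PARALOG_ONLY:
            iv = dup.overlapping(v.chrom, v.pos - 1)
            src = dup.source
            src_chrom = src.chrom
            src_pos = src.start + (v.pos - 1 - iv.start) + 1
            ploidy = sample.ploidy(src.chrom)
            evf = expected_artifact_vf(mismap_rate, len(dup.copies), ploidy)
        rows.append(
            {
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "zygosity": v.zygosity,
                "locus_class": v.locus_class,
                "source_chrom": src_chrom,
                "source_pos": src_pos,
                "expected_vf": evf,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "pos",
            "ref",
            "alt",
            "zygosity",
            "locus_class",
            "source_chrom",
            "source_pos",
            "expected_vf",
        ],
    )


def psv_table(reference: Reference, duplications: DuplicationAnnotation) -> pd.DataFrame:
    """All realized paralogous sequence variants of the duplication family.

    Positions where a copy's sequence differs from the source, with both the
    copy coordinates and the homologous source coordinates (1-based) and the
    base each locus carries.
    """
    src = duplications.source
    if src is None:
        return pd.DataFrame(columns=["copy_index", "chrom", "pos", "source_pos", "source_base", "copy_base"])
    src_seq = reference.codes(src.chrom)[src.start : src.end]
    rows = []
    for idx, iv in enumerate(duplications.copies):
        copy_seq = reference.codes(iv.chrom)[iv.start : iv.end]
        for off in np.flatnonzero(copy_seq != src_seq):
            rows.append(
                {
                    "copy_index": idx,
                    "chrom": iv.chrom,
                    "pos": iv.start + int(off) + 1,
                    "source_pos": src.start + int(off) + 1,
                    "source_base": BASES[src_seq[off]],
                    "copy_base": BASES[copy_seq[off]],
                }
            )
    return pd.DataFrame(rows, columns=["copy_index", "chrom", "pos", "source_pos", "source_base", "copy_base"])


@dataclass
class CohortSim:
    """Everything one simulated study produces, kept in memory."""

    config: SimulationConfig
    reference: Reference
    duplications: DuplicationAnnotation
    sample: SampleGenome
    truth: pd.DataFrame
    runs: dict[str, list[AlignedRead]]
    targets: list[tuple[str, int, int]] = field(default_factory=list)


def default_targets(reference: Reference, tile: int = 300, spacing: int = 500) -> list[tuple[str, int, int]]:
    """Capture-style target intervals: a `tile`-bp target every `spacing` bp."""
    targets = []
    for name, length in reference.lengths.items():
        for start in range(0, length - tile, spacing):
            targets.append((name, start, start + tile))
    return targets


def simulate_cohort(config: SimulationConfig, profiles: Optional[Iterable[RunProfile]] = None) -> CohortSim:
    """Build the reference, plant the sample, and simulate every configured run."""
    reference, duplications = build_reference(config)
    sample = plant_variants(reference, config.variant_specs, config.sample_sex, duplications)
    profiles = list(profiles) if profiles is not None else config.run_profiles
    mismap = profiles[0].mismap_rate if profiles else 0.0
    runs = {p.run_id: simulate_run(sample, p, run_seed(config.seed, p.run_id)) for p in profiles}
    return CohortSim(
        config=config,
        reference=reference,
        duplications=duplications,
        sample=sample,
        truth=truth_table(sample, mismap),
        runs=runs,
        targets=default_targets(reference),
    )


def het_read_counts(n_sites: int, depth: int, seed: int) -> np.ndarray:
    """Variant-read counts at ``n_sites`` independent het sites of fixed depth.

    Each read samples one of the two haplotypes uniformly, the same mechanism
    the full simulator uses, so counts are Binomial(depth, 1/2).
    """
    rng = np.random.default_rng(seed)
    return rng.integers(0, 2, size=(n_sites, depth), dtype=np.int8).sum(axis=1)


def default_config(seed: int = 1) -> SimulationConfig:
    """The study conditions the simulator emulates by default.

    A 60 kb genome (two autosomes plus an X), a 2 kb segment on the X copied
    four times onto the autosomes at 5% divergence (the reported 9,757 bp /
    four copies / ~95% identity regime, scaled down), a male sample with
    functional het/hom/compound-het and X-hemizygous variants plus twelve
    paralog-only variants (three per copy), and six runs whose depths follow
    the reported spread (138/137/170/169x Illumina-like, 65x and 93x
    ion-chip-like with higher error and duplicate rates).
    """
    chroms = [
        ChromosomeSpec("chr1", 25_000),
        ChromosomeSpec("chr2", 20_000),
        ChromosomeSpec("chrX", 15_000, is_x=True),
    ]
    dup = DupSegmentSpec(
        chrom="chrX",
        start=4_000,
        end=6_000,
        copy_count=4,
        divergence=0.05,
        copy_sites=(("chr1", 12_000), ("chr1", 16_000), ("chr2", 5_000), ("chr2", 9_000)),
    )
    functional = [
        PlantedVariant(ZYG_HET, "chr1", 2_001),
        PlantedVariant(ZYG_HOM, "chr1", 3_001),
        PlantedVariant(ZYG_HET, "chr1", 8_001),  # compound-het pair, same locus window
        PlantedVariant(ZYG_HET, "chr1", 8_051),
        PlantedVariant(ZYG_HET, "chr1", 20_001),
        PlantedVariant(ZYG_HOM, "chr1", 22_001),
        PlantedVariant(ZYG_HET, "chr2", 1_501),
        PlantedVariant(ZYG_HOM, "chr2", 2_501),
        PlantedVariant(ZYG_HET, "chr2", 15_001),
        PlantedVariant(ZYG_HEMI, "chrX", 10_001),
        PlantedVariant(ZYG_HEMI, "chrX", 12_001),
    ]
    # distinct offsets per copy so the twelve artifacts project onto twelve
    # distinct source positions
    paralog = [
        PlantedVariant(ZYG_HOM, locus_class=CLASS_PARALOG_ONLY, copy_index=c, segment_offset=off)
        for c in range(4)
        for off in (150 + 87 * c, 700 + 87 * c, 1_250 + 87 * c)
    ]
    profiles = [
        RunProfile("gaii_1", "illumina_gaii", 138, 100, 0.001, 0.05),
        RunProfile("gaii_2", "illumina_gaii", 137, 100, 0.001, 0.04),
        RunProfile("hiseq_1", "illumina_hiseq", 170, 100, 0.001, 0.06),
        RunProfile("hiseq_2", "illumina_hiseq", 169, 100, 0.001, 0.06),
        RunProfile("pgm", "ion_pgm", 65, 200, 0.01, 0.25),
        RunProfile("proton", "ion_proton", 93, 100, 0.01, 0.19),
    ]
    return SimulationConfig(
        chromosomes=chroms,
        dup_segment=dup,
        sample_sex="male",
        variant_specs=functional + paralog,
        run_profiles=profiles,
        seed=seed,
    )
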