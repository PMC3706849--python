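"""Read and reference containers shared across the pipeline.

Coordinates are 0-based half-open internally (and in BED); VCF-facing
positions are 1-based. Sequences are stored reference-oriented, as in SAM:
the strand flag is bookkeeping for strand-bias tests, not an instruction to
reverse-complement.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Optional

import numpy as np

BASES = "ACGT"
N_CODE = 4

_ENCODE = np.full(256, N_CODE, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i
_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)


def encode_bases(seq: str) -> np.ndarray:
    """Map an ACGT string to uint8 codes (A=0 .. T=3; anything else 4)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)].copy()


def decode_bases(codes: np.ndarray) -> str:
    """Inverse of :func:`encode_bases`; code 4+ renders as ``N``."""
    return _DECODE[np.minimum(np.asarray(codes, dtype=np.uint8), N_CODE)].tobytes().decode("ascii")


@dataclass(frozen=True)
class ReadOrigin:
    """Truth provenance of a simulated read (simulation only).

    ``chrom``/``start`` are the read's *true* origin, which differs from the
    reported alignment when the read was mismapped from a duplication copy.
    """

    chrom: str
    start: int
    haplotype: int
    mismapped: bool = False
    duplicate: bool = False

    def to_tag(self) -> str:
        return f"{self.chrom}|{self.start}|{self.haplotype}|{int(self.mismapped)}|{int(self.duplicate)}"

    @classmethod
    def from_tag(cls, tag: str) -> "ReadOrigin":
        chrom, start, hap, mism, dup = tag.split("|")
        return cls(chrom, int(start), int(hap), bool(int(mism)), bool(int(dup)))


@dataclass(eq=False)
class AlignedRead:
    """One mapped read: reported coordinates plus optional truth provenance."""

    run_id: str
    chrom: str
    start: int  # 0-based reported alignment start
    strand: str  # "+" or "-"
    mapq: int
    sequence: str
    base_qualities: np.ndarray
    duplicate_flag: bool = False
    truth_origin: Optional[ReadOrigin] = None

    def __post_init__(self) -> None:
        if not isinstance(self.base_qualities, np.ndarray):
            self.base_qualities = np.asarray(self.base_qualities, dtype=np.uint8)
        if len(self.sequence) != len(self.base_qualities):
            raise ValueError("sequence and base_qualities lengths differ")
        if not 0 <= self.mapq <= 60:
            raise ValueError(f"mapq {self.mapq} outside [0, 60]")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.start < 0:
            raise ValueError("negative alignment start")

    @property
    def end(self) -> int:
        """0-based exclusive end of the reported alignment."""
        return self.start + len(self.sequence)

    def overlaps(self, chrom: str, pos0: int) -> bool:
        return self.chrom == chrom and self.start <= pos0 < self.end

    def base_at(self, pos0: int) -> str:
        """Reported base covering reference position ``pos0`` (0-based)."""
        return self.sequence[pos0 - self.start]


class Reference:
    """In-memory genome: ordered contig name -> uint8 base codes, plus a sex model."""

    def __init__(self, seqs: Mapping[str, np.ndarray], x_chroms: Iterable[str] = ()):
        self._seqs = {name: np.ascontiguousarray(codes, dtype=np.uint8) for name, codes in seqs.items()}
        self.x_chroms = frozenset(x_chroms)
        unknown = self.x_chroms - set(self._seqs)
        if unknown:
            raise ValueError(f"x_chroms not in reference: {sorted(unknown)}")

    @classmethod
    def from_strings(cls, seqs: Mapping[str, str], x_chroms: Iterable[str] = ()) -> "Reference":
        return cls({n: encode_bases(s) for n, s in seqs.items()}, x_chroms)

    @property
    def names(self) -> list[str]:
        return list(self._seqs)

    @property
    def lengths(self) -> dict[str, int]:
        return {n: len(s) for n, s in self._seqs.items()}

    def __contains__(self, name: str) -> bool:
        return name in self._seqs

    def codes(self, name: str) -> np.ndarray:
        return self._seqs[name]

    def seq(self, name: str) -> str:
        return decode_bases(self._seqs[name])

    def base(self, chrom: str, pos0: int) -> str:
        return BASES[self._seqs[chrom][pos0]] if self._seqs[chrom][pos0] < 4 else "N"

    def is_x(self, chrom: str) -> bool:
        if chrom not in self._seqs:
            raise KeyError(f"unknown contig {chrom!r}")
        return chrom in self.x_chroms

    @property
    def chrom_model(self) -> dict[str, bool]:
        """Mapping contig -> is-X, for hemizygosity checks."""
        return {n: n in self.x_chroms for n in self._seqs}


class ReadIndex:
    """Sorted per-chromosome index for pulling the reads that overlap one site."""

    def __init__(self, reads: Iterable[AlignedRead]):
        per_chrom: dict[str, list[AlignedRead]] = {}
        for r in reads:
            per_chrom.setdefault(r.chrom, []).append(r)
        self._starts: dict[str, list[int]] = {}
        self._reads: dict[str, list[AlignedRead]] = {}
        self._max_len: dict[str, int] = {}
        for chrom, rs in per_chrom.items():
            rs.sort(key=lambda r: r.start)
            self._reads[chrom] = rs
            self._starts[chrom] = [r.start for r in rs]
            self._max_len[chrom] = max(len(r.sequence) for r in rs)

    def at(self, chrom: str, pos0: int) -> list[AlignedRead]:
        """All reads whose reported alignment covers ``pos0`` (duplicates included)."""
        if chrom not in self._reads:
            return []
        starts = self._starts[chrom]
        lo = bisect.bisect_left(starts, pos0 - self._max_len[chrom] + 1)
        hi = bisect.bisect_right(starts, pos0)
        return [r for r in self._reads[chrom][lo:hi] if r.end > pos0]

    def __iter__(self) -> Iterator[AlignedRead]:
        for chrom in self._reads:
            yield from self._reads[chrom]
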