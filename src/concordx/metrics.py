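"""Run-level quality metrics over capture targets.

Coverage statistics use the caller's view of the data — non-duplicate reads
passing the mapping-quality floor — so "fraction of targeted bases at 20x+"
means 20 reads the caller would actually count. Raw read totals and the
duplicate fraction are reported separately.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .caller import CallerThresholds, DEFAULT_THRESHOLDS, VariantCall
from .reads import AlignedRead


@dataclass
class RunMetrics:
    run_id: str
    total_reads: int
    duplicate_fraction: float
    aligned_fraction: float
    on_target_fraction: float
    mean_target_coverage: float
    median_target_coverage: float
    frac_bases_10x: float
    frac_bases_20x: float
    frac_bases_40x: float
    total_snvs: Optional[int] = None
    target_snvs: Optional[int] = None

    def __post_init__(self) -> None:
        fracs = [
            self.duplicate_fraction,
            self.aligned_fraction,
            self.on_target_fraction,
            self.frac_bases_10x,
            self.frac_bases_20x,
            self.frac_bases_40x,
        ]
        if any(not 0 <= f <= 1 for f in fracs):
            raise ValueError("fractions must lie in [0, 1]")

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def run_metrics(
    reads: Sequence[AlignedRead],
    targets: Sequence[tuple[str, int, int]],
    thresholds: CallerThresholds = DEFAULT_THRESHOLDS,
    calls: Optional[Iterable[VariantCall]] = None,
) -> RunMetrics:
    """Compute run-level metrics for one read set over target intervals.

    ``targets`` are BED-convention intervals (0-based half-open). SNV counts
    are filled only when ``calls`` is supplied.
    """
    targets = list(targets)
    if not targets:
        raise ValueError("empty target set")
    run_id = reads[0].run_id if reads else ""

    # per-chromosome boolean target masks and coverage diff arrays
    chrom_len: dict[str, int] = {}
    for chrom, start, end in targets:
        if end <= start or start < 0:
            raise ValueError(f"bad target interval {chrom}:{start}-{end}")
        chrom_len[chrom] = max(chrom_len.get(chrom, 0), end)
    for r in reads:
        if r.chrom in chrom_len:
            chrom_len[r.chrom] = max(chrom_len[r.chrom], r.end)
    masks = {c: np.zeros(n, dtype=bool) for c, n in chrom_len.items()}
    for chrom, start, end in targets:
        masks[chrom][start:end] = True

    diffs = {c: np.zeros(n + 1, dtype=np.int64) for c, n in chrom_len.items()}
    n_dup = n_aligned = n_on_target = 0
    for r in reads:
        if r.chrom is not None:
            n_aligned += 1
        if r.duplicate_flag:
            n_dup += 1
        mask = masks.get(r.chrom)
        if mask is not None and mask[r.start : r.end].any():
            n_on_target += 1
        if r.duplicate_flag or r.mapq < thresholds.min_mapq:
            continue
        d = diffs.get(r.chrom)
        if d is not None:
            d[r.start] += 1
            d[r.end] -= 1

    per_base = np.concatenate(
        [np.cumsum(diffs[c][:-1])[masks[c]] for c in sorted(chrom_len)]
    ) if chrom_len else np.empty(0, dtype=np.int64)

    n_reads = len(reads)
    total_snvs = target_snvs = None
    if calls is not None:
        calls = list(calls)
        total_snvs = len(calls)
        target_snvs = sum(
            1
            for c in calls
            if c.chrom in masks and c.pos - 1 < len(masks[c.chrom]) and masks[c.chrom][c.pos - 1]
        )

    return RunMetrics(
        run_id=run_id,
        total_reads=n_reads,
        duplicate_fraction=n_dup / n_reads if n_reads else 0.0,
        aligned_fraction=n_aligned / n_reads if n_reads else 0.0,
        on_target_fraction=n_on_target / n_reads if n_reads else 0.0,
        mean_target_coverage=float(per_base.mean()) if per_base.size else 0.0,
        median_target_coverage=float(np.median(per_base)) if per_base.size else 0.0,
        frac_bases_10x=float(np.mean(per_base >= 10)) if per_base.size else 0.0,
        frac_bases_20x=float(np.mean(per_base >= 20)) if per_base.size else 0.0,
        frac_bases_40x=float(np.mean(per_base >= 40)) if per_base.size else 0.0,
        total_snvs=total_snvs,
        target_snvs=target_snvs,
    )
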