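"""Explaining why a call present in one run is absent in another.

A fixed decision cascade assigns exactly one cause per missed variant, in the
order the causes dominate between same-platform replicate runs: no coverage,
insufficient filtered coverage, strand bias of the alternate support, low
variant ratio, and finally low quality of the supporting bases/alignments.
The cascade itself is this package's operationalization — the source ranking
names the causes but not the decision rules — and it shares every threshold
with the caller so "missed" means "the caller would have filtered it".
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .caller import CallerThresholds, DEFAULT_THRESHOLDS, PileupColumn, strand_bias
from .concordance import VariantKey


class Cause(enum.Enum):
    NOT_COVERED = "NOT_COVERED"
    LOW_COVERAGE = "LOW_COVERAGE"
    STRAND_BIAS = "STRAND_BIAS"
    LOW_VARIANT_RATIO = "LOW_VARIANT_RATIO"
    LOW_QUALITY = "LOW_QUALITY"


@dataclass
class DiscordanceRecord:
    """Why one variant key, called in one run, went missing in another."""

    key: VariantKey
    called_in: str
    absent_in: str
    cause: Cause
    raw_depth: int
    filtered_depth: int
    vf: float
    alt_fwd: int
    alt_rev: int
    mean_alt_mapq: float


def classify_missed(
    key: VariantKey,
    absent_run_pileup: PileupColumn,
    thresholds: CallerThresholds = DEFAULT_THRESHOLDS,
    *,
    called_in: str = "",
    absent_in: str = "",
) -> DiscordanceRecord:
    """Assign the first matching cause for a missed call; the cascade is total.

    Order: NOT_COVERED (raw depth 0) -> LOW_COVERAGE (filtered depth below
    min_coverage) -> STRAND_BIAS (alt present but strand test biased) ->
    LOW_VARIANT_RATIO (vf below min_maf or below the het band) -> LOW_QUALITY
    (everything else: alt support was eaten by base/mapping-quality filters).
    """
    chrom, pos, ref, alt = key
    if absent_run_pileup.chrom != chrom or absent_run_pileup.pos != pos:
        raise ValueError(f"pileup column is for {absent_run_pileup.chrom}:{absent_run_pileup.pos}, not {chrom}:{pos}")
    if absent_run_pileup.ref != ref:
        raise ValueError(f"pileup reference base {absent_run_pileup.ref} != key ref {ref}")

    col = absent_run_pileup
    rr = col.count(ref)
    vr = col.count(alt)
    vf = vr / (rr + vr) if rr + vr else 0.0

    if col.raw_depth == 0:
        cause = Cause.NOT_COVERED
    elif col.filtered_depth < thresholds.min_coverage:
        cause = Cause.LOW_COVERAGE
    else:
        _, biased = strand_bias(col, alt, thresholds)
        if vr > 0 and biased:
            cause = Cause.STRAND_BIAS
        elif vf < thresholds.min_maf or vf < thresholds.het_lower_vf:
            cause = Cause.LOW_VARIANT_RATIO
        else:
            cause = Cause.LOW_QUALITY

    return DiscordanceRecord(
        key=key,
        called_in=called_in,
        absent_in=absent_in,
        cause=cause,
        raw_depth=col.raw_depth,
        filtered_depth=col.filtered_depth,
        vf=vf,
        alt_fwd=col.count(alt, "+"),
        alt_rev=col.count(alt, "-"),
        mean_alt_mapq=col.mean_raw_mapq(alt),
    )


def summarize_causes(records: Iterable[DiscordanceRecord]) -> pd.DataFrame:
    """Counts and fractions per cause per run pair, in fixed cause order."""
    records = list(records)
    rows = []
    pairs = sorted({(r.called_in, r.absent_in) for r in records})
    if not pairs:
        pairs = [("", "")]
    for called_in, absent_in in pairs:
        sub = [r for r in records if (r.called_in, r.absent_in) == (called_in, absent_in)]
        total = len(sub)
        for cause in Cause:
            n = sum(r.cause is cause for r in sub)
            rows.append(
                {
                    "called_in": called_in,
                    "absent_in": absent_in,
                    "cause": cause.value,
                    "count": n,
                    "fraction": n / total if total else 0.0,
                }
            )
    return pd.DataFrame(rows, columns=["called_in", "absent_in", "cause", "count", "fraction"])
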