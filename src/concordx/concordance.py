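"""Variant-set comparison across runs and platforms.

Variant identity is the full key (chrom, pos, ref, alt) — matching position
alone is not enough. Because no single concordance denominator is canonical,
pairwise results carry all three: the key union and each run as reference
(concordant / |reference run|), the convention headline whole-genome
comparisons use.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

from .caller import VariantCall

logger = logging.getLogger(__name__)

VariantKey = tuple[str, int, str, str]
_SNV_BASES = frozenset("ACGT")


@dataclass
class RunVariantSet:
    """One run's variant keys mapped to their calls (SNVs only, decomposed)."""

    run_id: str
    platform: str = ""
    calls: dict[VariantKey, VariantCall] = field(default_factory=dict)

    def keys(self) -> set[VariantKey]:
        return set(self.calls)

    def __len__(self) -> int:
        return len(self.calls)

    def __contains__(self, key: VariantKey) -> bool:
        return key in self.calls

    @classmethod
    def from_calls(cls, calls: Iterable[VariantCall], run_id: str, platform: str = "") -> "RunVariantSet":
        out = cls(run_id=run_id, platform=platform)
        for c in calls:
            if c.key in out.calls:
                logger.warning("%s: duplicate record for %s collapsed", run_id, c.key)
            out.calls[c.key] = c
        return out

    def restrict_to_targets(self, targets: Iterable[tuple[str, int, int]]) -> "RunVariantSet":
        """Keep only keys falling in target intervals (the coding-SNV notion)."""
        per_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in targets:
            per_chrom.setdefault(chrom, []).append((start, end))
        kept = {
            k: v
            for k, v in self.calls.items()
            if any(s <= k[1] - 1 < e for s, e in per_chrom.get(k[0], ()))
        }
        return RunVariantSet(self.run_id, self.platform, kept)


def load_run(vcf_path: str, run_id: str, platform: str = "") -> RunVariantSet:
    """Read a run's VCF into a :class:`RunVariantSet`.

    SNV records only (alleles of length 1 in ACGT, uppercased); indels are
    excluded with a logged count; multiallelic records decompose into one key
    per alternate allele; duplicate keys collapse with a warning.
    """
    out = RunVariantSet(run_id=run_id, platform=platform)
    n_indel = 0
    with pysam.VariantFile(vcf_path) as vcf:
        for rec in vcf:
            ref = rec.ref.upper()
            for alt in rec.alts or ():
                alt = alt.upper()
                if len(ref) != 1 or len(alt) != 1 or ref not in _SNV_BASES or alt not in _SNV_BASES:
                    n_indel += 1
                    continue
                key = (rec.contig, rec.pos, ref, alt)
                if key in out.calls:
                    logger.warning("%s: duplicate record for %s collapsed", run_id, key)
                def _info(field, default):
                    try:  # absent INFO definitions raise inside pysam
                        value = rec.info.get(field, default)
                    except (KeyError, ValueError):
                        return default
                    return default if value is None else value

                rr = int(_info("RR", 0))
                vr = int(_info("VR", 0))
                tr = int(_info("TR", rr + vr))
                vf = float(_info("VF", vr / (rr + vr) if rr + vr else 0.0))
                out.calls[key] = VariantCall(
                    chrom=rec.contig,
                    pos=rec.pos,
                    ref=ref,
                    alt=alt,
                    rr=rr,
                    vr=vr,
                    tr=tr,
                    vf=vf,
                    ref_fwd=0,
                    ref_rev=0,
                    alt_fwd=0,
                    alt_rev=0,
                    tier=str(_info("TIER", "candidate")),
                    genotype=str(_info("GT_LABEL", "het")),
                )
    if n_indel:
        logger.info("%s: excluded %d non-SNV allele records", run_id, n_indel)
    logger.info("%s: loaded %d SNV keys", run_id, len(out))
    return out


def concordance_percent(n_concordant: int, n_reference: int) -> float:
    """Concordant calls as a percentage of a reference run's total."""
    if n_reference <= 0:
        raise ValueError("reference set must be non-empty")
    return 100.0 * n_concordant / n_reference


@dataclass
class ConcordanceResult:
    """Pairwise overlap with every denominator spelled out (percent scale)."""

    run_a: str
    run_b: str
    n_a: int
    n_b: int
    concordant: set[VariantKey]

    @property
    def n_concordant(self) -> int:
        return len(self.concordant)

    @property
    def pct_union(self) -> float:
        union = self.n_a + self.n_b - self.n_concordant
        return 100.0 * self.n_concordant / union if union else 100.0

    @property
    def pct_reference_a(self) -> float:
        return concordance_percent(self.n_concordant, self.n_a)

    @property
    def pct_reference_b(self) -> float:
        return concordance_percent(self.n_concordant, self.n_b)


def pairwise_concordance(a: RunVariantSet, b: RunVariantSet) -> ConcordanceResult:
    """Key intersection of two runs with union / per-reference-run percentages."""
    concordant = a.keys() & b.keys()
    return ConcordanceResult(run_a=a.run_id, run_b=b.run_id, n_a=len(a), n_b=len(b), concordant=concordant)


def nway_concordant(sets: Sequence[RunVariantSet]) -> set[VariantKey]:
    """Keys present in every run (needs at least two runs)."""
    if len(sets) < 2:
        raise ValueError("n-way concordance needs at least 2 variant sets")
    keys = sets[0].keys()
    for s in sets[1:]:
        keys &= s.keys()
    logger.info("n-way concordant across %d runs: %d keys", len(sets), len(keys))
    return keys


@dataclass
class PrivateCallProfile:
    """Variant-fraction / coverage records for calls private to one run."""

    run_id: str
    records: pd.DataFrame  # columns: chrom, pos, ref, alt, vf, coverage

    def __len__(self) -> int:
        return len(self.records)


def private_calls(target: RunVariantSet, others: Sequence[RunVariantSet]) -> PrivateCallProfile:
    """Calls present in ``target`` and in none of ``others``, with (vf, coverage)."""
    if any(o is target or o.run_id == target.run_id for o in others):
        raise ValueError("target run must not appear among the comparison runs")
    other_keys: set[VariantKey] = set()
    for o in others:
        other_keys |= o.keys()
    rows = [
        {"chrom": k[0], "pos": k[1], "ref": k[2], "alt": k[3], "vf": c.vf, "coverage": c.tr}
        for k, c in sorted(target.calls.items())
        if k not in other_keys
    ]
    return PrivateCallProfile(
        run_id=target.run_id,
        records=pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "vf", "coverage"]),
    )


def profile_bins(
    profile: PrivateCallProfile,
    vf_bin_width: float = 0.05,
    cov_bins: Sequence[float] = (0, 10, 20, 40, np.inf),
) -> tuple[pd.DataFrame, dict[str, float]]:
    """2-D histogram of (vf, coverage) plus the headline summary shares.

    Summary: the share of private calls with vf < 0.20 (below the reliable
    heterozygous band) and the share with vf > 0.20 but coverage < 10.
    """
    if vf_bin_width <= 0:
        raise ValueError("vf_bin_width must be positive")
    cov_edges = np.asarray(cov_bins, dtype=float)
    if len(cov_edges) < 2 or np.any(np.diff(cov_edges) <= 0):
        raise ValueError("cov_bins must be increasing with at least two edges")
    vf_edges = np.arange(0.0, 1.0 + vf_bin_width, vf_bin_width)
    if vf_edges[-1] < 1.0:
        vf_edges = np.append(vf_edges, 1.0)
    vf = profile.records["vf"].to_numpy(dtype=float) if len(profile) else np.empty(0)
    cov = profile.records["coverage"].to_numpy(dtype=float) if len(profile) else np.empty(0)
    hist, _, _ = np.histogram2d(vf, cov, bins=[vf_edges, cov_edges])
    table = pd.DataFrame(
        hist.astype(int),
        index=pd.IntervalIndex.from_breaks(np.round(vf_edges, 10), closed="left", name="vf"),
        columns=pd.IntervalIndex.from_breaks(cov_edges, closed="left", name="coverage"),
    )
    n = len(vf)
    summary = {
        "n": float(n),
        "share_vf_below_0.20": float(np.mean(vf < 0.20)) if n else 0.0,
        "share_vf_above_0.20_cov_below_10": float(np.mean((vf > 0.20) & (cov < 10))) if n else 0.0,
    }
    return table, summary


def concordance_report(sets: Sequence[RunVariantSet]) -> pd.DataFrame:
    """Tidy report: one row per run pair plus the n-way row."""
    rows = []
    for i in range(len(sets)):
        for j in range(i + 1, len(sets)):
            r = pairwise_concordance(sets[i], sets[j])
            rows.append(
                {
                    "run_a": r.run_a,
                    "run_b": r.run_b,
                    "n_a": r.n_a,
                    "n_b": r.n_b,
                    "concordant": r.n_concordant,
                    "pct_union": r.pct_union,
                    "pct_reference_a": r.pct_reference_a,
                    "pct_reference_b": r.pct_reference_b,
                }
            )
    if len(sets) >= 2:
        nway = nway_concordant(sets)
        rows.append(
            {
                "run_a": "all",
                "run_b": "+".join(s.run_id for s in sets),
                "n_a": sum(len(s) for s in sets),
                "n_b": len(sets),
                "concordant": len(nway),
                "pct_union": float("nan"),
                "pct_reference_a": float("nan"),
                "pct_reference_b": float("nan"),
            }
        )
    return pd.DataFrame(rows)
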