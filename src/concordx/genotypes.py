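"""Consensus genotyping across runs at a single site.

Deeper runs are trusted over shallow ones: runs below the caller's coverage
floor are ignored when adequate runs exist and agree, and disagreement among
adequate runs is settled by pooling their read counts and re-applying the
genotype rule. This is the logic that turns a 2-read homozygous-looking
whole-genome call plus a 65-read heterozygous exome call into a consensus
heterozygote.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .caller import CallerThresholds, DEFAULT_THRESHOLDS, TIER_HIGH_CONFIDENCE, assign_genotype
from .concordance import VariantKey

RULE_UNANIMOUS = "unanimous"
RULE_DEPTH_PREFERRED = "depth_preferred"
RULE_POOLED_RECALL = "pooled_recall"


@dataclass(frozen=True)
class RunEvidence:
    """One run's read support at a site: (rr, vr) plus optional labels."""

    run_id: str
    rr: int
    vr: int
    genotype: Optional[str] = None
    tier: Optional[str] = None

    @property
    def depth(self) -> int:
        return self.rr + self.vr

    def resolved_genotype(self, thresholds: CallerThresholds) -> str:
        return self.genotype if self.genotype is not None else assign_genotype(self.rr, self.vr, thresholds)


@dataclass
class SiteEvidence:
    key: VariantKey
    runs: list[RunEvidence] = field(default_factory=list)


@dataclass
class ConsensusCall:
    key: VariantKey
    genotype: str
    supporting_runs: list[str]
    rule: str
    pooled_counts: tuple[int, int]  # element-wise sums over contributing runs


def pooled_recall(
    counts_list: Iterable[tuple[int, int]], thresholds: CallerThresholds = DEFAULT_THRESHOLDS
) -> str:
    """Genotype from the element-wise sum of (rr, vr) pairs."""
    counts_list = list(counts_list)
    if not counts_list:
        raise ValueError("no counts to pool")
    rr = sum(c[0] for c in counts_list)
    vr = sum(c[1] for c in counts_list)
    if rr + vr == 0:
        raise ValueError("pooled counts are all zero")
    return assign_genotype(rr, vr, thresholds)


def resolve_site(
    evidence: SiteEvidence, thresholds: CallerThresholds = DEFAULT_THRESHOLDS
) -> ConsensusCall:
    """Integrate per-run evidence at one site into a consensus genotype.

    Zero-depth runs are ignored outright. Runs with depth >= min_coverage are
    "adequate": if they all agree the consensus is unanimous (depth_preferred
    when shallower runs had to be set aside); if they disagree, a single
    high-confidence adequate run wins the tie, otherwise their counts are
    pooled and the genotype rule re-applied. With no adequate run at all, all
    covered runs are pooled.
    """
    informative = sorted((r for r in evidence.runs if r.depth > 0), key=lambda r: r.run_id)
    if not informative:
        raise ValueError(f"no run has coverage at {evidence.key}")
    adequate = [r for r in informative if r.depth >= thresholds.min_coverage]

    if not adequate:
        pooled = (sum(r.rr for r in informative), sum(r.vr for r in informative))
        return ConsensusCall(
            key=evidence.key,
            genotype=assign_genotype(*pooled, thresholds),
            supporting_runs=[r.run_id for r in informative],
            rule=RULE_POOLED_RECALL,
            pooled_counts=pooled,
        )

    genotypes = {r.resolved_genotype(thresholds) for r in adequate}
    pooled = (sum(r.rr for r in adequate), sum(r.vr for r in adequate))
    if len(genotypes) == 1:
        rule = RULE_UNANIMOUS if len(adequate) == len(informative) else RULE_DEPTH_PREFERRED
        return ConsensusCall(
            key=evidence.key,
            genotype=genotypes.pop(),
            supporting_runs=[r.run_id for r in adequate],
            rule=rule,
            pooled_counts=pooled,
        )

    high_conf = [r for r in adequate if r.tier == TIER_HIGH_CONFIDENCE]
    if len(high_conf) == 1:
        winner = high_conf[0]
        return ConsensusCall(
            key=evidence.key,
            genotype=winner.resolved_genotype(thresholds),
            supporting_runs=[winner.run_id],
            rule=RULE_DEPTH_PREFERRED,
            pooled_counts=(winner.rr, winner.vr),
        )

    return ConsensusCall(
        key=evidence.key,
        genotype=assign_genotype(*pooled, thresholds),
        supporting_runs=[r.run_id for r in adequate],
        rule=RULE_POOLED_RECALL,
        pooled_counts=pooled,
    )
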