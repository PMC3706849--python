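"""Unit and property tests for duplicate marking, pileup filtering and SNV calling."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import concordx as cx
from concordx import simulate as sim
from concordx.caller import (
    DEFAULT_THRESHOLDS,
    FLAG_STRAND_BIAS,
    GT_BELOW_HET,
    GT_HET,
    GT_HOM_VAR,
    PileupColumn,
    TIER_CANDIDATE,
    TIER_HIGH_CONFIDENCE,
)
from helpers import mk_read, truth_keys


# ----------------------------------------------------------- duplicate marking

class TestMarkDuplicates:
    def test_identical_reads_one_flagged_either_mode(self):
        reads = [mk_read("chr1", 10, "ACGT" * 5), mk_read("chr1", 10, "ACGT" * 5)]
        for mode in ("start_only", "start_plus_end"):
            marked = cx.mark_duplicates(reads, mode)
            assert sum(r.duplicate_flag for r in marked) == 1

    def test_same_start_different_end_depends_on_mode(self):
        reads = [mk_read("chr1", 10, "A" * 20), mk_read("chr1", 10, "A" * 30)]
        assert sum(r.duplicate_flag for r in cx.mark_duplicates(reads, "start_only")) == 1
        assert sum(r.duplicate_flag for r in cx.mark_duplicates(reads, "start_plus_end")) == 0

    def test_highest_quality_read_kept_then_lexicographic(self):
        lo = mk_read("chr1", 5, "CCCC", qual=20)
        hi = mk_read("chr1", 5, "TTTT", qual=35)
        marked = cx.mark_duplicates([lo, hi], "start_only")
        assert marked[0].duplicate_flag and not marked[1].duplicate_flag
        # equal qualities: lexicographically smallest sequence survives
        a, b = mk_read("chr1", 5, "GGGG"), mk_read("chr1", 5, "AAAA")
        marked = cx.mark_duplicates([a, b], "start_only")
        assert marked[0].duplicate_flag and not marked[1].duplicate_flag

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            cx.mark_duplicates([], "by_name")

    def test_simulated_duplicate_rate_recovered(self):
        # low depth on purpose: coincidental same-start collisions are then rare
        cfg = sim.SimulationConfig(
            chromosomes=[sim.ChromosomeSpec("chr1", 50_000)],
            dup_segment=None,
            sample_sex="female",
            variant_specs=[],
            run_profiles=[],
            seed=3,
        )
        ref, dup = sim.build_reference(cfg)
        sample = sim.plant_variants(ref, [], "female")
        profile = sim.RunProfile("d", "illumina", 2.0, 100, 0.0, duplicate_rate=0.2)
        reads = sim.simulate_run(sample, profile, 99)
        injected = np.array([r.truth_origin.duplicate for r in reads])
        n = len(reads)
        sd = math.sqrt(0.2 * 0.8 / n)
        assert abs(injected.mean() - 0.2) < 3 * sd
        marked = cx.mark_duplicates(reads, "start_plus_end")
        flagged = np.array([r.duplicate_flag for r in marked])
        # every injected exact copy is flagged; coincidental extras stay rare here
        assert flagged[injected].all()
        assert abs(flagged.mean() - 0.2) < 3 * sd + 0.02


# ----------------------------------------------------------- pileup filtering

class TestBuildPileup:
    def setup_method(self):
        self.ref = cx.Reference.from_strings({"chr1": "A" * 60})

    def test_clean_reference_reads_count_only_ref(self):
        reads = [mk_read("chr1", 0, "A" * 30) for _ in range(10)]
        pileup = cx.build_pileup(reads, ("chr1", 10, 11), reference=self.ref)
        col = pileup.column_at(10)
        assert col.count("A") == 10 and col.filtered_depth == 10
        assert col.raw_depth == 10
        assert cx.call_site(col) is None

    def test_low_mapq_read_in_raw_but_not_filtered_depth(self):
        reads = [mk_read("chr1", 0, "A" * 30), mk_read("chr1", 0, "C" * 30, mapq=0)]
        col = cx.build_pileup(reads, ("chr1", 10, 11), reference=self.ref).column_at(10)
        assert col.raw_depth == 2 and col.filtered_depth == 1
        assert col.raw_allele_counts[1] == 1  # the C is visible in raw counts

    def test_duplicate_flagged_read_excluded(self):
        reads = [mk_read("chr1", 0, "A" * 30), mk_read("chr1", 0, "A" * 30, dup=True)]
        col = cx.build_pileup(reads, ("chr1", 10, 11), reference=self.ref).column_at(10)
        assert col.filtered_depth == 1 and col.raw_depth == 2

    def test_base_quality_cutoff(self):
        reads = [mk_read("chr1", 0, "A" * 30, qual=10)]
        col = cx.build_pileup(reads, ("chr1", 10, 11), reference=self.ref).column_at(10)
        assert col.filtered_depth == 0 and col.raw_depth == 1

    def test_end_trim_masks_read_margins(self):
        # a site covered only by the first five bases of every read is empty
        reads = [mk_read("chr1", 8, "A" * 30) for _ in range(4)]
        pileup = cx.build_pileup(reads, ("chr1", 8, 14), reference=self.ref)
        assert all(pileup.column_at(p).filtered_depth == 0 for p in range(8, 13))
        assert pileup.column_at(13).filtered_depth == 4

    def test_region_outside_reference_rejected(self):
        with pytest.raises(ValueError):
            cx.build_pileup([], ("chr1", 0, 100), reference=self.ref)
        with pytest.raises(ValueError):
            cx.build_pileup([], ("chr9", 0, 10), reference=self.ref)


# ----------------------------------------------------------- site calling

def col(rr, vr, ref="A", alt="C", split=True, **kw):
    """Two-allele column; alt split across strands unless split=False."""
    rc = (rr - rr // 2, rr // 2)
    vc = (vr - vr // 2, vr // 2) if split else (vr, 0)
    return PileupColumn.from_counts("chr1", 100, ref, {ref: rc, alt: vc}, **kw)


class TestCallSite:
    def test_depth_below_floor_is_no_call(self):
        assert cx.call_site(col(5, 4)) is None  # depth 9, vf ~0.44

    def test_candidate_but_not_high_confidence(self):
        call = cx.call_site(col(28, 2))
        assert call is not None and call.tier == TIER_CANDIDATE
        assert call.vf == pytest.approx(2 / 30)

    def test_deep_het_is_high_confidence(self):
        call = cx.call_site(col(71, 98))
        assert call.tier == TIER_HIGH_CONFIDENCE
        assert call.genotype == GT_HET
        assert call.printed_ratio == 0.58

    def test_zero_depth_column_is_no_call(self):
        empty = PileupColumn.from_counts("chr1", 100, "A", {})
        assert cx.call_site(empty) is None

    def test_alt_tie_breaks_to_smallest_base(self):
        column = PileupColumn.from_counts(
            "chr1", 100, "A", {"A": (10, 10), "G": (3, 3), "C": (3, 3)}
        )
        call = cx.call_site(column)
        assert call.alt == "C"

    def test_low_mapq_support_flag(self):
        column = col(80, 20, low_mapq={"C": 15})
        call = cx.call_site(column)
        assert "LOW_MAPQ_SUPPORT" in call.flags

    def test_strand_bias_flag_on_one_sided_alt(self):
        call = cx.call_site(col(60, 30, split=False))
        assert FLAG_STRAND_BIAS in call.flags


class TestAssignGenotype:
    @pytest.mark.parametrize(
        "rr,vr,expect",
        [
            (0, 147, GT_HOM_VAR),
            (9, 14, GT_HET),  # vf 0.609
            (13, 2, GT_BELOW_HET),  # vf 0.133: the threshold-miss regime
            (8, 2, GT_HET),  # vf 0.20 sits inside the band
            (2, 8, GT_HET),  # vf 0.80 sits inside the band
            (1, 9, GT_HOM_VAR),
        ],
    )
    def test_band_assignment(self, rr, vr, expect):
        assert cx.assign_genotype(rr, vr) == expect

    def test_zero_reads_is_an_error(self):
        with pytest.raises(ValueError):
            cx.assign_genotype(0, 0)


class TestStrandBias:
    def test_symmetric_support_not_biased(self):
        _, biased = cx.strand_bias(
            PileupColumn.from_counts("chr1", 1, "A", {"A": (50, 50), "C": (20, 20)}), "C"
        )
        assert not biased

    def test_alt_absent_on_one_strand_is_biased(self):
        p, biased = cx.strand_bias(
            PileupColumn.from_counts("chr1", 1, "A", {"A": (50, 50), "C": (40, 0)}), "C"
        )
        assert biased

    def test_matches_hypergeometric_tail_oracle(self):
        # independent oracle: enumerate the conditional (hypergeometric)
        # distribution of the table with fixed margins, sum tables whose
        # probability does not exceed the observed one
        def fisher_two_sided(ref_f, ref_r, alt_f, alt_r):
            n = ref_f + ref_r + alt_f + alt_r
            row1, col1 = ref_f + ref_r, ref_f + alt_f

            def prob(a):
                return (
                    math.comb(row1, a)
                    * math.comb(n - row1, col1 - a)
                    / math.comb(n, col1)
                )

            p_obs = prob(ref_f)
            return sum(
                prob(a)
                for a in range(max(0, col1 - (n - row1)), min(row1, col1) + 1)
                if prob(a) <= p_obs * (1 + 1e-9)
            )

        cases = [(30, 30, 12, 2), (30, 30, 7, 7), (10, 50, 2, 12), (25, 35, 1, 9)]
        for ref_f, ref_r, alt_f, alt_r in cases:
            column = PileupColumn.from_counts(
                "chr1", 1, "A", {"A": (ref_f, ref_r), "C": (alt_f, alt_r)}
            )
            p, biased = cx.strand_bias(column, "C")
            expect = fisher_two_sided(ref_f, ref_r, alt_f, alt_r)
            assert p == pytest.approx(expect, rel=1e-6)
            assert biased == (p < 0.05 or min(alt_f, alt_r) < 1)


# ----------------------------------------------------------- caller properties

def literal_threshold_oracle(rr, vr, thr=DEFAULT_THRESHOLDS):
    """The calling rules transcribed literally, independent of the caller path."""
    tr = rr + vr
    if tr == 0:
        return (False, None, None)
    vf = vr / tr
    if tr < thr.min_coverage or vf < thr.min_maf:
        return (False, None, None)
    tier = (
        TIER_HIGH_CONFIDENCE if tr >= thr.hc_min_coverage and vf >= thr.hc_min_maf else TIER_CANDIDATE
    )
    if thr.het_lower_vf <= vf <= thr.het_upper_vf:
        gt = GT_HET
    elif vf > thr.het_upper_vf:
        gt = GT_HOM_VAR
    else:
        gt = GT_BELOW_HET
    return (True, tier, gt)


def test_caller_agrees_with_bruteforce_oracle_up_to_depth_60():
    for tr in range(0, 61):
        for vr in range(0, tr + 1):
            rr = tr - vr
            expect = literal_threshold_oracle(rr, vr)
            assert cx.classify_counts(rr, vr) == expect
            call = cx.call_site(col(rr, vr)) if tr else None
            if expect[0]:
                assert call is not None
                assert (call.tier, call.genotype) == expect[1:]
                assert call.vf == vr / (rr + vr)  # full precision, no rounding
            else:
                assert call is None


@given(st.integers(0, 200), st.integers(0, 200), st.integers(2, 6))
def test_calling_is_monotone_in_depth_at_fixed_vf(rr, vr, scale):
    called, _, _ = cx.classify_counts(rr, vr)
    if called:
        assert cx.classify_counts(rr * scale, vr * scale)[0]


def test_printed_ratio_uses_round_half_up():
    assert cx.round_half_up(69 / 114, 2) == 0.61  # 0.6053
    assert cx.round_half_up(0.125, 2) == 0.13  # banker's rounding would say 0.12
    assert cx.round_half_up(0.605, 2) == 0.61


# ----------------------------------------------------------- caller on simulation

def test_clean_simulation_recovers_exactly_the_planted_variants(clean_cohort):
    """No errors, no duplicates, no mismapping: the call set equals the truth."""
    truth = clean_cohort.truth
    planted = truth_keys(truth, "functional")
    for reads in clean_cohort.runs.values():
        calls = cx.call_variants(reads, reference=clean_cohort.reference)
        assert {c.key for c in calls} == planted
        by_key = {c.key: c for c in calls}
        for _, row in truth.iterrows():
            call = by_key[(row.chrom, row.pos, row.ref, row.alt)]
            expect_gt = GT_HET if row.zygosity == "het" else GT_HOM_VAR
            assert call.genotype == expect_gt


def test_empty_read_set_yields_no_calls(clean_cohort):
    assert cx.call_variants([], reference=clean_cohort.reference) == []
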