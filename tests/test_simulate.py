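"""Tests of the synthetic-genome generator and the mismapping read model."""

import math

import numpy as np
import pytest
from scipy import stats

import concordx as cx
from concordx import simulate as sim
from conftest import small_config
from helpers import truth_keys


def test_identical_seeds_give_identical_outputs(tmp_path):
    a = sim.simulate_cohort(small_config(seed=5))
    b = sim.simulate_cohort(small_config(seed=5))
    for name in a.reference.names:
        assert np.array_equal(a.reference.codes(name), b.reference.codes(name))
    assert a.truth.equals(b.truth)
    for run_id in a.runs:
        ra, rb = a.runs[run_id], b.runs[run_id]
        assert len(ra) == len(rb)
        assert all(
            (x.chrom, x.start, x.strand, x.mapq, x.sequence) == (y.chrom, y.start, y.strand, y.mapq, y.sequence)
            for x, y in zip(ra, rb)
        )
    # and byte-identical files
    from concordx import ioutils

    for cohort, sub in ((a, "a"), (b, "b")):
        d = tmp_path / sub
        d.mkdir()
        ioutils.write_fasta(cohort.reference, d / "ref.fasta")
        ioutils.write_dup_bed(cohort.duplications, d / "dups.bed")
        ioutils.write_sam(cohort.runs["run_a"], cohort.reference, d / "run_a.sam")
    for fname in ("ref.fasta", "dups.bed", "run_a.sam"):
        assert (tmp_path / "a" / fname).read_bytes() == (tmp_path / "b" / fname).read_bytes()


def test_different_seeds_differ():
    a = sim.simulate_cohort(small_config(seed=5))
    b = sim.simulate_cohort(small_config(seed=6))
    assert not np.array_equal(a.reference.codes("chr1"), b.reference.codes("chr1"))


class TestBuildReference:
    def test_zero_divergence_copies_are_identical(self):
        cfg = small_config()
        cfg.dup_segment = sim.DupSegmentSpec(
            chrom="chrX", start=2_000, end=3_000, copy_count=2, divergence=0.0,
            copy_sites=(("chr1", 5_000), ("chr1", 8_000)),
        )
        ref, dup = sim.build_reference(cfg)
        assert all(iv.identity == 100.0 for iv in dup.copies)
        src = dup.source
        for iv in dup.copies:
            assert cx.segment_identity(ref, (src.chrom, src.start, src.end), (iv.chrom, iv.start, iv.end)) == 100.0

    def test_realized_identity_within_binomial_band(self):
        # divergence 0.05 over 2 kb: identity 95 +/- 3 binomial sd (~1.5 points)
        cfg = sim.default_config(seed=2)
        ref, dup = sim.build_reference(cfg)
        L = cfg.dup_segment.length
        band = 3 * math.sqrt(0.05 * 0.95 / L) * 100
        for iv in dup.copies:
            assert abs(iv.identity - 95.0) < band
            src = dup.source
            recomputed = cx.segment_identity(ref, (src.chrom, src.start, src.end), (iv.chrom, iv.start, iv.end))
            assert recomputed == pytest.approx(iv.identity)

    def test_segment_longer_than_chromosome_rejected(self):
        cfg = small_config()
        cfg.dup_segment = sim.DupSegmentSpec(chrom="chrX", start=0, end=9_000, copy_count=1, copy_sites=(("chr1", 100),))
        with pytest.raises(sim.ConfigurationError):
            sim.build_reference(cfg)

    def test_overlapping_copy_placement_rejected(self):
        cfg = small_config()
        cfg.dup_segment = sim.DupSegmentSpec(
            chrom="chrX", start=2_000, end=3_000, copy_count=2,
            copy_sites=(("chr1", 5_000), ("chr1", 5_500)),
        )
        with pytest.raises(sim.ConfigurationError):
            sim.build_reference(cfg)

    def test_auto_placement_avoids_source_and_fits(self):
        cfg = small_config()
        cfg.dup_segment = sim.DupSegmentSpec(chrom="chrX", start=2_000, end=3_000, copy_count=3)
        ref, dup = sim.build_reference(cfg)
        placed = [(iv.chrom, iv.start, iv.end) for iv in dup.intervals]
        for i, (ca, sa, ea) in enumerate(placed):
            assert ea <= ref.lengths[ca]
            for cb, sb, eb in placed[i + 1:]:
                assert ca != cb or sa >= eb or ea <= sb


class TestPlantVariants:
    def test_hom_alters_both_haplotypes_het_one(self, small_cohort):
        sample = small_cohort.sample
        truth = small_cohort.truth
        for _, row in truth[truth.locus_class == "functional"].iterrows():
            haps = sample.haplotypes[row.chrom]
            carriers = sum(cx.reads.BASES[h[row.pos - 1]] == row.alt for h in haps)
            if row.zygosity == "het":
                assert carriers == 1 and len(haps) == 2
            elif row.zygosity == "hom":
                assert carriers == 2
            else:  # hemizygous male X
                assert carriers == 1 and len(haps) == 1

    def test_paralog_only_leaves_source_segment_unchanged(self, small_cohort):
        sample, ref = small_cohort.sample, small_cohort.reference
        src = small_cohort.duplications.source
        for hap in sample.haplotypes[src.chrom]:
            assert np.array_equal(hap[src.start:src.end], ref.codes(src.chrom)[src.start:src.end])

    def test_het_spec_on_male_x_rejected(self):
        cfg = small_config()
        ref, dup = sim.build_reference(cfg)
        with pytest.raises(sim.VariantSpecError):
            sim.plant_variants(ref, [sim.PlantedVariant("het", "chrX", 6_001)], "male", dup)

    def test_hemizygous_spec_on_autosome_rejected(self):
        cfg = small_config()
        ref, dup = sim.build_reference(cfg)
        with pytest.raises(sim.VariantSpecError):
            sim.plant_variants(ref, [sim.PlantedVariant("hemizygous", "chr1", 1_001)], "male", dup)

    def test_mismatching_ref_base_rejected(self):
        cfg = small_config()
        ref, dup = sim.build_reference(cfg)
        actual = ref.base("chr1", 1_000)
        wrong = "A" if actual != "A" else "C"
        with pytest.raises(sim.VariantSpecError):
            sim.plant_variants(ref, [sim.PlantedVariant("het", "chr1", 1_001, ref=wrong)], "male", dup)

    def test_paralog_only_outside_copies_rejected(self):
        cfg = small_config()
        ref, dup = sim.build_reference(cfg)
        with pytest.raises(sim.VariantSpecError):
            sim.plant_variants(
                ref, [sim.PlantedVariant("hom", "chr1", 1_001, locus_class="paralog_only")], "male", dup
            )


class TestSimulateRun:
    def test_no_mismapping_means_reported_equals_true_origin(self, clean_cohort):
        for reads in clean_cohort.runs.values():
            assert all(r.chrom == r.truth_origin.chrom and r.start == r.truth_origin.start for r in reads)

    def test_mismapped_reads_carry_low_mapq_and_source_coordinates(self, small_cohort):
        dup = small_cohort.duplications
        src = dup.source
        mismapped = [r for r in small_cohort.runs["run_a"] if r.truth_origin.mismapped]
        assert mismapped, "expected some mismapped reads under mismap_rate=0.2"
        for r in mismapped:
            assert r.mapq == 0
            assert r.chrom == src.chrom
            assert src.start <= r.start and r.end <= src.end
            iv = dup.overlapping(r.truth_origin.chrom, r.truth_origin.start)
            assert iv is not None and not iv.is_source

    def test_hemizygous_site_appears_fully_variant(self, small_cohort):
        truth = small_cohort.truth
        row = truth[truth.zygosity == "hemizygous"].iloc[0]
        index = cx.ReadIndex(small_cohort.runs["run_a"])
        bases = [r.base_at(row.pos - 1) for r in index.at(row.chrom, row.pos - 1)]
        vf = bases.count(row.alt) / len(bases)
        assert vf > 0.95  # errors aside, every correctly mapped read carries the allele

    def test_psv_apparent_vf_matches_closed_form(self, small_cohort):
        """At a planted PSV's source locus, vf ~= m / (p/2 + k*m) within binomial error."""
        truth = small_cohort.truth
        dup = small_cohort.duplications
        m = small_cohort.config.run_profiles[0].mismap_rate
        expect = sim.expected_artifact_vf(m, len(dup.copies), small_cohort.sample.ploidy(dup.source.chrom))
        index = cx.ReadIndex(small_cohort.runs["run_a"])
        for _, row in truth[truth.locus_class == "paralog_only"].iterrows():
            reads = index.at(row.source_chrom, int(row.source_pos) - 1)
            bases = [r.base_at(int(row.source_pos) - 1) for r in reads]
            n = len(bases)
            vf = bases.count(row.alt) / n
            assert abs(vf - expect) < 3 * math.sqrt(expect * (1 - expect) / n) + 0.02

    def test_zero_depth_yields_empty_set(self, small_cohort):
        profile = sim.RunProfile("tiny", "x", mean_depth=1e-9, read_length=100)
        assert sim.simulate_run(small_cohort.sample, profile, 1) == []

    def test_het_allele_sampling_is_unbiased(self):
        # >= 1000 het sites: the summed variant-read count passes a two-sided
        # binomial test against p=0.5 at alpha=0.001
        counts = sim.het_read_counts(1_000, 30, seed=17)
        total = int(counts.sum())
        p = stats.binomtest(total, 1_000 * 30, 0.5).pvalue
        assert p > 0.001

    def test_expected_artifact_vf_closed_form_values(self):
        # hemizygous source, 4 copies, m=0.2 -> 0.2/(0.5+0.8)
        assert sim.expected_artifact_vf(0.2, 4, 1) == pytest.approx(0.2 / 1.3)
        assert sim.expected_artifact_vf(0.0, 4, 2) == 0.0


def test_truth_table_is_lossless_roundtrip(small_cohort, tmp_path):
    from concordx import ioutils

    path = tmp_path / "truth.tsv"
    ioutils.write_truth(small_cohort.truth, path)
    back = ioutils.read_truth(path)
    assert len(back) == len(small_cohort.truth)
    assert truth_keys(back, "functional") == truth_keys(small_cohort.truth, "functional")
    assert truth_keys(back, "paralog_only") == truth_keys(small_cohort.truth, "paralog_only")


def test_rate_validation():
    with pytest.raises(sim.ConfigurationError):
        sim.RunProfile("r", "p", mean_depth=10, error_rate=1.5)
    with pytest.raises(sim.ConfigurationError):
        sim.RunProfile("r", "p", mean_depth=0)
    with pytest.raises(sim.ConfigurationError):
        sim.DupSegmentSpec(chrom="c", start=10, end=5)
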