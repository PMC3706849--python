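import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from concordx import simulate as sim  # noqa: E402


def small_config(seed: int = 7) -> sim.SimulationConfig:
    """A compact male genome: one autosome, one X, a 1 kb segment duplicated twice."""
    chroms = [
        sim.ChromosomeSpec("chr1", 12_000),
        sim.ChromosomeSpec("chrX", 8_000, is_x=True),
    ]
    dup = sim.DupSegmentSpec(
        chrom="chrX", start=2_000, end=3_000, copy_count=2, divergence=0.05,
        copy_sites=(("chr1", 5_000), ("chr1", 8_000)),
    )
    variants = [
        sim.PlantedVariant("het", "chr1", 1_001),
        sim.PlantedVariant("hom", "chr1", 1_501),
        sim.PlantedVariant("het", "chr1", 10_001),
        sim.PlantedVariant("hemizygous", "chrX", 6_001),
        sim.PlantedVariant("hom", locus_class="paralog_only", copy_index=0, segment_offset=400),
        sim.PlantedVariant("hom", locus_class="paralog_only", copy_index=1, segment_offset=700),
    ]
    profiles = [
        sim.RunProfile("run_a", "illumina", 60, 100, 0.001, 0.05),
        sim.RunProfile("run_b", "illumina", 55, 100, 0.001, 0.05),
        sim.RunProfile("run_c", "ion", 40, 100, 0.01, 0.20),
    ]
    return sim.SimulationConfig(chroms, dup, "male", variants, profiles, seed=seed)


@pytest.fixture(scope="session")
def small_cohort() -> sim.CohortSim:
    return sim.simulate_cohort(small_config())


@pytest.fixture(scope="session")
def clean_cohort() -> sim.CohortSim:
    """Error-free, duplicate-free, mismap-free runs over functional variants only."""
    cfg = small_config(seed=11)
    cfg.variant_specs = [v for v in cfg.variant_specs if v.locus_class == "functional"]
    cfg.run_profiles = [
        sim.RunProfile("clean_a", "illumina", 40, 100, 0.0, 0.0, mismap_rate=0.0),
        sim.RunProfile("clean_b", "illumina", 45, 100, 0.0, 0.0, mismap_rate=0.0),
    ]
    return sim.simulate_cohort(cfg)
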