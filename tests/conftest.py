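import pytest
from hypothesis import settings

from nbsca import synthetic_data

settings.register_profile("deterministic", derandomize=True, max_examples=100)
settings.load_profile("deterministic")
from nbsca.core_io import ArmMap, ChromosomeArms, SegmentRecord


@pytest.fixture(scope="session")
def arm_map():
    """Bundled hg19 arm definitions (chr1, chr2, chr11, chr17, chr19)."""
    return synthetic_data.default_arm_map()


@pytest.fixture()
def toy_arm_map():
    """A 100-Mb toy chromosome with p = [0, 40 Mb), q = [42 Mb, 100 Mb)."""
    arms = ChromosomeArms(
        chromosome="chrT", p_start=0, p_end=40_000_000,
        q_start=42_000_000, q_end=100_000_000, length=100_000_000,
    )
    return ArmMap(chromosomes={"chrT": arms})


def make_segment(sample="S1", chrom="chr19", start=0, end=5_000_000, log2=-0.6):
    return SegmentRecord(sample, chrom, start, end, log2)


@pytest.fixture(scope="session")
def discovery_cohort():
    """One deterministic discovery-style synthetic cohort."""
    params = synthetic_data.SimulationParams.discovery_like(seed=11)
    return params, synthetic_data.generate_cohort(params)
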