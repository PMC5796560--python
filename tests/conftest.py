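import dataclasses

import pytest

from tescan.clustering import Cluster
from tescan.core import PipelineParams, default_profiles
from tescan.simulate import SimConfig, run_simulation


@pytest.fixture(scope="session")
def profiles():
    return default_profiles()


@pytest.fixture()
def params():
    return PipelineParams()


@pytest.fixture(scope="session")
def sim_default(profiles):
    """One default-condition simulated experiment, shared across tests:
    100 kb genome, 10 reference + 10 non-reference insertions per
    subfamily, 10 fragments per locus, error rate 0, 30% background."""
    config = SimConfig(seed=12345)
    reference, donor, truth, pairs = run_simulation(profiles, config)
    return config, reference, donor, truth, pairs


def make_cluster(
    chrom="chr1",
    start=1000,
    end=1200,
    subfamily="L1HS",
    sample="s1",
    hq=2,
    total=2,
    read2_mapped=0,
    polya=0,
    member_ids=(),
):
    return Cluster(
        sample_id=sample,
        subfamily_name=subfamily,
        chrom=chrom,
        start=start,
        end=end,
        read1_count_hq=hq,
        read1_total=total,
        read2_mapped_count=read2_mapped,
        polya_count=polya,
        member_ids=list(member_ids),
    )


@pytest.fixture()
def cluster_factory():
    return make_cluster
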