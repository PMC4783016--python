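import hypothesis
import pytest

from otunet import MockCommunitySpec, RunConfig, cluster_dataset, generate_mock_community

hypothesis.settings.register_profile(
    "suite", derandomize=True, max_examples=30, deadline=None
)
hypothesis.settings.load_profile("suite")


@pytest.fixture(scope="session")
def frozen_community():
    """Seed-frozen mock community used by several structural tests."""
    spec = MockCommunitySpec(
        n_strains=6,
        reads_per_strain=25,
        center_length=300,
        rng_seed=20160308,
    )
    return generate_mock_community(spec)


@pytest.fixture(scope="session")
def frozen_run(frozen_community):
    """The frozen community clustered at the species-like 3% threshold."""
    config = RunConfig(sample_size=50, workers=1, rng_seed=11)
    return cluster_dataset(frozen_community.records, config)
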