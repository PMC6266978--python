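import dataclasses

import pytest

from atrasig import SyntheticConfig, generate_cohort, run_discovery


@pytest.fixture(scope="session")
def default_cohort():
    """Full-size cohort at the default study conditions."""
    return generate_cohort(SyntheticConfig(seed=11))


@pytest.fixture(scope="session")
def default_discovery(default_cohort):
    """End-to-end discovery run on the default cohort."""
    return run_discovery(default_cohort)


@pytest.fixture(scope="session")
def small_config():
    """Compact configuration for fast structural tests."""
    return dataclasses.replace(
        SyntheticConfig(),
        n_probes=400,
        n_genes=60,
        n_queries=20,
        n_planted_dmp=30,
        n_planted_de=15,
        n_coupled=5,
        genome_length=1_500_000,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)
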