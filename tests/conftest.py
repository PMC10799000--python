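import dataclasses

import pytest

from dryq10 import GeneratorConfig, RunConfig, generate_cohort
from dryq10.pipeline import build_factors, q10_table, q10_wide


@pytest.fixture(scope="session")
def run_config():
    return RunConfig(seed=0, generator=GeneratorConfig(seed=0)).validate()


@pytest.fixture(scope="session")
def cohort(run_config):
    """Default noisy synthetic cohort (the study conditions)."""
    return generate_cohort(run_config.generator)


@pytest.fixture(scope="session")
def noiseless_cohort(run_config):
    return generate_cohort(run_config.generator.noiseless())


@pytest.fixture(scope="session")
def fits(cohort, run_config):
    return q10_table(cohort, run_config)


@pytest.fixture(scope="session")
def wide(fits, cohort):
    return q10_wide(fits, cohort.sites)


@pytest.fixture(scope="session")
def factors(wide, cohort):
    return build_factors(wide, cohort.samples)
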