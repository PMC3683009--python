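import logging

import pytest

from rdexome import CascadeConfig, GeneratorParams, generate_cohort, run_cascade

logging.getLogger("rdexome").setLevel(logging.WARNING)


@pytest.fixture(scope="session")
def cohort():
    """Default 12-family synthetic cohort, generated once per session."""
    return generate_cohort(GeneratorParams(seed=7))


@pytest.fixture(scope="session")
def cascade_config(cohort):
    return CascadeConfig(
        panel=cohort.panel,
        frequency_catalog=cohort.frequency_catalog,
        mutation_catalog=cohort.mutation_catalog,
    )


@pytest.fixture(scope="session")
def cohort_results(cohort, cascade_config):
    """Per-patient (trace, candidates) over the default cohort."""
    return {
        pid: run_cascade(exome, exome.sex, cascade_config)
        for pid, exome in cohort.exomes.items()
    }
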