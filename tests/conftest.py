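import pytest

from evescreen.io import RunConfig
from evescreen.pipeline import run_screen
from evescreen.simulate import generate_cohort, generate_viral_genome


@pytest.fixture(scope="session")
def viral_genome():
    """Small annotated circular viral genome with one tandem array and
    one inverted-repeat pair."""
    return generate_viral_genome(
        n_orfs=10, seed=3,
        dr_spec=[{"unit_length": 12, "copies": 10}],
        ir_spec=[{"arm_length": 150, "identity": 0.98, "gap": 2}],
    )


@pytest.fixture(scope="session")
def cohort_truth():
    """The default 50-element ground-truthed screening cohort."""
    return generate_cohort(seed=1)


@pytest.fixture(scope="session")
def cohort_screen(cohort_truth):
    """Full pipeline run (scan -> filter -> merge -> evidence -> score)
    on the default cohort."""
    truth = cohort_truth
    return run_screen(
        truth.scaffolds, truth.viral_proteins, truth.annotations,
        truth.depth_table, truth.config,
        species_of_scaffold=truth.species_of_scaffold,
    )


@pytest.fixture()
def config():
    return RunConfig()
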