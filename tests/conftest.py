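import numpy as np
import pandas as pd
import pytest

from cogtraj.cohort import CohortConfig, generate_cohort
from cogtraj.pipeline import PipelineConfig, run_pipeline


@pytest.fixture(scope="session")
def small_config():
    """A reduced cohort (82 participants, 30 scores) for cheap unit tests."""
    return CohortConfig(
        n_participants=82,
        wave_sizes=(30, 60, 20),
        wave_overlaps=(15, 10, 3),
        n_cognitive_scores=30,
        loading_matrix_rank=5,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def default_cohort():
    """The default three-wave cohort: 582 participants, 77 scores."""
    return generate_cohort(CohortConfig(seed=0))


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One full default-cohort pipeline run (all stages), shared across tests."""
    outdir = tmp_path_factory.mktemp("pipeline") / "run"
    return run_pipeline(PipelineConfig(seed=0, outdir=str(outdir))), outdir


def make_long(records):
    """Helper: long feature table from (pid, visit, age, variable, value) tuples."""
    return pd.DataFrame(
        records, columns=["participant_id", "visit_index", "age", "variable", "value"]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
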