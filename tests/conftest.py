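import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # expose oracles.py

from cernax import (CohortSpec, ExpressionMatrix, PipelineConfig,
                    SimulationConfig, default_truth, generate_cohort,
                    run_pipeline, simulate_bundle)


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def small_matrix(rng):
    """20-feature, 10-sample log2 microarray-like matrix, no planted effect."""
    values = pd.DataFrame(
        rng.normal(7.0, 1.0, size=(20, 10)),
        index=[f"G{i:02d}" for i in range(20)],
        columns=[f"S{i:02d}" for i in range(10)],
    )
    return ExpressionMatrix(values, scale="log2", platform="microarray")


@pytest.fixture
def groups10():
    labels = ["tumor"] * 5 + ["normal"] * 5
    return pd.Series(labels, index=[f"S{i:02d}" for i in range(10)])


@pytest.fixture
def truth():
    return default_truth()


@pytest.fixture
def clean_cohort(truth):
    """Moderate-noise microarray cohort with the planted effects."""
    spec = CohortSpec(n_tumor=8, n_normal=8, n_features=120,
                      platform="microarray", noise_sd=0.4, seed=11)
    return generate_cohort(spec, truth)


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One full synthetic-bundle pipeline run shared across tests."""
    outdir = tmp_path_factory.mktemp("pipeline") / "run"
    config = PipelineConfig(outdir=str(outdir), seed=7,
                            simulation=SimulationConfig.clean_fixture())
    wired, truth = simulate_bundle(config)
    result = run_pipeline(wired)
    return wired, truth, result
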