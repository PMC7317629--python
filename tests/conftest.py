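import numpy as np
import pandas as pd
import pytest

from mlmfi import (
    ConditionCatalog,
    DeficitMatrix,
    PipelineConfig,
    RFSettings,
    SimulationConfig,
    ascertain_deficits,
    generate_cohort,
    make_catalog,
    run_pipeline,
)


def demo_config(output_dir: str) -> PipelineConfig:
    """The n=2000 demonstration pipeline configuration."""
    return PipelineConfig(
        output_dir=output_dir,
        seed=42,
        simulation=SimulationConfig(n_subjects=2000, seed=42),
        rf=RFSettings(n_trees=150, seed=42),
        k_stride=3,
    )

BASELINE_WINDOW = (pd.Timestamp("2005-01-01"), pd.Timestamp("2005-12-31"))


def toy_matrix(values: np.ndarray, prefix: str = "C") -> DeficitMatrix:
    """Wrap a binary array in a DeficitMatrix with synthetic labels."""
    values = np.asarray(values)
    return DeficitMatrix(
        subject_ids=[f"s{i:04d}" for i in range(values.shape[0])],
        condition_ids=[f"{prefix}{j:03d}" for j in range(values.shape[1])],
        values=values,
        window=BASELINE_WINDOW,
    )


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """One full pipeline run on the 2000-subject demo cohort."""
    out = tmp_path_factory.mktemp("demo")
    report = run_pipeline(demo_config(str(out)))
    return report


@pytest.fixture(scope="session")
def small_cohort():
    """300-subject synthetic cohort shared by read-only tests."""
    config = SimulationConfig(n_subjects=300, seed=7)
    subjects, claims, truth = generate_cohort(config)
    return config, subjects, claims, truth


@pytest.fixture(scope="session")
def small_deficits(small_cohort):
    config, subjects, claims, _ = small_cohort
    catalog = ConditionCatalog.from_frame(make_catalog(config.n_conditions))
    matrix = ascertain_deficits(
        claims, catalog, BASELINE_WINDOW, subject_ids=subjects["subject_id"].tolist()
    )
    return catalog, matrix
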