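import numpy as np
import pandas as pd
import pytest

from papmeth import pipeline, simulate


@pytest.fixture(scope="session")
def small_params():
    """A small but fully featured synthetic study (fast to generate)."""
    return simulate.SimParams(n_genes=60, n_markers=6, read_depth=20_000, seed=11)


@pytest.fixture(scope="session")
def small_study(small_params):
    """Tissue + array + pooled datasets sharing one truth."""
    tissue = simulate.generate_tissue_readset(small_params)
    arr = simulate.generate_array_dataset(small_params)
    pooled = simulate.generate_pooled_array(small_params)
    return tissue, arr, pooled


@pytest.fixture(scope="session")
def default_config():
    return pipeline.PipelineConfig()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def discover_fn():
    """Callable running the full discovery pipeline on in-memory datasets."""
    return run_discovery_on


def run_discovery_on(config, tissue, arr, pooled):
    return pipeline.run_discovery(
        config,
        tissue.reads,
        tissue.annotation,
        tissue.labels.to_numpy(),
        arr.manifest,
        arr.betas,
        arr.detection_p,
        arr.labels.to_numpy(),
        pooled.manifest,
        pooled.betas,
        pooled.pool_labels.to_numpy(),
    )


@pytest.fixture(scope="session")
def qmsp_train_test():
    """Calibrated train (31+31) and test (21+21) qMSP cohorts, one seed."""
    params = simulate.SimParams(seed=3)
    panel = ["AMPD3", "NRN1", "TBX15"]
    train = simulate.generate_qmsp_cohort(
        params, panel, target_medians=simulate.TRAINING_TARGET_MEDIANS,
        prefix="TR", stage=5,
    )
    test = simulate.generate_qmsp_cohort(
        params, panel, n_case=params.test_n_per_group,
        n_control=params.test_n_per_group,
        target_medians=simulate.TESTING_TARGET_MEDIANS, prefix="TE", stage=6,
    )
    return train, test
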