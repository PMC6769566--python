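import warnings

import numpy as np
import pytest

warnings.filterwarnings("ignore", category=FutureWarning)

from msicyto import (
    PipelineConfig,
    SyntheticConfig,
    run_training,
    simulate_cohort,
)


def small_synthetic_config(**overrides) -> SyntheticConfig:
    """Desk-scale cohort settings shared by the cheaper end-to-end tests."""
    kwargs = dict(
        n_benign_patients=3,
        n_malignant_patients=3,
        rois_per_patient_range=(4, 6),
        pixels_per_roi_range=(3, 10),
        seed=11,
    )
    kwargs.update(overrides)
    return SyntheticConfig(**kwargs)


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(small_synthetic_config())


@pytest.fixture(scope="session")
def small_training(small_cohort):
    """A trained model on the small cohort, shared read-only across tests."""
    datasets, rois, truth = small_cohort
    config = PipelineConfig(seed=11, synthetic=small_synthetic_config())
    result = run_training(config, datasets, rois, truth.specimen_class)
    return config, result, truth


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
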