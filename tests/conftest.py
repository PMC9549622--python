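import numpy as np
import pandas as pd
import pytest

from metabocv import (
    SpectralDataset,
    SyntheticConfig,
    constant_sum_normalize,
    generate_cohort,
    generate_null_cohort,
)


@pytest.fixture(scope="session")
def small_cohort():
    """Effect-bearing cohort small enough for fast ensemble tests."""
    cfg = SyntheticConfig(
        n_per_group=8, n_bins=40, marker_bins=(3, 11, 19, 27, 35),
        effect_by_timepoint={12: 0.30, 28: 0.15, 60: 0.05},
        noise_cv=0.1, seed=42,
    )
    dataset, covariates = generate_cohort(cfg)
    return cfg, dataset, covariates


@pytest.fixture(scope="session")
def small_null_cohort():
    cfg = SyntheticConfig(n_per_group=8, n_bins=40, noise_cv=0.1, seed=43)
    return cfg, generate_null_cohort(cfg)


@pytest.fixture()
def normalized(small_cohort):
    _, dataset, _ = small_cohort
    return dataset.with_intensities(constant_sum_normalize(dataset.intensities))


@pytest.fixture()
def normalized_null(small_null_cohort):
    _, dataset = small_null_cohort
    return dataset.with_intensities(constant_sum_normalize(dataset.intensities))


@pytest.fixture()
def toy_dataset():
    """Hand-built 6-sample dataset with valid metadata."""
    rng = np.random.default_rng(0)
    ids = [f"s{i}" for i in range(6)]
    X = pd.DataFrame(
        rng.uniform(1, 10, size=(6, 4)),
        index=pd.Index(ids, name="sample_id"),
        columns=["b0", "b1", "b2", "b3"],
    )
    meta = pd.DataFrame(
        {
            "group": ["DTH", "DTH", "DTH", "control", "control", "control"],
            "timepoint": [12] * 6,
            "fluid": ["serum"] * 6,
        },
        index=X.index,
    )
    return SpectralDataset(X, meta)
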