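import numpy as np
import pandas as pd
import pytest

from bsgdiag import (
    CohortConfig,
    MarkerPanel,
    generate_tissue_cohort,
    train_methylation_classifier,
)


@pytest.fixture(scope="session")
def default_config() -> CohortConfig:
    return CohortConfig(seed=7)


@pytest.fixture(scope="session")
def cohort(default_config):
    """Default 45-per-subtype tissue cohort, shared across tests."""
    return generate_tissue_cohort(default_config)


@pytest.fixture(scope="session")
def small_cohort():
    """Quick 12-per-subtype cohort for cheap checks."""
    return generate_tissue_cohort(CohortConfig(n_per_subtype=(12, 12, 12), seed=3))


@pytest.fixture(scope="session")
def trained_model(cohort):
    """Forest trained on the default cohort's planted panel (single grid
    point keeps the suite fast; grid search is covered separately)."""
    panel = cohort.truth_panel
    return train_methylation_classifier(
        cohort.tissue_betas[panel.cpg_ids],
        cohort.subtype_labels,
        seed=0,
        grid=[{"max_features": "sqrt", "min_samples_leaf": 1}],
    )


@pytest.fixture
def tiny_panel() -> MarkerPanel:
    return MarkerPanel.from_sites(["h3_a", "h3_b"], ["idh_a", "idh_b"])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_beta_matrix(rng, n_samples, cpgs, mean=0.5, sd=0.1):
    vals = np.clip(rng.normal(mean, sd, size=(n_samples, len(cpgs))), 0, 1)
    return pd.DataFrame(vals, index=[f"S{i:03d}" for i in range(n_samples)], columns=cpgs)
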