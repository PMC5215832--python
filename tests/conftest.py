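import numpy as np
import pandas as pd
import pytest

from multilca import (
    IndicatorDataset,
    LCAParams,
    compress_patterns,
    default_config,
    simulate_population,
)


@pytest.fixture(scope="session")
def two_class_params():
    """Well-separated two-class, two-item toy parameters."""
    return LCAParams(
        class_proportions=np.array([0.6, 0.4]),
        item_probs=np.array([[0.9, 0.2], [0.1, 0.7]]),
    )


@pytest.fixture(scope="session")
def reference_config():
    """Seven-class default generator configuration (no covariates/outcomes)."""
    return default_config(include_covariates=False, include_outcomes=False)


@pytest.fixture(scope="session")
def reference_population(reference_config):
    """Mid-sized population from the seven-class reference model."""
    ds, labels = simulate_population(reference_config, n=20_000, seed=42)
    return ds, labels


@pytest.fixture()
def small_dataset():
    rng = np.random.default_rng(7)
    ind = rng.integers(0, 2, size=(40, 2)).astype(float)
    return IndicatorDataset(ind, weights=rng.uniform(0.5, 2.0, size=40))


def person_level_loglik(params: LCAParams, ds: IndicatorDataset) -> float:
    """Independent oracle: per-person mixture log-likelihood by direct
    enumeration over classes, no pattern compression, plain loops."""
    total = 0.0
    for i in range(ds.n_persons):
        y = ds.indicators[i]
        p = 0.0
        for k in range(params.n_classes):
            term = params.class_proportions[k]
            for j in range(params.n_items):
                rho = min(max(params.item_probs[k, j], 1e-6), 1 - 1e-6)
                term *= rho if y[j] == 1 else (1.0 - rho)
            p += term
        total += ds.weights[i] * np.log(p)
    return total
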