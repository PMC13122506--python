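import numpy as np
import pandas as pd
import pytest

import wormdeconv as wd


@pytest.fixture(scope="session")
def small_config():
    return wd.SimulationConfig(
        n_cell_types=3, n_features=300, markers_per_type=20,
        marker_fold_change=5.0, n_days=6, replicates_per_day=4,
        noise_cv=0.05, seed=7,
    )


@pytest.fixture(scope="session")
def small_reference(small_config):
    return wd.simulate_reference(small_config)


@pytest.fixture(scope="session")
def small_cohort(small_config, small_reference):
    profiles, _ = small_reference
    return wd.simulate_aging_cohort(small_config, profiles)


@pytest.fixture(scope="session")
def five_type_config():
    return wd.SimulationConfig(
        n_cell_types=5, n_features=500, markers_per_type=20,
        n_days=8, replicates_per_day=3, noise_cv=0.0, seed=3,
    )


@pytest.fixture(scope="session")
def five_type_signature(five_type_config):
    profiles, markers = wd.simulate_reference(five_type_config)
    kept, _ = wd.prepare_markers(
        markers, profiles.index, wd.SignatureConfig.rna()
    )
    return profiles, markers, wd.build_signature(profiles, kept)


@pytest.fixture
def toy_proportions():
    values = pd.DataFrame(
        {
            "a": [0.5, 0.48, 0.30, 0.28, 0.1],
            "b": [0.3, 0.32, 0.40, 0.42, 0.2],
            "c": [0.2, 0.20, 0.30, 0.30, 0.7],
        },
        index=[f"s{i}" for i in range(5)],
    )
    day = pd.Series([1, 1, 2, 2, 3], index=values.index)
    return wd.ProportionMatrix(values=values, day=day)


def mixture_from(signature, weights, name="mix"):
    """Noise-free bulk vector from signature columns and a weight vector."""
    w = np.asarray(weights, dtype=float)
    return pd.Series(
        signature.values.to_numpy() @ w, index=signature.values.index,
        name=name,
    )
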