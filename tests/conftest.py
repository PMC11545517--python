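import numpy as np
import pandas as pd
import pytest

from gclayers import LayerSpec, generate_cohort
from gclayers.matrix import ExpressionMatrix


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    """4 genes × 5 samples with two missing entries."""
    df = pd.DataFrame(
        {
            "S1": [8.0, 1.0, 4.0, np.nan],
            "S2": [2.0, 3.0, 4.0, 5.0],
            "S3": [1.0, np.nan, 4.0, 6.0],
            "S4": [0.5, 2.0, 4.0, 7.0],
            "S5": [4.0, 6.0, 4.0, 8.0],
        },
        index=["GA", "GB", "GC", "GD"],
    )
    return ExpressionMatrix(df)


@pytest.fixture(scope="session")
def planted_cohort():
    """60 samples, one 20-gene layer (δ=5, sd=0.5) + 30 background genes."""
    return generate_cohort(
        n_samples=60,
        layer_specs=[LayerSpec(20, 2, effect_size=5.0)],
        n_background_genes=30,
        noise_sd=0.5,
        seed=11,
        subtype_layers=(),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
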