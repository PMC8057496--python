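import numpy as np
import pandas as pd
import pytest

from checkmine import (
    ClinicalTable,
    CohortSpec,
    ExpressionMatrix,
    Platform,
    derive_rng,
    simulate_bulk_cohort,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def toy_matrix():
    """3 genes x 4 samples with one exact linear dependency."""
    x = np.array([1.0, 2.0, 3.0, 4.0])
    values = pd.DataFrame(
        [x, 2 * x + 1, [5.0, 1.0, 4.0, 2.0]],
        index=["G1", "G2", "G3"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return ExpressionMatrix(values=values, platform=Platform.rnaseq)


@pytest.fixture
def small_cohort():
    """Planted cohort small enough for exhaustive checking."""
    spec = CohortSpec(n_genes=120, n_samples=150)
    return spec, *simulate_bulk_cohort(spec, derive_rng(7, "bulk"))


@pytest.fixture
def clinical_frame():
    return pd.DataFrame({
        "sample_id": [f"P{i}" for i in range(8)],
        "dfs_months": [0.0, 3.5, 12.0, 0.0, 7.2, 30.0, 18.0, 2.2],
        "dfs_event": [1, 1, 0, 0, 1, 0, 1, 1],
        "age": [60.0, np.nan, 55.0, 70.0, 65.0, np.nan, 50.0, 62.0],
        "stage": ["II", "III", np.nan, "II", "III", "II", "III", "II"],
    })
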