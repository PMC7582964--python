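import numpy as np
import pandas as pd
import pytest

from metamodule import ExpressionMatrix, PhenotypeTable, SyntheticCohortSpec, \
    simulate_cohort


@pytest.fixture
def tight_cohort():
    """Small cohort with two tight planted modules and some noise genes:
    the regime where module recovery should be essentially exact."""
    spec = SyntheticCohortSpec(
        n_samples=150, module_sizes=(60, 40), n_noise_genes=50,
        loading_range=(1.0, 1.0), sigma=0.4, seed=11)
    return simulate_cohort(spec)


@pytest.fixture
def toy_expression():
    data = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0],
         [2.0, 4.0, 6.0, 8.0],
         [5.0, 1.0, 4.0, 2.0]],
        index=["g1", "g2", "g3"],
        columns=["s1", "s2", "s3", "s4"])
    return ExpressionMatrix(data)


@pytest.fixture
def toy_phenotype():
    return PhenotypeTable(pd.DataFrame({
        "sample_id": ["s1", "s2", "s3", "s4"],
        "recurrence": [0, 1, 0, 1],
        "who_grade": [1, 2, 1, 3],
        "simpson_grade": [1, 2, np.nan, 4],
        "time_to_recurrence": [np.nan, 2.0, np.nan, 4.0],
        "follow_up": [5.0, 2.0, 6.0, 4.0],
        "batch": ["a", "a", "a", "a"],
    }))
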