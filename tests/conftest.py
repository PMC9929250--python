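import numpy as np
import pandas as pd
import pytest

from multiprot.normalize import prepare_layer
from multiprot.synthetic import CohortParams, generate_cohort

# a reduced cohort: same structure as the defaults, sized for fast unit tests
SMALL_PARAMS = CohortParams(
    n_patients=(("DGC", 12), ("IGC", 14)),
    n_proteins=400,
    n_phospho=500,
    n_tf=40,
    n_subtypes=(("DGC", 2), ("IGC", 2)),
    signature_per_subtype=20,
    tf_signature_per_subtype=5,
    targets_per_tf=8,
    n_kinases=8,
    substrates_per_kinase=10,
    n_active_kinases=2,
    n_negative_kinases=1,
    panel_size=6,
    trans_targets_per_gene=5,
    markers_per_cell_type=12,
)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(SMALL_PARAMS, seed=7)


@pytest.fixture(scope="session")
def small_prepared(small_cohort):
    return {
        name: prepare_layer(matrix) for name, matrix in small_cohort.layers.items()
    }


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def toy_matrix():
    """4x3 raw matrix with one missing cell, as a plain DataFrame factory."""
    from multiprot.datamodel import AbundanceMatrix

    data = pd.DataFrame(
        {
            "S1": [1.0, 2.0, 4.0, 8.0],
            "S2": [2.0, 4.0, np.nan, 16.0],
            "S3": [1.0, 1.0, 2.0, 4.0],
        },
        index=["F1", "F2", "F3", "F4"],
    )
    return AbundanceMatrix(data, scale="raw", layer="proteome")
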