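import numpy as np
import pandas as pd
import pytest

from mcc import SimConfig, make_feature_frame, make_layer, simulate_cohort


def small_config(**overrides) -> SimConfig:
    """A desk-scale cohort configuration for fast unit tests."""
    base = dict(
        n_pairs=4,
        cells_per_sample_mean=90,
        n_genes=80,
        n_peaks=120,
        n_variants=6,
        seed=0,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def tiny_cohort():
    """One small three-layer cohort shared by read-only tests."""
    return simulate_cohort(small_config(seed=11))


@pytest.fixture()
def toy_layer():
    """A hand-built 4-cell x 3-gene snRNA layer with known counts."""
    var = make_feature_frame(
        ["gA", "gB", "gC"],
        "gene",
        "chr1",
        [100, 1000, 5000],
        [600, 2000, 6000],
        [100.0, 1000.0, 5000.0],
    )
    obs = pd.DataFrame(
        {
            "donor_id": ["d1", "d1", "d2", "d1"],
            "lineage": ["Monocyte", "Monocyte", "Monocyte", "not_assigned"],
            "timepoint": ["T1", "T1", "T1", "T1"],
        },
        index=pd.Index(["bc1", "bc2", "bc3", "bc4"], name="barcode"),
    )
    counts = np.array(
        [
            [1, 2, 0],
            [3, 4, 1],
            [5, 0, 2],
            [7, 7, 7],
        ]
    )
    return make_layer(counts, obs, var, "snRNA")
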