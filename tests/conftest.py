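import numpy as np
import pandas as pd
import pytest

from arrayscreen.synth import PlateSimSpec, simulate_plate


@pytest.fixture
def small_plate():
    """A deterministic 96-well plate with all content types present."""
    spec = PlateSimSpec(
        gene_effects={"GENE1": 0.2, "GENE2": 1.0},
        noise_cv=0.0,
        mock_mean=1100.0,
        blank_mean=100.0,
        seed=11,
    )
    return simulate_plate(spec)


@pytest.fixture
def noisy_plate():
    spec = PlateSimSpec(
        gene_effects={f"G{i}": 1.0 for i in range(10)} | {"KILL": 0.2},
        noise_cv=0.05,
        seed=7,
    )
    return simulate_plate(spec)


def match_centroids(objects: pd.DataFrame, truth: pd.DataFrame) -> np.ndarray:
    """Distance from each detected centroid to its nearest truth center."""
    from scipy.spatial import cKDTree

    tree = cKDTree(truth[["center_r", "center_c"]].to_numpy())
    d, _ = tree.query(objects[["centroid_r", "centroid_c"]].to_numpy())
    return d
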