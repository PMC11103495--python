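import numpy as np
import pytest

import tripodd as tp


@pytest.fixture(scope="session")
def noiseless_sf() -> tp.ScalingFactor:
    """SF fitted from a noiseless titration with true slopes 3 and 6."""
    ts = tp.generate_titration(3.0, 6.0, [1, 2, 4, 8], noise_sigma=0.0, seed=0)
    df = ts.mean_intensities()
    series = {
        probe: tp.TitrationSeries(
            probe, tuple(sub["concentration"]), tuple(sub["mean_intensity"])
        )
        for probe, sub in df.groupby("probe")
    }
    return tp.calibrate_from_series(series["targeted"], series["untargeted"])


@pytest.fixture(scope="session")
def clean_phantom():
    """Noiseless, autofluorescence-free phantom: the exact-DTA oracle scene."""
    config = tp.PhantomConfig(
        n_cells=60,
        field_size=(448, 448),
        noise_sigma=0.0,
        autofluorescence_levels={"DAPI": 0.0, "Cy2": 2.0, "Cy3": 0.0, "Cy5": 0.0},
        seed=42,
    )
    return config, *tp.generate_phantom(config)


@pytest.fixture(scope="session")
def noisy_phantom():
    """Default-noise phantom used by registration/segmentation tests."""
    config = tp.PhantomConfig(n_cells=60, field_size=(448, 448), seed=7)
    return config, *tp.generate_phantom(config)


def match_cells_to_truth(cells, truth_cells):
    """Pair each segmented cell with the nearest ground-truth centroid."""
    from scipy.spatial import cKDTree

    tree = cKDTree(np.c_[truth_cells["row"], truth_cells["col"]])
    dist, idx = tree.query(np.c_[cells["centroid_row"], cells["centroid_col"]])
    return dist, idx
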