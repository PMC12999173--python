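import numpy as np
import pandas as pd
import pytest

from azprofile.core import CLUSTER_COLUMNS, ClusterTable


def make_table(points, intensities=None, volumes=None, compartments=None,
               spacing=(0.37, 0.079, 0.079)) -> ClusterTable:
    """Build a ClusterTable directly from points (x, y, z in um)."""
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    n = len(pts)
    df = pd.DataFrame({
        "id": np.arange(1, n + 1),
        "x_um": pts[:, 0], "y_um": pts[:, 1], "z_um": pts[:, 2],
        "volume_vox": np.ones(n, dtype=int) if volumes is None else np.asarray(volumes),
        "intensity": np.ones(n) if intensities is None else np.asarray(intensities, float),
        "seed_z": -1, "seed_y": -1, "seed_x": -1,
        "compartment": "" if compartments is None else list(compartments),
    })[CLUSTER_COLUMNS]
    return ClusterTable(df=df, spacing=spacing)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def collinear_table():
    """Three collinear clusters at x = 0, 1, 3 um with intensities 1, 2, 3."""
    return make_table([(0, 0, 0), (1, 0, 0), (3, 0, 0)], intensities=[1, 2, 3])
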