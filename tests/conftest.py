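import numpy as np
import pandas as pd
import pytest

from sgctme.simulate import SimulationConfig, generate_roi


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_patients=4, rois_per_patient=1,
                            cells_per_roi=400, seed=7)


@pytest.fixture(scope="session")
def roi_cells(small_config):
    """One seeded SDC ROI plus its planted truth."""
    cells, truth = generate_roi(small_config, "SDC", seed=42)
    return cells, truth


def toy_roi(coords, labels, roi_id="toy"):
    """Hand-built minimal cell table from coordinate/label lists."""
    coords = np.asarray(coords, dtype=float)
    return pd.DataFrame({
        "cell_id": [f"c{i:03d}" for i in range(len(coords))],
        "patient_id": "P000",
        "roi_id": roi_id,
        "x_um": coords[:, 0],
        "y_um": coords[:, 1],
        "label_final": list(labels),
    })
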