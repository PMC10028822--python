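import numpy as np
import pandas as pd
import pytest

from brainatlas import synthetic
from brainatlas.core_io import CellTable, ReferenceDataset


@pytest.fixture(scope="session")
def specs():
    return synthetic.default_specs()


@pytest.fixture(scope="session")
def integration_data(specs):
    """Reference + measured draw from the 10-subclass / 30-cluster fixture."""
    spec = specs["integration"]
    ref = synthetic.simulate_reference(spec, n_per_cluster=100, seed=1)
    meas, truth = synthetic.simulate_measured(spec, n_per_cluster=50, seed=2)
    return spec, ref, meas, truth


@pytest.fixture
def tiny_cells():
    """Three cells, four genes, hand-set coordinates and volumes."""
    meta = pd.DataFrame(
        {
            "section_id": ["s1", "s1", "s1"],
            "x": [0.0, 10.0, 100.0],
            "y": [0.0, 0.0, 0.0],
            "z_planes": [3, 3, 3],
            "volume": [100.0, 200.0, 100.0],
        },
        index=pd.Index(["c1", "c2", "c3"], name="cell_id"),
    )
    counts = np.array([[5, 0, 2, 1], [0, 3, 0, 7], [1, 1, 1, 1]])
    return CellTable(genes=["Slc17a7", "Slc32a1", "gA", "gB"], counts=counts, meta=meta)


@pytest.fixture
def two_cluster_reference():
    """Two well-separated clusters of 200 cells over 6 genes."""
    rng = np.random.default_rng(0)
    profile_a = np.array([8.0, 2.0, 5.0, 5.0, 0.5, 5.0])
    profile_b = np.array([2.0, 8.0, 5.0, 5.0, 0.5, 5.0])
    counts = np.vstack(
        [rng.poisson(profile_a, (200, 6)), rng.poisson(profile_b, (200, 6))]
    )
    return ReferenceDataset(
        genes=[f"g{i}" for i in range(6)],
        counts=counts,
        cell_ids=[f"c{i}" for i in range(400)],
        subclass_labels=np.array(["A"] * 200 + ["B"] * 200, dtype=object),
        cluster_labels=np.array(["A1"] * 200 + ["B1"] * 200, dtype=object),
    )
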