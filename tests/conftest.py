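import numpy as np
import pandas as pd
import pytest

from geosurv.data_model import SpatialFrame, build_region_graph
from geosurv.spatial_model import ModelSpec, build_model


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def path_graph():
    """Three regions in a line: g = (1, 2, 1)."""
    return build_region_graph([("A", "B"), ("B", "C")])


@pytest.fixture
def tiny_model():
    """4 clusters, 2 regions, 12 children — small enough to hand-assemble."""
    rng = np.random.default_rng(7)
    cluster_ids = np.array(["c0", "c1", "c2", "c3"])
    lonlat = np.array([[0.0, 12.0], [0.2, 12.1], [0.5, 12.4], [0.7, 12.6]])
    region_of = pd.Series(["A", "A", "B", "B"], index=cluster_ids)
    frame = SpatialFrame(cluster_ids, lonlat, region_of)
    graph = build_region_graph([("A", "B")])
    coverage = pd.DataFrame(
        {"itn_use": [0.40, 0.70]}, index=pd.Index(["A", "B"], name="region_id")
    )
    children = pd.DataFrame(
        {
            "child_id": [f"k{i}" for i in range(12)],
            "cluster_id": np.repeat(cluster_ids, 3),
            "time_months": rng.uniform(1.0, 59.0, 12).round(3),
            "event": rng.integers(0, 2, 12),
            "sex": rng.choice(["female", "male"], 12),
        }
    )
    spec = ModelSpec(intervention="itn_use", covariates=("sex",))
    data = build_model(children, frame, graph, coverage, spec)
    return data
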