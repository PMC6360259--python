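import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from pgcna import ExpressionMatrix, SimConfig, simulate_timecourse

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def make_expression(values, sample_meta=None):
    """Small ExpressionMatrix helper: values is dict probe -> list."""
    frame = pd.DataFrame.from_dict(values, orient="index")
    frame.index.name = "probe_id"
    n = frame.shape[1]
    frame.columns = [f"s{i + 1}" for i in range(n)]
    if sample_meta is None:
        sample_meta = pd.DataFrame(
            {
                "donor": [f"D{i % 2 + 1}" for i in range(n)],
                "condition": ["C1"] * n,
                "timepoint": [f"t{i // 2}" for i in range(n)],
                "time_order": [i // 2 for i in range(n)],
            },
            index=pd.Index(frame.columns, name="sample_id"),
        )
    return ExpressionMatrix(values=frame.astype(float), samples=sample_meta)


@pytest.fixture(scope="session")
def default_dataset():
    """One default synthetic time course, shared across tests."""
    return simulate_timecourse(SimConfig(seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def two_triangles():
    """Two disjoint unweighted triangles: known optimum Q = 0.5."""
    import networkx as nx

    g = nx.Graph()
    g.add_edges_from([("a", "b"), ("b", "c"), ("a", "c"), ("x", "y"), ("y", "z"), ("x", "z")])
    return g
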