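import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import cyclenet as cn

settings.register_profile(
    "suite", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("suite")


def make_matrix(values: dict[str, list[float]], experiment: str = "V1",
                condition: str = "18C",
                zt: list[float] | None = None) -> cn.TimeCourseMatrix:
    """Build a small TimeCourseMatrix from per-gene value lists."""
    n = len(next(iter(values.values())))
    zt = zt if zt is not None else [2.0 * i for i in range(n)]
    samples = [f"{experiment}_{condition}_s{i}" for i in range(n)]
    vals = pd.DataFrame(values, index=samples).T
    meta = pd.DataFrame({
        "sample_id": samples, "zt_hours": zt, "replicate": 1,
        "experiment": experiment, "condition": condition,
    })
    return cn.TimeCourseMatrix(vals, meta)


@pytest.fixture(scope="session")
def er_graph():
    """A connected 500-node sparse random graph reused across tests."""
    g = cn.generate_network(500, 8.0, "erdos_renyi", seed=42)
    from cyclenet.network import largest_connected_component
    return largest_connected_component(g)


@pytest.fixture(scope="session")
def flat_truth():
    """Truth table of 2000 non-cycling genes at a common mesor."""
    n = 2000
    return pd.DataFrame({
        "gene_id": [f"g{i:05d}" for i in range(n)],
        "is_cycling": False,
        "phase_true": np.nan,
        "amplitude_true": 0.0,
        "mesor_true": 50.0,
        "condition": "18C",
    })
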