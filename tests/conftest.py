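import networkx as nx
import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import nwtopo as nw

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

#: the study-grid parameter variations at fixed network size
GRID = {"mean_length": [6.0, 7.0, 8.0, 9.0], "dispersion": [0.0, 0.1, 0.2, 0.5]}


def study_grid_ensemble(n_wires: int, seed: int = 1) -> list[nw.NanowireNetwork]:
    """Depositions spanning mean lengths 6-9 um x dispersions 0-50% on the
    30x30 um plane, one network per grid point (16 >= 10)."""
    return nw.generate_ensemble({"n_wires": [n_wires], **GRID}, seed=seed)


@pytest.fixture(scope="session")
def asn100():
    return study_grid_ensemble(100)


@pytest.fixture(scope="session")
def asn500():
    return study_grid_ensemble(500)


@pytest.fixture(scope="session")
def small_deposition():
    params = nw.WireEnsembleParams(120, 8.0, 0.2, seed=7)
    return nw.build_network(nw.sample_wires(params), params)


@pytest.fixture(scope="session")
def synthetic_connectome_fixture():
    return nw.synthetic_connectome(n_nodes=277, n_edges=2105, hub_fraction=0.1, seed=3)


def random_graph(n: int, p: float, seed: int) -> nx.Graph:
    return nx.gnp_random_graph(n, p, seed=seed)
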