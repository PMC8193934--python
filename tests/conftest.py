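import logging

import networkx as nx
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

logging.getLogger("netpharm").setLevel(logging.WARNING)


@pytest.fixture()
def clique_pendant() -> nx.Graph:
    """5-clique with one pendant leaf per clique node (10 nodes)."""
    g = nx.Graph()
    for i in range(5):
        for j in range(i + 1, 5):
            g.add_edge(f"C{i}", f"C{j}")
        g.add_edge(f"C{i}", f"L{i}")
    return g


@pytest.fixture(scope="session")
def bundle():
    """One shared synthetic pipeline instance (in memory)."""
    from netpharm.synthetic_data import simulate

    return simulate(seed=7)


@pytest.fixture(scope="session")
def sim_dir(tmp_path_factory):
    """The same synthetic instance written to disk."""
    from netpharm.synthetic_data import simulate

    outdir = tmp_path_factory.mktemp("sim")
    simulate(seed=7, outdir=outdir)
    return outdir
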