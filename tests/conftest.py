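import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import capnet

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_net(segments, edges):
    """Build a network from terse row tuples.

    segments: (id, length_um, diameter_um) tuples (None allowed);
    edges: (junction_id, kind, major, minor1, minor2) tuples.
    """
    seg_df = pd.DataFrame(segments, columns=["id", "length_um", "diameter_um"])
    edge_df = pd.DataFrame(
        edges, columns=["junction_id", "kind", "parent_id", "daughter1_id", "daughter2_id"]
    )
    return capnet.build_network(seg_df, edge_df)


@pytest.fixture
def toy_net():
    """Feeder -> bifurcation -> two terminals -> confluence -> venule."""
    net = make_net(
        [("F", 100.0, 10.0), ("A", 50.0, 4.0), ("B", 60.0, 5.0),
         ("C", 30.0, 6.0)],
        [("J1", "BIFURCATION", "F", "A", "B"),
         ("J2", "CONFLUENCE", "C", "A", "B")],
    )
    capnet.identify_feeders(net)
    return net


@pytest.fixture(scope="session")
def small_generated():
    """One generated network with ground truth, shared across tests."""
    cfg = capnet.SyntheticConfig(seed=5, n_feeders=2, tree_depth=3, unorthodox_fraction=0.2)
    net, truth = capnet.generate_network(cfg)
    return cfg, net, truth
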