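import networkx as nx
import numpy as np
import pandas as pd
import pytest

import capnet
from capnet import CapillaryType as CT
from capnet.errors import AnalysisError, InputError, StructureError

from conftest import make_net


class TestBuild:
    def test_single_bifurcation(self):
        net = make_net(
            [("P", 10.0, 8.0), ("D1", 10.0, 4.0), ("D2", 10.0, 4.0)],
            [("J1", "BIFURCATION", "P", "D1", "D2")],
        )
        assert len(net.junctions) == 1
        assert net.graph.out_degree("P") == 2

    def test_unknown_id_named_in_error(self):
        with pytest.raises(InputError, match="99"):
            make_net(
                [("P", 10.0, 8.0), ("D1", 10.0, 4.0)],
                [("J1", "BIFURCATION", "P", "D1", "99")],
            )

    def test_empty_edges_gives_isolated_unclassified(self):
        net = make_net([("A", 10.0, 4.0), ("B", 10.0, 4.0)], [])
        assert capnet.classify_network(net) == {"A": CT.UNCLASSIFIED, "B": CT.UNCLASSIFIED}
        assert net.graph.number_of_edges() == 0

    def test_duplicate_segment_id_rejected(self):
        with pytest.raises(InputError, match="duplicate"):
            make_net([("A", 10.0, 4.0), ("A", 10.0, 4.0)], [])

    def test_junction_needs_three_distinct_segments(self):
        with pytest.raises(StructureError):
            make_net(
                [("P", 10.0, 8.0), ("D1", 10.0, 4.0)],
                [("J1", "BIFURCATION", "P", "D1", "D1")],
            )

    def test_crossing_creates_no_adjacency(self):
        net = make_net(
            [("A", 10.0, 4.0), ("B", 10.0, 4.0)],
            [("X1", "CROSSING", "A", "B", "")],
        )
        assert net.crossings == [("A", "B")]
        assert net.graph.number_of_edges() == 0


class TestValidate:
    def test_generator_output_clean(self, small_generated):
        _, net, _ = small_generated
        assert capnet.validate_network(net) == []

    def test_mislabeled_confluence_reported_as_kind_mismatch(self):
        # true topology: P splits into A, B which then merge into C, but the
        # merge is mislabeled as a bifurcation with C as its parent
        net = make_net(
            [("P", 10.0, 9.0), ("A", 10.0, 4.0), ("B", 10.0, 4.0), ("C", 10.0, 5.0)],
            [("J1", "BIFURCATION", "P", "A", "B"),
             ("J2", "BIFURCATION", "C", "A", "B")],
        )
        capnet.identify_feeders(net)
        report = capnet.validate_network(net)
        mismatches = [v for v in report if v["type"] == "kind-mismatch"]
        assert len(mismatches) == 1
        assert mismatches[0]["junction_id"] == "J2"

    def test_feeder_with_inflow_flagged(self):
        net = make_net(
            [("U", 10.0, 9.0), ("F", 10.0, 9.0), ("X", 10.0, 4.0)],
            [("J1", "BIFURCATION", "U", "F", "X")],
        )
        net.segments["F"].is_feeder = True
        assert any(v["type"] == "feeder-inflow" for v in capnet.validate_network(net))


class TestFeeders:
    def test_wide_parentless_segment_is_feeder(self):
        net = make_net(
            [("F", 10.0, 9.0), ("A", 10.0, 4.0), ("B", 10.0, 4.0)],
            [("J1", "BIFURCATION", "F", "A", "B")],
        )
        assert capnet.identify_feeders(net) == {"F"}

    def test_no_candidate_feeder_raises(self):
        net = make_net([("A", 10.0, 4.0), ("B", 10.0, 7.9)], [])
        with pytest.raises(AnalysisError):
            capnet.identify_feeders(net)

    def test_two_components_two_feeders(self):
        net = make_net(
            [("F1", 10.0, 9.0), ("A", 10.0, 4.0), ("B", 10.0, 4.0),
             ("F2", 10.0, 12.0), ("C", 10.0, 4.0), ("D", 10.0, 4.0)],
            [("J1", "BIFURCATION", "F1", "A", "B"),
             ("J2", "BIFURCATION", "F2", "C", "D")],
        )
        assert capnet.identify_feeders(net) == {"F1", "F2"}


class TestClassification:
    @pytest.mark.parametrize(
        "seg,expected",
        [("A", CT.TC), ("B", CT.TC), ("F", CT.UNCLASSIFIED), ("C", CT.UNCLASSIFIED)],
    )
    def test_toy_types(self, toy_net, seg, expected):
        assert capnet.classify_segment(toy_net, seg) is expected

    def test_unorthodox_between_confluence_and_bifurcation(self):
        # W is fed by a confluence and drained by a bifurcation
        net = make_net(
            [("A", 10.0, 4.0), ("B", 10.0, 4.0), ("W", 10.0, 5.0),
             ("X", 10.0, 3.0), ("Y", 10.0, 3.0)],
            [("J1", "CONFLUENCE", "W", "A", "B"),
             ("J2", "BIFURCATION", "W", "X", "Y")],
        )
        assert capnet.classify_segment(net, "W") is CT.WC

    def test_totality_on_generated_network(self, small_generated):
        _, net, truth = small_generated
        classes = capnet.classify_network(net)
        counts = pd.Series([c.value for c in classes.values()]).value_counts()
        assert counts.sum() == len(net.segments)
        assert {c.value for c in classes.values()} <= {t.value for t in CT}
        assert {s: c.value for s, c in classes.items()} == truth.capillary_type


class TestTopology:
    def test_feeder_is_order_one_and_half_length(self, toy_net):
        assert capnet.branch_order(toy_net, "F") == 1
        assert capnet.feeder_distance(toy_net, "F") == pytest.approx(50.0)

    def test_daughter_of_feeder_bifurcation_is_order_two(self, toy_net):
        assert capnet.branch_order(toy_net, "A") == 2

    def test_path_sum_plus_half_own_length(self):
        net = make_net(
            [("F", 100.0, 9.0), ("A", 50.0, 5.0), ("Z", 40.0, 5.0),
             ("B", 30.0, 4.0), ("C", 30.0, 4.0)],
            [("J1", "BIFURCATION", "F", "A", "Z"),
             ("J2", "BIFURCATION", "A", "B", "C")],
        )
        capnet.identify_feeders(net)
        assert capnet.feeder_distance(net, "B") == pytest.approx(100 + 50 + 15)

    def test_chain_of_eight_bifurcations_gives_order_nine(self):
        segs, edges = [("S0", 10.0, 40.0)], []
        prev = "S0"
        for k in range(1, 9):
            a, b = f"S{k}", f"T{k}"
            segs += [(a, 10.0, 30.0 - 3 * k), (b, 10.0, 30.0 - 3 * k)]
            edges.append((f"J{k}", "BIFURCATION", prev, a, b))
            prev = a
        net = make_net(segs, edges)
        capnet.identify_feeders(net)
        assert capnet.branch_order(net, "S8") == 9

    def test_shortest_path_rule_against_enumeration(self):
        # two routes of summed upstream length 200 vs 260 reach C
        net = make_net(
            [("F", 100.0, 9.0), ("A", 100.0, 5.0), ("B", 160.0, 5.0),
             ("C", 30.0, 6.0)],
            [("J1", "BIFURCATION", "F", "A", "B"),
             ("J2", "CONFLUENCE", "C", "A", "B")],
        )
        capnet.identify_feeders(net)
        # oracle: enumerate all upstream paths with networkx
        best = min(
            sum(net.segments[s].length for s in path[:-1])
            for path in nx.all_simple_paths(net.graph, "F", "C")
        )
        assert best == 200.0
        assert capnet.feeder_distance(net, "C") == pytest.approx(best + 15.0)
        # confluence does not increment branch order
        assert capnet.branch_order(net, "C") == 2

    def test_additivity_across_a_bifurcation(self, toy_net):
        dF = capnet.feeder_distance(toy_net, "F")
        dA = capnet.feeder_distance(toy_net, "A")
        assert dA == pytest.approx(dF + 100.0 / 2 + 50.0 / 2)

    def test_unreachable_segment_raises(self):
        net = make_net([("F", 10.0, 9.0), ("L", 10.0, 4.0)], [])
        capnet.identify_feeders(net)
        with pytest.raises(AnalysisError):
            capnet.branch_order(net, "L")

    def test_generated_topology_matches_ground_truth(self, small_generated):
        _, net, truth = small_generated
        topo = capnet.compute_topology(net)
        for _, row in topo.iterrows():
            assert row["branch_order"] == truth.branch_order[row["id"]]
            assert row["feeder_distance_um"] == pytest.approx(
                truth.feeder_distance[row["id"]], abs=1e-9
            )

    def test_crossings_do_not_affect_topology(self, toy_net):
        d0 = capnet.feeder_distance(toy_net, "C")
        toy_net.crossings.append(("F", "C"))
        assert capnet.feeder_distance(toy_net, "C") == d0
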