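"""Subnetwork decomposition: splitting, linkers, suggestions, validation."""

import networkx as nx
import pytest

from conftest import make_random_bipartite, split_oracle
from glyphnet.model import (
    BipartitionSpec,
    EdgeRole,
    Network,
    NetworkError,
    NodeClass,
    NodeRecord,
)
from glyphnet.subnetworks import (
    SplitConfig,
    split,
    subnetwork_graph,
    suggest_exclusions,
    validate_split,
)


def _linker_triples(subs):
    return {
        (l.home_group, l.target_group, l.anchor_id) for s in subs for l in s.linkers
    }


class TestSplitBasics:
    def test_two_groups_shared_bridge_symmetric_linkers(self, simple_net):
        subs = split(simple_net, SplitConfig())
        by_group = {s.group: s for s in subs}
        assert set(by_group) == {"A", "B"}
        a_linkers = [(l.label, l.anchor_id) for l in by_group["A"].linkers]
        b_linkers = [(l.label, l.anchor_id) for l in by_group["B"].linkers]
        assert a_linkers == [("B", "mShared")]
        assert b_linkers == [("A", "mShared")]
        # linker node is inside the subnetwork, wired to the anchor by a link edge
        lid = by_group["A"].linkers[0].id
        assert by_group["A"].net.node(lid).node_class == NodeClass.LINKER
        assert by_group["A"].net.neighbors("mShared", {"link"}) == {lid}

    def test_gene_companions_follow_their_reactions(self, simple_net):
        subs = split(simple_net, SplitConfig())
        by_group = {s.group: s for s in subs}
        assert by_group["A"].net.has_node("gene:g1")
        assert not by_group["B"].net.has_node("gene:g1")

    def test_single_group_no_linkers(self):
        net = Network()
        net.add_node(NodeRecord(id="r", node_class=NodeClass.REACTION, subsystems=["X"]))
        net.add_node(NodeRecord(id="m", node_class=NodeClass.SPECIES))
        net.add_edge("m", "r", EdgeRole.SUBSTRATE)
        subs = split(net, SplitConfig())
        assert len(subs) == 1
        assert subs[0].linkers == []

    def test_nonlink_bridge_present_in_both_groups_no_linkers(self, simple_net):
        subs = split(simple_net, SplitConfig(nonlink_ids={"mShared"}))
        by_group = {s.group: s for s in subs}
        assert by_group["A"].net.has_node("mShared")
        assert by_group["B"].net.has_node("mShared")
        assert _linker_triples(subs) == set()

    def test_removed_bridge_absent_everywhere(self, simple_net):
        subs = split(simple_net, SplitConfig(removed_ids={"mShared"}))
        for sub in subs:
            assert not sub.net.has_node("mShared")
        assert _linker_triples(subs) == set()

    def test_unassigned_members_pooled(self):
        net = Network()
        net.add_node(NodeRecord(id="r1", node_class=NodeClass.REACTION, subsystems=["X"]))
        net.add_node(NodeRecord(id="r2", node_class=NodeClass.REACTION))
        net.add_node(NodeRecord(id="m", node_class=NodeClass.SPECIES))
        net.add_edge("m", "r1", EdgeRole.SUBSTRATE)
        net.add_edge("m", "r2", EdgeRole.SUBSTRATE)
        subs = split(net, SplitConfig())
        groups = {s.group for s in subs}
        assert groups == {"X", "(unassigned)"}
        unassigned = next(s for s in subs if s.group == "(unassigned)")
        assert unassigned.net.has_node("r2")

    def test_overlapping_removed_nonlink_rejected(self, simple_net):
        with pytest.raises(NetworkError, match="overlap"):
            split(simple_net, SplitConfig(removed_ids={"mA"}, nonlink_ids={"mA"}))

    def test_wrong_class_exclusion_rejected(self, simple_net):
        with pytest.raises(NetworkError, match="class"):
            split(simple_net, SplitConfig(removed_ids={"rA"}))

    def test_collapse_linkers_single_node_per_target_group(self):
        net = Network()
        for g, rids in [("A", ["r1", "r2"]), ("B", ["r3", "r4"])]:
            for rid in rids:
                net.add_node(
                    NodeRecord(id=rid, node_class=NodeClass.REACTION, subsystems=[g])
                )
        for i, (ra, rb) in enumerate([("r1", "r3"), ("r2", "r4")]):
            mid = f"m{i}"
            net.add_node(NodeRecord(id=mid, node_class=NodeClass.SPECIES))
            net.add_edge(ra, mid, EdgeRole.PRODUCT)
            net.add_edge(mid, rb, EdgeRole.SUBSTRATE)
        per_anchor = split(net, SplitConfig())
        collapsed = split(net, SplitConfig(collapse_linkers=True))
        a_default = next(s for s in per_anchor if s.group == "A")
        a_collapsed = next(s for s in collapsed if s.group == "A")
        assert len({l.id for l in a_default.linkers}) == 2
        assert len({l.id for l in a_collapsed.linkers}) == 1


class TestSplitAgainstOracle:
    @pytest.mark.parametrize("seed", range(20))
    def test_membership_edges_linkers_match_definition(self, seed):
        """Exhaustive per-definition oracle on seeded random bipartite nets,
        with and without removed/non-linking sets."""
        net = make_random_bipartite(seed, n_members=40, n_bridges=25, n_groups=4)
        spec = BipartitionSpec()
        removed = {"m0", "m1"} if seed % 2 else set()
        nonlink = {"m2"} if seed % 3 == 0 else set()
        config = SplitConfig(
            bipartition=spec, removed_ids=removed, nonlink_ids=nonlink
        )
        subs = split(net, config)
        expected = split_oracle(net, spec, removed, nonlink)
        assert {s.group for s in subs} == set(expected)
        for sub in subs:
            exp = expected[sub.group]
            members = {
                n.id for n in sub.net.nodes if n.node_class == NodeClass.REACTION
            }
            bridges = {
                n.id for n in sub.net.nodes if n.node_class == NodeClass.SPECIES
            }
            edges = {
                e.key()
                for e in sub.net.edges
                if e.role in (EdgeRole.SUBSTRATE, EdgeRole.PRODUCT, EdgeRole.MODIFIER)
            }
            assert members == exp["members"]
            assert bridges == exp["bridges"]
            assert edges == exp["edges"]
            assert {
                (l.home_group, l.target_group, l.anchor_id) for l in sub.linkers
            } == exp["linkers"]

    @pytest.mark.parametrize("seed", [0, 5, 13])
    def test_linker_symmetry(self, seed):
        net = make_random_bipartite(seed)
        subs = split(net, SplitConfig())
        triples = _linker_triples(subs)
        assert triples, "expected some cross-group connectivity"
        for home, target, anchor in triples:
            assert (target, home, anchor) in triples

    @pytest.mark.parametrize("seed", [1, 9])
    def test_determinism(self, seed):
        net = make_random_bipartite(seed)
        first = split(net, SplitConfig())
        second = split(net, SplitConfig())
        assert [s.group for s in first] == [s.group for s in second]
        for a, b in zip(first, second):
            assert a.net == b.net
            assert [(l.id, l.anchor_id) for l in a.linkers] == [
                (l.id, l.anchor_id) for l in b.linkers
            ]


class TestNavigability:
    @pytest.mark.parametrize("seed", range(20))
    def test_connected_members_have_connected_groups(self, seed):
        """Any two members joined by a path over allowed bridges must have
        their groups connected in the navigation meta-graph."""
        net = make_random_bipartite(seed, n_members=30, n_bridges=20, n_groups=3)
        removed = {"m0"} if seed % 2 else set()
        nonlink = {"m1"} if seed % 3 == 0 else set()
        config = SplitConfig(removed_ids=removed, nonlink_ids=nonlink)
        subs = split(net, config)
        meta = subnetwork_graph(subs)

        # oracle graphs via networkx connectivity
        allowed = nx.Graph()
        for e in net.edges:
            if (
                net.node(e.source).node_class == NodeClass.GENE
                or net.node(e.target).node_class == NodeClass.GENE
            ):
                continue
            if {e.source, e.target} & (removed | nonlink):
                continue
            allowed.add_edge(e.source, e.target)
        meta_graph = nx.Graph()
        meta_graph.add_nodes_from(meta.node_ids())
        for e in meta.edges:
            meta_graph.add_edge(e.source, e.target)

        members = [n.id for n in net.nodes_of_class(NodeClass.REACTION)]
        for component in nx.connected_components(allowed):
            groups = set()
            for nid in component:
                if nid in members:
                    groups.update(net.group_values(nid, "subsystems") or ["(unassigned)"])
            for a in groups:
                for b in groups:
                    assert nx.has_path(meta_graph, a, b)


class TestSubnetworkGraph:
    def test_three_pathway_toy_fully_connected(self):
        net = Network()
        groups = ["P1", "P2", "P3"]
        for g in groups:
            net.add_node(
                NodeRecord(id=f"r_{g}", node_class=NodeClass.REACTION, subsystems=[g])
            )
        for a, b in [("P1", "P2"), ("P1", "P3"), ("P2", "P3")]:
            mid = f"m_{a}{b}"
            net.add_node(NodeRecord(id=mid, node_class=NodeClass.SPECIES))
            net.add_edge(f"r_{a}", mid, EdgeRole.PRODUCT)
            net.add_edge(mid, f"r_{b}", EdgeRole.SUBSTRATE)
        subs = split(net, SplitConfig())
        meta = subnetwork_graph(subs)
        assert meta.n_nodes() == 3
        assert meta.n_edges() == 3  # all pairs share a metabolite

    def test_single_subnetwork_graph(self):
        net = Network()
        net.add_node(NodeRecord(id="r", node_class=NodeClass.REACTION, subsystems=["X"]))
        net.add_node(NodeRecord(id="m", node_class=NodeClass.SPECIES))
        net.add_edge("m", "r", EdgeRole.SUBSTRATE)
        meta = subnetwork_graph(split(net, SplitConfig()))
        assert meta.n_nodes() == 1 and meta.n_edges() == 0

    def test_meta_edges_equal_pairs_sharing_a_linking_bridge(self):
        net = make_random_bipartite(17)
        subs = split(net, SplitConfig())
        meta = subnetwork_graph(subs)
        expected_pairs = {
            tuple(sorted((l.home_group, l.target_group)))
            for s in subs
            for l in s.linkers
        }
        assert {tuple(sorted((e.source, e.target))) for e in meta.edges} == expected_pairs


class TestSuggestions:
    def _degree_net(self, degrees):
        net = Network()
        for i, d in enumerate(degrees):
            net.add_node(NodeRecord(id=f"m{i}", node_class=NodeClass.SPECIES))
            for j in range(d):
                rid = f"r_{i}_{j}"
                net.add_node(
                    NodeRecord(id=rid, node_class=NodeClass.REACTION, subsystems=["X"])
                )
                net.add_edge(f"m{i}", rid, EdgeRole.SUBSTRATE)
        return net

    def test_hub_flagged_for_removal(self):
        net = self._degree_net([40] + [2] * 10)
        report = suggest_exclusions(net, BipartitionSpec(), 30, 8)
        assert report.removed_ids == {"m0"}
        assert report.nonlink_ids == set()

    def test_uniform_degrees_nothing_flagged(self):
        net = self._degree_net([2] * 12)
        report = suggest_exclusions(net, BipartitionSpec(), 30, 8)
        assert report.removal_candidates == []
        assert report.nonlink_candidates == []

    def test_threshold_filter_matches_brute_force(self):
        import random

        rng = random.Random(3)
        degrees = [max(1, int(rng.paretovariate(1.2))) for _ in range(60)]
        net = self._degree_net(degrees)
        report = suggest_exclusions(net, BipartitionSpec(), 12, 5)
        expect_rm = sorted(
            [(f"m{i}", d) for i, d in enumerate(degrees) if d >= 12],
            key=lambda kv: (-kv[1], kv[0]),
        )
        expect_nl = sorted(
            [(f"m{i}", d) for i, d in enumerate(degrees) if 5 <= d < 12],
            key=lambda kv: (-kv[1], kv[0]),
        )
        assert report.removal_candidates == expect_rm
        assert report.nonlink_candidates == expect_nl
        assert report.removed_ids.isdisjoint(report.nonlink_ids)

    def test_no_bridge_nodes_errors(self):
        net = Network()
        net.add_node(NodeRecord(id="r", node_class=NodeClass.REACTION))
        with pytest.raises(NetworkError):
            suggest_exclusions(net, BipartitionSpec())


class TestValidateSplit:
    def test_correct_split_passes(self):
        net = make_random_bipartite(4)
        config = SplitConfig(removed_ids={"m0"})
        subs = split(net, config)
        assert validate_split(net, config, subs).ok

    def test_injected_removed_node_detected(self, simple_net):
        config = SplitConfig(removed_ids={"mB"})
        subs = split(simple_net, config)
        subs[0].net.add_node(NodeRecord(id="mB", node_class=NodeClass.SPECIES))
        report = validate_split(simple_net, config, subs)
        assert not report.ok
        assert any("removed node" in v for v in report.violations)

    def test_deleted_linker_breaks_symmetry(self):
        net = make_random_bipartite(6)
        config = SplitConfig()
        subs = split(net, config)
        victim = next(s for s in subs if s.linkers)
        victim.linkers.pop()
        report = validate_split(net, config, subs)
        assert not report.ok
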