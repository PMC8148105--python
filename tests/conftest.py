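"""Shared fixtures: random network builders and small SBML models."""

from __future__ import annotations

import random
from typing import Dict, List, Set, Tuple

import pytest

from glyphnet.model import (
    BipartitionSpec,
    EdgeRole,
    Network,
    NodeClass,
    NodeRecord,
)


def make_random_bipartite(
    seed: int,
    n_members: int = 50,
    n_bridges: int = 30,
    n_groups: int = 4,
    edge_prob: float = 0.08,
    multi_group_frac: float = 0.15,
    with_genes: bool = False,
) -> Network:
    """Random member/bridge bipartite network with group labels.

    Members are reactions carrying 1-2 subsystem values; bridges are
    species.  Optionally attaches gene companions to some members.
    """
    rng = random.Random(seed)
    net = Network(f"random_{seed}")
    groups = [f"G{i}" for i in range(n_groups)]
    for i in range(n_members):
        subsystems = [rng.choice(groups)]
        if rng.random() < multi_group_frac:
            other = rng.choice(groups)
            if other not in subsystems:
                subsystems.append(other)
        net.add_node(
            NodeRecord(
                id=f"r{i}", node_class=NodeClass.REACTION, subsystems=subsystems
            )
        )
    for j in range(n_bridges):
        net.add_node(NodeRecord(id=f"m{j}", node_class=NodeClass.SPECIES))
    for i in range(n_members):
        for j in range(n_bridges):
            if rng.random() < edge_prob:
                role = rng.choice([EdgeRole.SUBSTRATE, EdgeRole.PRODUCT])
                if role == EdgeRole.SUBSTRATE:
                    net.add_edge(f"m{j}", f"r{i}", role)
                else:
                    net.add_edge(f"r{i}", f"m{j}", role)
    # keep every member attached to at least one bridge
    for i in range(n_members):
        if net.degree(f"r{i}") == 0:
            j = rng.randrange(n_bridges)
            net.add_edge(f"m{j}", f"r{i}", EdgeRole.SUBSTRATE)
    if with_genes:
        for i in range(0, n_members, 3):
            gid = f"gene:g{i}"
            if not net.has_node(gid):
                net.add_node(NodeRecord(id=gid, node_class=NodeClass.GENE))
            net.add_edge(gid, f"r{i}", EdgeRole.GPR, directed=False)
    return net


def split_oracle(
    net: Network, spec: BipartitionSpec, removed: Set[str], nonlink: Set[str]
) -> Dict[str, dict]:
    """Exhaustive per-definition expectation for a split.

    Independently enumerates, per group: member ids, included bridge
    ids, conserved member-bridge edge keys, and linker triples
    (home, target, anchor) from all (bridge, group-pair) adjacencies.
    """
    members = [n for n in net.nodes if n.node_class == spec.member_class]
    bridges = [n for n in net.nodes if n.node_class == spec.bridge_class]

    def groups_of(node) -> List[str]:
        values = net.group_values(node.id, spec.group_attribute)
        return values if values else ["(unassigned)"]

    all_groups = sorted({g for m in members for g in groups_of(m)})
    expected: Dict[str, dict] = {
        g: {"members": set(), "bridges": set(), "edges": set(), "linkers": set()}
        for g in all_groups
    }
    for m in members:
        for g in groups_of(m):
            expected[g]["members"].add(m.id)
    member_ids = {m.id for m in members}
    for e in net.edges:
        endpoints = {e.source, e.target}
        ms = endpoints & member_ids
        bs = {b.id for b in bridges} & endpoints
        if len(ms) == 1 and len(bs) == 1:
            (mid,) = ms
            (bid,) = bs
            if bid in removed:
                continue
            for g in groups_of(net.node(mid)):
                expected[g]["bridges"].add(bid)
                expected[g]["edges"].add(e.key())
    for b in bridges:
        if b.id in removed or b.id in nonlink or b.duplication_group is not None:
            continue
        touched = set()
        for nb in net.neighbors(b.id):
            if nb in member_ids:
                touched.update(groups_of(net.node(nb)))
        for v in touched:
            for w in touched:
                if v != w:
                    expected[v]["linkers"].add((v, w, b.id))
    return expected


@pytest.fixture
def simple_net() -> Network:
    """Two pathways (A, B) sharing one bridge metabolite plus a gene."""
    net = Network("simple")
    net.add_node(NodeRecord(id="rA", node_class=NodeClass.REACTION, subsystems=["A"]))
    net.add_node(NodeRecord(id="rB", node_class=NodeClass.REACTION, subsystems=["B"]))
    net.add_node(NodeRecord(id="mShared", node_class=NodeClass.SPECIES))
    net.add_node(NodeRecord(id="mA", node_class=NodeClass.SPECIES))
    net.add_node(NodeRecord(id="mB", node_class=NodeClass.SPECIES))
    net.add_node(NodeRecord(id="gene:g1", node_class=NodeClass.GENE))
    net.add_edge("mA", "rA", EdgeRole.SUBSTRATE)
    net.add_edge("rA", "mShared", EdgeRole.PRODUCT)
    net.add_edge("mShared", "rB", EdgeRole.SUBSTRATE)
    net.add_edge("rB", "mB", EdgeRole.PRODUCT)
    net.add_edge("gene:g1", "rA", EdgeRole.GPR, directed=False)
    return net
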