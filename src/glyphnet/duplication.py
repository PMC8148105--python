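"""Linked replication of highly connected nodes, and their remerge.

Abundant co-factors (ATP, CoA, NAD(P)H ...) connect so many reactions
that any automatic layout degenerates.  Duplication replaces one hub
node by several replicates — one per incident edge or one per distinct
neighbor — that stay *linked*: they share a duplication group, so
attribute updates propagate across all replicates, the original can be
restored exactly (remerge), and omics data mapped to the original id
reaches every replicate through the ``data_id`` attribute.  Replicates
are treated as non-branching by the subnetwork decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Literal

from .model import EdgeRecord, Network, NetworkError, NodeClass, NodeRecord

__all__ = ["DuplicationRecord", "duplicate_node", "remerge", "propagate_attributes"]


@dataclass
class DuplicationRecord:
    group_id: str
    original: NodeRecord
    replicate_ids: List[str]
    edge_assignment: Dict[str, List[EdgeRecord]] = field(default_factory=dict)


def duplicate_node(
    net: Network,
    node_id: str,
    mode: Literal["per_edge", "per_neighbor"] = "per_edge",
) -> DuplicationRecord:
    """Replace a node by linked replicates, one per edge or per neighbor.

    The original node is removed; each replicate ``<id>#k`` (k in
    sorted-edge order, so the operation is deterministic) carries
    ``duplication_group`` and ``data_id`` = the original id.  Returns the
    record needed for :func:`remerge`; it is also stored on
    ``net.duplications``.
    """
    node = net.node(node_id)
    if node.node_class == NodeClass.LINKER:
        raise NetworkError(f"cannot duplicate linker node {node_id!r}")
    if node.duplication_group is not None:
        raise NetworkError(f"node {node_id!r} is already a replicate")
    if mode not in ("per_edge", "per_neighbor"):
        raise NetworkError(f"unknown duplication mode {mode!r}")

    edges = net.incident_edges(node_id)  # sorted by (source, target, role)
    if mode == "per_edge":
        buckets = [[e] for e in edges]
    else:
        by_neighbor: Dict[str, List[EdgeRecord]] = {}
        for e in edges:
            by_neighbor.setdefault(e.other(node_id), []).append(e)
        buckets = [by_neighbor[n] for n in sorted(by_neighbor)]
    if not buckets:  # isolated node still yields one replicate
        buckets = [[]]

    group_id = f"dup:{node_id}"
    if group_id in net.duplications:
        raise NetworkError(f"duplication group {group_id!r} already exists")
    original = node.copy()
    net.remove_node(node_id)

    record = DuplicationRecord(group_id=group_id, original=original, replicate_ids=[])
    for k, bucket in enumerate(buckets, start=1):
        rid = f"{node_id}#{k}"
        if net.has_node(rid):
            raise NetworkError(f"replicate id collision: {rid!r}")
        replicate = original.copy()
        replicate.id = rid
        replicate.duplication_group = group_id
        replicate.attributes["data_id"] = node_id
        net.add_node(replicate)
        for e in bucket:
            src = rid if e.source == node_id else e.source
            tgt = rid if e.target == node_id else e.target
            net.add_edge(src, tgt, e.role, e.directed, e.attr_dict())
        record.replicate_ids.append(rid)
        record.edge_assignment[rid] = list(bucket)
    net.duplications[group_id] = record
    return record


def remerge(net: Network, group_id: str) -> Network:
    """Collapse the replicates of a duplication group back into the original.

    Restores the original node id and its exact edge set; the group is
    consumed, so a second remerge of the same group errors.
    """
    record = net.duplications.get(group_id)
    if not isinstance(record, DuplicationRecord):
        raise NetworkError(f"unknown duplication group {group_id!r}")
    for rid in record.replicate_ids:
        if net.has_node(rid):
            net.remove_node(rid)
    net.add_node(record.original.copy())
    for edges in record.edge_assignment.values():
        for e in edges:
            net.add_edge(e.source, e.target, e.role, e.directed, e.attr_dict())
    del net.duplications[group_id]
    return net


def propagate_attributes(net: Network, group_id: str, attrs: Dict[str, str]) -> Network:
    """Apply an attribute update to every replicate of a duplication group.

    ``label`` is treated as the display label; any other key updates the
    free-form attribute map.  ``data_id`` and ``duplication_group`` stay
    under the module's control and cannot be overridden.
    """
    record = net.duplications.get(group_id)
    if not isinstance(record, DuplicationRecord):
        raise NetworkError(f"unknown duplication group {group_id!r}")
    clean = {k: v for k, v in attrs.items() if k not in ("data_id", "duplication_group")}
    for rid in record.replicate_ids:
        node = net.node(rid)
        for key, value in clean.items():
            if key == "label":
                node.label = value
            else:
                node.attributes[key] = value
    return net
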