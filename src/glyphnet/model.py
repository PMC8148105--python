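"""Typed multi-partite network model.

The central container is :class:`Network`, a lightweight typed graph whose
nodes are species, reactions, genes, proteins or linker placeholders and
whose edges carry a biochemical role (substrate, product, modifier,
catalyzes, encodes, gpr, link).  All higher-level operations (SBML
annotation, subnetwork decomposition, hub duplication, glyph rendering)
work on this container.

Identifiers are case-sensitive and matched exactly; no namespace
normalisation is performed.  Edge direction is stored but degree and
adjacency treat the graph as undirected, matching visual-navigation
semantics.  Parallel edges with distinct roles are allowed (a metabolite
can be both substrate and product of one reaction); identical
(source, target, role) triples collapse to a single edge.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Iterator, List, Optional, Set, Tuple

__all__ = [
    "NodeClass",
    "EdgeRole",
    "NodeRecord",
    "EdgeRecord",
    "Network",
    "BipartitionSpec",
    "NetworkError",
    "DuplicateNodeError",
    "UnknownNodeError",
]


class NetworkError(ValueError):
    """Base class for network consistency errors."""


class DuplicateNodeError(NetworkError):
    pass


class UnknownNodeError(NetworkError, KeyError):
    def __str__(self) -> str:  # KeyError quotes its args; keep the message readable
        return ValueError.__str__(self)


class NodeClass(str, enum.Enum):
    SPECIES = "species"
    REACTION = "reaction"
    GENE = "gene"
    PROTEIN = "protein"
    LINKER = "linker"
    OTHER = "other"


class EdgeRole(str, enum.Enum):
    SUBSTRATE = "substrate"
    PRODUCT = "product"
    MODIFIER = "modifier"
    CATALYZES = "catalyzes"
    ENCODES = "encodes"
    GPR = "gpr"
    LINK = "link"


@dataclass
class NodeRecord:
    """A single node with display metadata.

    ``duplication_group`` is set only on replicates created by the
    duplication module; ``attributes`` holds free-form string annotations
    (e.g. COBRA note tags, ``data_id`` for replicate data mapping).
    """

    id: str
    label: str = ""
    node_class: NodeClass = NodeClass.OTHER
    compartment: Optional[str] = None
    subsystems: List[str] = field(default_factory=list)
    sbo_term: Optional[str] = None
    attributes: Dict[str, str] = field(default_factory=dict)
    duplication_group: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise NetworkError("node id must be non-empty")
        if not self.label:
            self.label = self.id
        if isinstance(self.node_class, str):
            self.node_class = NodeClass(self.node_class)

    def copy(self) -> "NodeRecord":
        return replace(
            self,
            subsystems=list(self.subsystems),
            attributes=dict(self.attributes),
        )


@dataclass(frozen=True)
class EdgeRecord:
    source: str
    target: str
    role: EdgeRole
    directed: bool = True
    attributes: Tuple[Tuple[str, str], ...] = ()

    def key(self) -> Tuple[str, str, str]:
        return (self.source, self.target, self.role.value)

    def attr_dict(self) -> Dict[str, str]:
        return dict(self.attributes)

    def touches(self, node_id: str) -> bool:
        return self.source == node_id or self.target == node_id

    def other(self, node_id: str) -> str:
        if self.source == node_id:
            return self.target
        if self.target == node_id:
            return self.source
        raise UnknownNodeError(f"edge {self.key()} is not incident to {node_id!r}")


@dataclass
class BipartitionSpec:
    """Which node class belongs to subnetworks and which bridges them.

    ``group_attribute`` names the field or attribute on member nodes that
    holds the grouping value(s): ``"subsystems"`` (list-valued),
    ``"compartment"``, or any key of ``NodeRecord.attributes``.
    """

    member_class: NodeClass = NodeClass.REACTION
    bridge_class: NodeClass = NodeClass.SPECIES
    group_attribute: str = "subsystems"

    def __post_init__(self) -> None:
        if isinstance(self.member_class, str):
            self.member_class = NodeClass(self.member_class)
        if isinstance(self.bridge_class, str):
            self.bridge_class = NodeClass(self.bridge_class)
        allowed = {NodeClass.SPECIES, NodeClass.REACTION}
        if self.member_class == self.bridge_class:
            raise NetworkError("member_class and bridge_class must differ")
        if self.member_class not in allowed or self.bridge_class not in allowed:
            raise NetworkError("bipartition classes must be species/reaction")


class Network:
    """A typed multi-partite graph with unique node ids and role-typed edges.

    Edges are stored as a set of (source, target, role) triples with
    per-edge attributes; an adjacency index is maintained for O(1) degree
    and neighbor queries.  Self-loops are rejected.
    """

    def __init__(self, name: str = "network") -> None:
        self.name = name
        self._nodes: Dict[str, NodeRecord] = {}
        self._edges: Dict[Tuple[str, str, str], EdgeRecord] = {}
        self._incident: Dict[str, Set[Tuple[str, str, str]]] = {}
        # duplication bookkeeping (filled by the duplication module)
        self.duplications: Dict[str, object] = {}

    # -- nodes ---------------------------------------------------------

    def add_node(self, node: NodeRecord) -> "Network":
        if node.id in self._nodes:
            raise DuplicateNodeError(f"duplicate node id: {node.id!r}")
        self._nodes[node.id] = node
        self._incident[node.id] = set()
        return self

    def remove_node(self, node_id: str) -> NodeRecord:
        node = self.node(node_id)
        for key in list(self._incident[node_id]):
            self._remove_edge_key(key)
        del self._incident[node_id]
        del self._nodes[node_id]
        return node

    def node(self, node_id: str) -> NodeRecord:
        try:
            return self._nodes[node_id]
        except KeyError:
            raise UnknownNodeError(f"unknown node id: {node_id!r}") from None

    def has_node(self, node_id: str) -> bool:
        return node_id in self._nodes

    @property
    def nodes(self) -> List[NodeRecord]:
        return list(self._nodes.values())

    def node_ids(self) -> List[str]:
        return list(self._nodes)

    def nodes_of_class(self, cls: NodeClass) -> List[NodeRecord]:
        return [n for n in self._nodes.values() if n.node_class == cls]

    # -- edges ---------------------------------------------------------

    def add_edge(
        self,
        source: str,
        target: str,
        role: EdgeRole | str,
        directed: bool = True,
        attributes: Optional[Dict[str, str]] = None,
    ) -> "Network":
        if isinstance(role, str):
            role = EdgeRole(role)
        if source == target:
            raise NetworkError(f"self-loop rejected on node {source!r}")
        if source not in self._nodes:
            raise UnknownNodeError(f"unknown node id: {source!r}")
        if target not in self._nodes:
            raise UnknownNodeError(f"unknown node id: {target!r}")
        attrs = tuple(sorted((attributes or {}).items()))
        edge = EdgeRecord(source, target, role, directed, attrs)
        self._edges[edge.key()] = edge  # identical triples collapse
        self._incident[source].add(edge.key())
        self._incident[target].add(edge.key())
        return self

    def _remove_edge_key(self, key: Tuple[str, str, str]) -> None:
        edge = self._edges.pop(key)
        self._incident[edge.source].discard(key)
        self._incident[edge.target].discard(key)

    def remove_edge(self, source: str, target: str, role: EdgeRole | str) -> None:
        if isinstance(role, str):
            role = EdgeRole(role)
        key = (source, target, role.value)
        if key not in self._edges:
            raise NetworkError(f"no such edge: {key}")
        self._remove_edge_key(key)

    @property
    def edges(self) -> List[EdgeRecord]:
        return list(self._edges.values())

    def incident_edges(self, node_id: str) -> List[EdgeRecord]:
        self.node(node_id)
        return [self._edges[k] for k in sorted(self._incident[node_id])]

    def degree(self, node_id: str) -> int:
        """Number of incident edges; each edge counts once regardless of direction."""
        self.node(node_id)
        return len(self._incident[node_id])

    def neighbors(
        self, node_id: str, role_filter: Optional[Iterable[EdgeRole | str]] = None
    ) -> Set[str]:
        """Adjacent node ids via edges matching ``role_filter`` (all roles if None)."""
        self.node(node_id)
        roles = None
        if role_filter is not None:
            roles = {EdgeRole(r) if isinstance(r, str) else r for r in role_filter}
        out: Set[str] = set()
        for key in self._incident[node_id]:
            edge = self._edges[key]
            if roles is None or edge.role in roles:
                out.add(edge.other(node_id))
        return out

    # -- counts & equality --------------------------------------------

    def n_nodes(self) -> int:
        return len(self._nodes)

    def n_edges(self) -> int:
        return len(self._edges)

    def __contains__(self, node_id: str) -> bool:
        return node_id in self._nodes

    def __iter__(self) -> Iterator[NodeRecord]:
        return iter(self._nodes.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Network):
            return NotImplemented
        if set(self._edges) != set(other._edges):
            return False
        for key, edge in self._edges.items():
            if other._edges[key] != edge:
                return False
        if set(self._nodes) != set(other._nodes):
            return False
        for nid, node in self._nodes.items():
            o = other._nodes[nid]
            if (
                node.label != o.label
                or node.node_class != o.node_class
                or node.compartment != o.compartment
                or node.subsystems != o.subsystems
                or node.sbo_term != o.sbo_term
                or node.attributes != o.attributes
                or node.duplication_group != o.duplication_group
            ):
                return False
        return True

    def copy(self, name: Optional[str] = None) -> "Network":
        out = Network(name if name is not None else self.name)
        for node in self._nodes.values():
            out.add_node(node.copy())
        for edge in self._edges.values():
            out.add_edge(
                edge.source, edge.target, edge.role, edge.directed, edge.attr_dict()
            )
        return out

    # -- validation ----------------------------------------------------

    def check_integrity(self) -> List[str]:
        """Full-scan referential integrity check; returns violation messages."""
        problems: List[str] = []
        for key, edge in self._edges.items():
            if edge.source not in self._nodes:
                problems.append(f"edge {key}: missing source node")
            if edge.target not in self._nodes:
                problems.append(f"edge {key}: missing target node")
            if edge.source == edge.target:
                problems.append(f"edge {key}: self-loop")
            if edge.role == EdgeRole.LINK:
                ok = any(
                    self._nodes.get(e) is not None
                    and self._nodes[e].node_class == NodeClass.LINKER
                    for e in (edge.source, edge.target)
                )
                if not ok:
                    problems.append(f"edge {key}: link role without linker endpoint")
        for nid, keys in self._incident.items():
            for key in keys:
                if key not in self._edges:
                    problems.append(f"stale incidence entry {key} on {nid!r}")
        return problems

    # -- group attribute access (used by subnetworks) ------------------

    def group_values(self, node_id: str, group_attribute: str) -> List[str]:
        """Grouping value(s) of a node: a field name or an attributes key."""
        node = self.node(node_id)
        if group_attribute == "subsystems":
            return [s for s in node.subsystems if s]
        if group_attribute == "compartment":
            return [node.compartment] if node.compartment else []
        value = node.attributes.get(group_attribute, "")
        return [v.strip() for v in value.split(";") if v.strip()] if value else []

    def __repr__(self) -> str:
        return (
            f"Network({self.name!r}, {self.n_nodes()} nodes, {self.n_edges()} edges)"
        )
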