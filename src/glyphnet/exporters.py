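"""Graph format exporters: GraphML, Cytoscape.js JSON (CYJS) and SIF.

GraphML serialisation goes through networkx; CYJS and SIF are written
directly.  All exporters flatten multi-valued fields into strings
(subsystems joined with ``";"``, with literal ``";"`` in names replaced
by ``","``) and both GraphML and CYJS round-trip a network exactly:
node count, edge count, classes and attributes are preserved.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple, Union

import networkx as nx

from .model import EdgeRole, Network, NetworkError, NodeClass, NodeRecord

__all__ = [
    "ExportBundle",
    "write_graphml",
    "read_graphml",
    "write_cyjs",
    "read_cyjs",
    "write_sif",
]

_ATTR_PREFIX = "attr_"


@dataclass
class ExportBundle:
    networks: List[Tuple[str, Network]]
    image_manifest: Optional[Dict[str, object]] = None
    attribute_schema: Dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        names = [name for name, _ in self.networks]
        if len(set(names)) != len(names):
            raise NetworkError("bundle network names must be unique")
        present = {
            key
            for _, net in self.networks
            for node in net.nodes
            for key in node.attributes
        }
        unused = set(self.attribute_schema) - present
        if unused:
            raise NetworkError(
                f"attribute schema names unused attributes: {sorted(unused)}"
            )


def _join_subsystems(subsystems: List[str]) -> str:
    return ";".join(s.replace(";", ",") for s in subsystems)


def _split_subsystems(raw: str) -> List[str]:
    return [p for p in raw.split(";") if p]


def _node_data(node: NodeRecord, image: Optional[str] = None) -> Dict[str, str]:
    data: Dict[str, str] = {
        "label": node.label,
        "node_class": node.node_class.value,
    }
    if node.compartment is not None:
        data["compartment"] = node.compartment
    if node.subsystems:
        data["subsystems"] = _join_subsystems(node.subsystems)
    if node.sbo_term is not None:
        data["sbo_term"] = node.sbo_term
    if node.duplication_group is not None:
        data["duplication_group"] = node.duplication_group
    if image is not None:
        data["image"] = image
    for key, value in node.attributes.items():
        data[_ATTR_PREFIX + key] = value
    return data


def _node_from_data(node_id: str, data: Dict[str, str]) -> NodeRecord:
    return NodeRecord(
        id=node_id,
        label=data.get("label", node_id),
        node_class=NodeClass(data.get("node_class", "other")),
        compartment=data.get("compartment"),
        subsystems=_split_subsystems(data.get("subsystems", "")),
        sbo_term=data.get("sbo_term"),
        duplication_group=data.get("duplication_group"),
        attributes={
            k[len(_ATTR_PREFIX):]: str(v)
            for k, v in data.items()
            if k.startswith(_ATTR_PREFIX)
        },
    )


def _image_for(node_id: str, manifest: Optional[Dict[str, object]]) -> Optional[str]:
    if not manifest:
        return None
    files = manifest.get("nodes", {}).get(node_id, [])
    return files[0] if files else None


def to_networkx(net: Network, manifest: Optional[Dict[str, object]] = None) -> nx.MultiDiGraph:
    graph = nx.MultiDiGraph(name=net.name)
    for node in net.nodes:
        graph.add_node(node.id, **_node_data(node, _image_for(node.id, manifest)))
    for edge in net.edges:
        attrs = {("e_" + k): v for k, v in edge.attr_dict().items()}
        graph.add_edge(
            edge.source,
            edge.target,
            key=edge.role.value,
            role=edge.role.value,
            directed=edge.directed,
            **attrs,
        )
    return graph


def from_networkx(graph: nx.MultiDiGraph, name: Optional[str] = None) -> Network:
    net = Network(name or graph.graph.get("name", "network"))
    for node_id, data in graph.nodes(data=True):
        net.add_node(_node_from_data(str(node_id), data))
    for source, target, data in graph.edges(data=True):
        net.add_edge(
            str(source),
            str(target),
            EdgeRole(data["role"]),
            bool(data.get("directed", True)),
            {k[2:]: str(v) for k, v in data.items() if k.startswith("e_")},
        )
    return net


BundleOrNet = Union[ExportBundle, Network]


def _as_bundle(obj: BundleOrNet) -> ExportBundle:
    if isinstance(obj, Network):
        return ExportBundle(networks=[(obj.name, obj)])
    obj.validate()
    return obj


def write_graphml(bundle: BundleOrNet, path: str) -> List[str]:
    """Write GraphML with typed keys.

    A single Network writes one file at ``path``; a multi-network bundle
    treats ``path`` as a directory and writes ``<name>.graphml`` per
    member.  Returns the written paths.
    """
    bundle = _as_bundle(bundle)
    if len(bundle.networks) == 1 and not os.path.isdir(path) and path.endswith(".graphml"):
        name, net = bundle.networks[0]
        nx.write_graphml(to_networkx(net, bundle.image_manifest), path)
        return [path]
    os.makedirs(path, exist_ok=True)
    written = []
    for name, net in bundle.networks:
        target = os.path.join(path, f"{name.replace(os.sep, '_').replace(' ', '_')}.graphml")
        nx.write_graphml(to_networkx(net, bundle.image_manifest), target)
        written.append(target)
    return written


def read_graphml(path: str, name: Optional[str] = None) -> Network:
    graph = nx.read_graphml(path, force_multigraph=True)
    return from_networkx(graph, name or os.path.basename(path).rsplit(".", 1)[0])


def write_cyjs(bundle: BundleOrNet, path: str) -> List[str]:
    """Write Cytoscape.js JSON (elements.nodes / elements.edges data maps)."""
    bundle = _as_bundle(bundle)

    def _write_one(name: str, net: Network, target: str) -> None:
        nodes = []
        for node in net.nodes:
            data = {"id": node.id, **_node_data(node, _image_for(node.id, bundle.image_manifest))}
            nodes.append({"data": data})
        edges = []
        for edge in net.edges:
            data = {
                "id": f"{edge.source}|{edge.role.value}|{edge.target}",
                "source": edge.source,
                "target": edge.target,
                "role": edge.role.value,
                "directed": edge.directed,
            }
            data.update({("e_" + k): v for k, v in edge.attr_dict().items()})
            edges.append({"data": data})
        doc = {
            "format_version": "1.0",
            "data": {"name": name},
            "elements": {"nodes": nodes, "edges": edges},
        }
        with open(target, "w") as handle:
            json.dump(doc, handle, indent=1, sort_keys=True)

    if len(bundle.networks) == 1 and path.endswith(".cyjs"):
        name, net = bundle.networks[0]
        _write_one(name, net, path)
        return [path]
    os.makedirs(path, exist_ok=True)
    written = []
    for name, net in bundle.networks:
        target = os.path.join(path, f"{name.replace(os.sep, '_').replace(' ', '_')}.cyjs")
        _write_one(name, net, target)
        written.append(target)
    return written


def read_cyjs(path: str) -> Network:
    with open(path) as handle:
        doc = json.load(handle)
    net = Network(doc.get("data", {}).get("name", "network"))
    for element in doc["elements"]["nodes"]:
        data = dict(element["data"])
        node_id = data.pop("id")
        net.add_node(_node_from_data(node_id, data))
    for element in doc["elements"].get("edges", []):
        data = dict(element["data"])
        net.add_edge(
            data["source"],
            data["target"],
            EdgeRole(data["role"]),
            bool(data.get("directed", True)),
            {k[2:]: str(v) for k, v in data.items() if k.startswith("e_")},
        )
    return net


def write_sif(net: Network, path: str) -> str:
    """Write SIF: one ``source<TAB>role<TAB>target`` line per edge;
    isolated nodes are listed alone on their own line."""
    for node_id in net.node_ids():
        if "\t" in node_id:
            raise NetworkError(f"node id contains a tab: {node_id!r}")
    lines = []
    connected = set()
    for edge in sorted(net.edges, key=lambda e: e.key()):
        lines.append(f"{edge.source}\t{edge.role.value}\t{edge.target}")
        connected.update((edge.source, edge.target))
    for node_id in sorted(set(net.node_ids()) - connected):
        lines.append(node_id)
    with open(path, "w") as handle:
        handle.write("\n".join(lines) + ("\n" if lines else ""))
    return path
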