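"""SBML import and annotation into a typed :class:`~glyphnet.model.Network`.

Reads SBML Level 2 (COBRA notes dialect) and Level 3 (+fbc) metabolic
models, then materialises the annotation layers that standard network
imports leave behind:

* COBRA-style notes (``GENE_ASSOCIATION``, ``SUBSYSTEM`` and other
  ``TAG: value`` lines stored in species/reaction ``<notes>`` elements),
* SBO-term / biological-qualifier species classification (enzymes and
  polypeptide chains become protein nodes),
* explicit gene nodes wired to reactions (via GPR rules) and to proteins
  (via ``isEncodedBy`` annotations).

fbc ``geneProductAssociation`` elements are translated into the same
boolean GPR trees as note strings, so downstream code sees one dialect.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Set

import libsbml

from .gpr import BoolOp, Gene, GprError, GprExpression, parse_gpr, serialize_gpr
from .model import EdgeRole, Network, NodeClass, NodeRecord

__all__ = [
    "CobraNotes",
    "SpeciesClassificationRule",
    "SbmlReadError",
    "read_sbml",
    "extract_cobra_notes",
    "classify_species",
    "attach_genes",
    "extract_subsystems",
    "annotate_sbml",
]

logger = logging.getLogger(__name__)


class SbmlReadError(ValueError):
    pass


@dataclass
class CobraNotes:
    """Parsed COBRA-style note lines. Absent tags stay ``None`` / empty."""

    gene_association: Optional[str] = None
    subsystem: Optional[List[str]] = None
    other: Dict[str, str] = field(default_factory=dict)


@dataclass
class SpeciesClassificationRule:
    """Which annotations mark a species as a protein.

    SBO:0000014 (enzyme) and SBO:0000252 (polypeptide chain) are the
    defaults; a species carrying a biological qualifier ``isEncodedBy``
    is also classified as protein.
    """

    protein_sbo_terms: Set[str] = field(
        default_factory=lambda: {"SBO:0000014", "SBO:0000252"}
    )
    encoded_by_qualifier: str = "isEncodedBy"

    def matches_sbo(self, term: Optional[str]) -> bool:
        if not term:
            return False
        digits = term.split(":")[-1].strip()
        wanted = {t.split(":")[-1] for t in self.protein_sbo_terms}
        return digits in wanted


_TAG_RE = re.compile(r"<[^>]+>")


def _strip_markup(text: str) -> List[str]:
    """Flatten notes XHTML into text lines (paragraph tags become breaks)."""
    text = re.sub(r"(?i)</(?:[a-z]+:)?(?:p|div|br)\s*>|<(?:[a-z]+:)?br\s*/?>", "\n", text)
    text = _TAG_RE.sub("", text)
    return [line.strip() for line in text.splitlines() if line.strip()]


def extract_cobra_notes(notes_text: str) -> CobraNotes:
    """Parse ``TAG: value`` lines from the body of an SBML ``<notes>`` element.

    ``GENE_ASSOCIATION`` (or ``GENE ASSOCIATION``) feeds
    :attr:`CobraNotes.gene_association`; ``SUBSYSTEM`` is split on ``";"``
    and trimmed; every other tag lands, upper-cased, in
    :attr:`CobraNotes.other`.  Tag matching is case-insensitive and the
    first matching line wins.  Unparseable lines are ignored and logged.
    """
    notes = CobraNotes()
    if not notes_text:
        return notes
    for line in _strip_markup(notes_text):
        if ":" not in line:
            logger.debug("ignoring unparseable note line: %r", line)
            continue
        tag, _, value = line.partition(":")
        tag = tag.strip().upper()
        value = value.strip()
        if not tag:
            logger.debug("ignoring unparseable note line: %r", line)
            continue
        if tag in ("GENE_ASSOCIATION", "GENE ASSOCIATION"):
            if notes.gene_association is None and value:
                notes.gene_association = value
        elif tag == "SUBSYSTEM":
            if notes.subsystem is None and value:
                notes.subsystem = [p.strip() for p in value.split(";") if p.strip()]
        else:
            notes.other.setdefault(tag, value)
    return notes


def _encoded_by_genes(element) -> List[str]:
    """Gene tokens referenced by biological-qualifier isEncodedBy CVTerms."""
    genes: List[str] = []
    for i in range(element.getNumCVTerms()):
        cv = element.getCVTerm(i)
        if cv.getQualifierType() != libsbml.BIOLOGICAL_QUALIFIER:
            continue
        if cv.getBiologicalQualifierType() != libsbml.BQB_IS_ENCODED_BY:
            continue
        for j in range(cv.getNumResources()):
            uri = cv.getResourceURI(j)
            token = uri.rstrip("/").rsplit("/", 1)[-1].rsplit(":", 1)[-1]
            if token:
                genes.append(token)
    return genes


def _fbc_association_to_gpr(assoc, fbc_model) -> Optional[GprExpression]:
    """Translate an fbc association tree into a GprExpression."""
    if assoc is None:
        return None
    if assoc.isFbcAnd() or assoc.isFbcOr():
        children = []
        for i in range(assoc.getNumAssociations()):
            child = _fbc_association_to_gpr(assoc.getAssociation(i), fbc_model)
            if child is not None:
                children.append(child)
        if not children:
            return None
        if len(children) == 1:
            return children[0]
        return BoolOp("AND" if assoc.isFbcAnd() else "OR", tuple(children))
    if assoc.isGeneProductRef():
        ref = assoc.getGeneProduct()
        gp = fbc_model.getGeneProduct(ref) if fbc_model is not None else None
        label = gp.getLabel() if gp is not None and gp.isSetLabel() else ""
        return Gene(label or ref)
    return None


def read_sbml(path: str) -> Network:
    """Read an SBML Level 2/3 file into a Network.

    Produces one species node per SBML species, one reaction node per
    reaction, and substrate/product/modifier edges per species reference.
    Compartments, SBO terms, COBRA note tags and fbc gene associations
    are captured into node fields/attributes; stoichiometric coefficients
    are stored as an edge attribute string and never computed on.
    """
    doc = libsbml.readSBMLFromFile(str(path))
    for i in range(doc.getNumErrors()):
        err = doc.getError(i)
        if err.getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
            raise SbmlReadError(
                f"SBML parse error at line {err.getLine()}: {err.getMessage().strip()}"
            )
    model = doc.getModel()
    if model is None:
        raise SbmlReadError(f"no model element found in {path}")
    if doc.getLevel() not in (2, 3):
        raise SbmlReadError(f"unsupported SBML level {doc.getLevel()} (need 2 or 3)")

    net = Network(model.getId() or model.getName() or "sbml_model")
    fbc_model = model.getPlugin("fbc")

    for sp in model.getListOfSpecies():
        node = NodeRecord(
            id=sp.getId(),
            label=sp.getName() or sp.getId(),
            node_class=NodeClass.SPECIES,
            compartment=sp.getCompartment() or None,
            sbo_term=sp.getSBOTermID() if sp.isSetSBOTerm() else None,
        )
        if sp.isSetNotes():
            notes = extract_cobra_notes(sp.getNotesString())
            node.attributes.update(notes.other)
        encoded_by = _encoded_by_genes(sp)
        if encoded_by:
            node.attributes["encoded_by"] = ";".join(encoded_by)
        net.add_node(node)

    for rxn in model.getListOfReactions():
        node = NodeRecord(
            id=rxn.getId(),
            label=rxn.getName() or rxn.getId(),
            node_class=NodeClass.REACTION,
            sbo_term=rxn.getSBOTermID() if rxn.isSetSBOTerm() else None,
        )
        if rxn.isSetNotes():
            notes = extract_cobra_notes(rxn.getNotesString())
            if notes.gene_association:
                node.attributes["gene_association"] = notes.gene_association
            if notes.subsystem:
                node.attributes["cobra_subsystem"] = ";".join(notes.subsystem)
            node.attributes.update(notes.other)
        rplug = rxn.getPlugin("fbc")
        if rplug is not None and rplug.isSetGeneProductAssociation():
            tree = _fbc_association_to_gpr(
                rplug.getGeneProductAssociation().getAssociation(), fbc_model
            )
            if tree is not None and "gene_association" not in node.attributes:
                node.attributes["gene_association"] = serialize_gpr(tree)
        net.add_node(node)

        for ref in rxn.getListOfReactants():
            net.add_edge(
                ref.getSpecies(),
                rxn.getId(),
                EdgeRole.SUBSTRATE,
                attributes={"stoichiometry": repr(ref.getStoichiometry())},
            )
        for ref in rxn.getListOfProducts():
            net.add_edge(
                rxn.getId(),
                ref.getSpecies(),
                EdgeRole.PRODUCT,
                attributes={"stoichiometry": repr(ref.getStoichiometry())},
            )
        for ref in rxn.getListOfModifiers():
            net.add_edge(ref.getSpecies(), rxn.getId(), EdgeRole.MODIFIER)

    return net


def classify_species(
    net: Network, rules: Optional[SpeciesClassificationRule] = None
) -> Network:
    """Reclassify species nodes as proteins by SBO term or isEncodedBy.

    Species whose SBO term is in the rule set (enzyme/polypeptide chain),
    or that carry an ``isEncodedBy`` qualifier annotation, get
    ``node_class=protein``; modifier edges from a protein to a reaction
    are retyped as ``catalyzes``.  Reaction and gene nodes are untouched.
    """
    rules = rules or SpeciesClassificationRule()
    proteins: Set[str] = set()
    for node in net.nodes_of_class(NodeClass.SPECIES):
        if rules.matches_sbo(node.sbo_term) or "encoded_by" in node.attributes:
            node.node_class = NodeClass.PROTEIN
            proteins.add(node.id)
    for node in net.nodes_of_class(NodeClass.PROTEIN):
        proteins.add(node.id)
    for edge in list(net.edges):
        if edge.role == EdgeRole.MODIFIER and edge.source in proteins:
            if net.node(edge.target).node_class == NodeClass.REACTION:
                net.remove_edge(edge.source, edge.target, edge.role)
                net.add_edge(
                    edge.source,
                    edge.target,
                    EdgeRole.CATALYZES,
                    edge.directed,
                    edge.attr_dict(),
                )
    return net


def _gene_node_id(token: str) -> str:
    # "gene:" namespace prevents collision with species ids sharing the token
    return f"gene:{token}"


def _ensure_gene_node(net: Network, token: str) -> str:
    gid = _gene_node_id(token)
    if not net.has_node(gid):
        net.add_node(NodeRecord(id=gid, label=token, node_class=NodeClass.GENE))
    return gid


def attach_genes(net: Network) -> Network:
    """Materialise gene nodes from GPR rules and isEncodedBy references.

    One gene node per unique gene token across all GPRs; each reaction
    with a GPR gains a ``gpr`` edge from every leaf gene and an attribute
    ``gpr`` holding the serialised expression.  Proteins with
    ``encoded_by`` references gain ``encodes`` edges from the referenced
    genes.  Reactions with unparseable GPRs are skipped; each failure is
    logged and the total failure count is reported in a summary warning.
    Idempotent: a second application changes nothing.
    """
    n_errors = 0
    for node in net.nodes_of_class(NodeClass.REACTION):
        raw = node.attributes.get("gene_association")
        if not raw:
            continue
        try:
            tree = parse_gpr(raw)
        except GprError as exc:
            n_errors += 1
            logger.warning("skipping reaction %s: bad GPR %r (%s)", node.id, raw, exc)
            continue
        node.attributes["gpr"] = serialize_gpr(tree)
        for token in sorted(set(tree.leaves())):
            gid = _ensure_gene_node(net, token)
            net.add_edge(gid, node.id, EdgeRole.GPR, directed=False)
    for node in net.nodes_of_class(NodeClass.PROTEIN):
        encoded = node.attributes.get("encoded_by", "")
        for token in [t for t in encoded.split(";") if t]:
            gid = _ensure_gene_node(net, token)
            net.add_edge(gid, node.id, EdgeRole.ENCODES, directed=False)
    if n_errors:
        logger.warning("attach_genes: %d reaction(s) skipped due to GPR errors", n_errors)
    return net


def extract_subsystems(net: Network) -> Network:
    """Populate ``reaction.subsystems`` from COBRA SUBSYSTEM notes.

    Reactions without a SUBSYSTEM note keep an empty list.
    """
    for node in net.nodes_of_class(NodeClass.REACTION):
        raw = node.attributes.get("cobra_subsystem", "")
        if raw:
            node.subsystems = [p.strip() for p in raw.split(";") if p.strip()]
    return net


def annotate_sbml(path: str, rules: Optional[SpeciesClassificationRule] = None) -> Network:
    """Full annotation pipeline: read, classify, attach genes, extract subsystems."""
    net = read_sbml(path)
    classify_species(net, rules)
    attach_genes(net)
    extract_subsystems(net)
    return net
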