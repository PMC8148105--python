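"""Synthetic SBML models and omics tables with known ground truth.

Every capability of the package is testable without downloading a real
genome-scale model: this module writes small (or paper-scale) SBML
files whose pathway structure, gene associations, shared metabolites
and co-factor hubs are recorded as ground truth, plus matching omics
CSV tables with known value matrices.

The generated models emulate the skeleton of a bacterial core
metabolic network: each pathway is a linear reaction chain over its own
metabolites, pathway pairs share a configurable number of junction
metabolites (the future linker anchors), and a few co-factor species
attach to a fraction of all reactions to create realistic hubs.
Reactions carry COBRA-style notes (``SUBSYSTEM``, ``GENE_ASSOCIATION``
with random and/or trees over a shared gene pool).  All randomness is
driven by the spec's seed; the same seed yields byte-identical files.
"""

from __future__ import annotations

import csv
import json
import os
import random
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set, Tuple

import libsbml

from .gpr import BoolOp, Gene, GprExpression, serialize_gpr
from .model import Network

__all__ = [
    "ToyModelSpec",
    "GroundTruth",
    "generate_toy_sbml",
    "generate_omics_tables",
    "generate_annotated_species_sbml",
    "three_pathway_spec",
    "paper_scale_spec",
]


@dataclass
class ToyModelSpec:
    n_pathways: int = 3
    reactions_per_pathway: int = 5
    shared_metabolites_per_pathway_pair: int = 1
    n_cofactors: int = 2
    genes_per_reaction: Tuple[int, int] = (1, 3)
    seed: int = 42
    # extras beyond the core knobs
    cofactor_fraction: float = 0.6  # fraction of reactions each co-factor touches
    gene_pool_size: Optional[int] = None  # default: max(3, n_reactions)
    pathway_names: Optional[List[str]] = None

    def __post_init__(self) -> None:
        if min(
            self.n_pathways,
            self.reactions_per_pathway,
            self.shared_metabolites_per_pathway_pair,
            self.n_cofactors,
        ) < 0:
            raise ValueError("all counts must be >= 0")
        if self.n_pathways < 1 or self.reactions_per_pathway < 1:
            raise ValueError("need at least one pathway with one reaction")

    @property
    def names(self) -> List[str]:
        if self.pathway_names is not None:
            if len(self.pathway_names) != self.n_pathways:
                raise ValueError("pathway_names length must equal n_pathways")
            return list(self.pathway_names)
        return [f"Pathway_{i + 1}" for i in range(self.n_pathways)]


@dataclass
class GroundTruth:
    n_species: int
    n_reactions: int
    pathway_of: Dict[str, str]  # reaction id -> pathway name
    gene_map: Dict[str, List[str]]  # reaction id -> sorted gene tokens
    gpr_of: Dict[str, str]  # reaction id -> GPR string as written
    cofactor_ids: List[str]
    shared_metabolites: Dict[str, List[str]]  # "P1|P2" -> metabolite ids
    edges: List[Tuple[str, str, str]]  # (source, target, role) species<->reaction
    unique_genes: List[str]

    def expected_degree(self, node_id: str) -> int:
        return sum(1 for s, t, _ in self.edges if node_id in (s, t))

    def to_json(self, path: str) -> None:
        with open(path, "w") as handle:
            json.dump(
                {
                    "n_species": self.n_species,
                    "n_reactions": self.n_reactions,
                    "pathway_of": self.pathway_of,
                    "gene_map": self.gene_map,
                    "gpr_of": self.gpr_of,
                    "cofactor_ids": self.cofactor_ids,
                    "shared_metabolites": self.shared_metabolites,
                    "edges": self.edges,
                    "unique_genes": self.unique_genes,
                },
                handle,
                indent=1,
                sort_keys=True,
            )


def _random_gpr(tokens: List[str], rng: random.Random) -> GprExpression:
    if len(tokens) == 1:
        return Gene(tokens[0])
    cut = rng.randint(1, len(tokens) - 1)
    left = _random_gpr(tokens[:cut], rng)
    right = _random_gpr(tokens[cut:], rng)
    return BoolOp(rng.choice(("AND", "OR")), (left, right))


def _notes_xhtml(lines: List[str]) -> str:
    body = "".join(f"<p>{line}</p>" for line in lines)
    return f'<body xmlns="http://www.w3.org/1999/xhtml">{body}</body>'


def _check(code: int, what: str) -> None:
    if code != libsbml.LIBSBML_OPERATION_SUCCESS:
        raise RuntimeError(f"libsbml refused to {what} (code {code})")


def generate_toy_sbml(spec: ToyModelSpec, path: str) -> Tuple[str, GroundTruth]:
    """Write a synthetic COBRA-notes SBML model; return (path, ground truth)."""
    rng = random.Random(spec.seed)
    names = spec.names

    doc = libsbml.SBMLDocument(2, 4)
    model = doc.createModel()
    model.setId("toy_model")
    comp = model.createCompartment()
    comp.setId("c")
    comp.setSize(1.0)

    species_ids: List[str] = []

    def add_species(sid: str, name: str) -> None:
        sp = model.createSpecies()
        _check(sp.setId(sid), f"set species id {sid}")
        sp.setName(name)
        sp.setCompartment("c")
        sp.setInitialConcentration(1.0)
        species_ids.append(sid)

    # per-pathway metabolite chains
    chain_mets: Dict[int, List[str]] = {}
    for p in range(spec.n_pathways):
        mets = [f"m_p{p + 1}_{j}" for j in range(spec.reactions_per_pathway + 1)]
        chain_mets[p] = mets
        for m in mets:
            add_species(m, m)

    # shared junction metabolites per pathway pair
    shared: Dict[str, List[str]] = {}
    for p in range(spec.n_pathways):
        for q in range(p + 1, spec.n_pathways):
            ids = [
                f"s_p{p + 1}p{q + 1}_{i}"
                for i in range(spec.shared_metabolites_per_pathway_pair)
            ]
            shared[f"{names[p]}|{names[q]}"] = ids
            for sid in ids:
                add_species(sid, sid)

    cofactors = [f"cof_{i + 1}" for i in range(spec.n_cofactors)]
    for sid in cofactors:
        add_species(sid, sid)

    n_reactions = spec.n_pathways * spec.reactions_per_pathway
    pool_size = spec.gene_pool_size or max(3, n_reactions)
    gene_pool = [f"g{i + 1:04d}" for i in range(pool_size)]

    edges: List[Tuple[str, str, str]] = []
    edge_set: Set[Tuple[str, str, str]] = set()

    def record(source: str, target: str, role: str) -> None:
        key = (source, target, role)
        if key not in edge_set:
            edge_set.add(key)
            edges.append(key)

    pathway_of: Dict[str, str] = {}
    gene_map: Dict[str, List[str]] = {}
    gpr_of: Dict[str, str] = {}
    reaction_ids: List[str] = []
    substrates: Dict[str, List[str]] = {}
    products: Dict[str, List[str]] = {}

    for p in range(spec.n_pathways):
        for j in range(spec.reactions_per_pathway):
            rid = f"r_p{p + 1}_{j + 1}"
            reaction_ids.append(rid)
            pathway_of[rid] = names[p]
            substrates[rid] = [chain_mets[p][j]]
            products[rid] = [chain_mets[p][j + 1]]
            lo, hi = spec.genes_per_reaction
            k = rng.randint(lo, hi) if hi >= lo and hi > 0 else 0
            if k > 0:
                tokens = rng.sample(gene_pool, min(k, len(gene_pool)))
                tree = _random_gpr(tokens, rng)
                gene_map[rid] = sorted(set(tokens))
                gpr_of[rid] = serialize_gpr(tree)

    # wire shared metabolites: product of a reaction in p, substrate in q
    for p in range(spec.n_pathways):
        for q in range(p + 1, spec.n_pathways):
            for sid in shared[f"{names[p]}|{names[q]}"]:
                rp = f"r_p{p + 1}_{rng.randint(1, spec.reactions_per_pathway)}"
                rq = f"r_p{q + 1}_{rng.randint(1, spec.reactions_per_pathway)}"
                products[rp].append(sid)
                substrates[rq].append(sid)

    # co-factor hubs touch a seeded fraction of all reactions
    for cof in cofactors:
        k = max(1, round(spec.cofactor_fraction * n_reactions))
        for rid in rng.sample(reaction_ids, min(k, n_reactions)):
            substrates[rid].append(cof)

    for rid in reaction_ids:
        rxn = model.createReaction()
        _check(rxn.setId(rid), f"set reaction id {rid}")
        rxn.setName(rid)
        rxn.setReversible(False)
        for sid in substrates[rid]:
            ref = rxn.createReactant()
            ref.setSpecies(sid)
            ref.setStoichiometry(1.0)
            record(sid, rid, "substrate")
        for sid in products[rid]:
            ref = rxn.createProduct()
            ref.setSpecies(sid)
            ref.setStoichiometry(1.0)
            record(rid, sid, "product")
        lines = [f"SUBSYSTEM: {pathway_of[rid]}"]
        if rid in gpr_of:
            lines.insert(0, f"GENE_ASSOCIATION: {gpr_of[rid]}")
        _check(rxn.setNotes(_notes_xhtml(lines)), f"set notes on {rid}")

    libsbml.writeSBMLToFile(doc, str(path))
    truth = GroundTruth(
        n_species=len(species_ids),
        n_reactions=n_reactions,
        pathway_of=pathway_of,
        gene_map=gene_map,
        gpr_of=gpr_of,
        cofactor_ids=cofactors,
        shared_metabolites=shared,
        edges=edges,
        unique_genes=sorted({g for gs in gene_map.values() for g in gs}),
    )
    return str(path), truth


def generate_annotated_species_sbml(path: str) -> str:
    """Write a small model exercising the protein classification rules:
    one enzyme (SBO:0000014), one polypeptide chain (SBO:0000252), one
    species with an isEncodedBy qualifier, one plain metabolite, and a
    reaction each protein modifies."""
    doc = libsbml.SBMLDocument(2, 4)
    model = doc.createModel()
    model.setId("annotated_species")
    comp = model.createCompartment()
    comp.setId("c")
    comp.setSize(1.0)

    def add_species(sid: str, sbo: Optional[int] = None, encoded_by: Optional[str] = None):
        sp = model.createSpecies()
        sp.setId(sid)
        sp.setName(sid)
        sp.setCompartment("c")
        sp.setInitialConcentration(1.0)
        if sbo is not None:
            sp.setSBOTerm(sbo)
        if encoded_by is not None:
            sp.setMetaId(f"meta_{sid}")
            cv = libsbml.CVTerm()
            cv.setQualifierType(libsbml.BIOLOGICAL_QUALIFIER)
            cv.setBiologicalQualifierType(libsbml.BQB_IS_ENCODED_BY)
            cv.addResource(f"http://identifiers.org/ncbigene/{encoded_by}")
            _check(sp.addCVTerm(cv), f"add CVTerm on {sid}")
        return sp

    add_species("enzyme_a", sbo=14)
    add_species("peptide_b", sbo=252)
    add_species("protein_c", encoded_by="b0099")
    add_species("metabolite_d", sbo=247)  # simple chemical: must stay species
    add_species("substrate_x")
    add_species("product_y")

    rxn = model.createReaction()
    rxn.setId("r_demo")
    rxn.setReversible(False)
    ref = rxn.createReactant()
    ref.setSpecies("substrate_x")
    ref.setStoichiometry(1.0)
    ref = rxn.createProduct()
    ref.setSpecies("product_y")
    ref.setStoichiometry(1.0)
    for modifier in ("enzyme_a", "peptide_b", "protein_c", "metabolite_d"):
        mod = rxn.createModifier()
        mod.setSpecies(modifier)
    rxn.setNotes(_notes_xhtml(["GENE_ASSOCIATION: b0001 or b0002", "SUBSYSTEM: Demo"]))

    libsbml.writeSBMLToFile(doc, str(path))
    return str(path)


def generate_omics_tables(
    net: Network,
    n_datasets: int,
    coverage_fraction: float,
    n_columns: int,
    seed: int,
    out_dir: str,
    missing_rate: float = 0.05,
    node_ids: Optional[Sequence[str]] = None,
) -> Tuple[List[str], Dict[str, Dict[str, List[float]]]]:
    """Write CSV omics tables over a seeded random node subset.

    Each dataset covers ``round(coverage_fraction * n)`` nodes drawn
    independently per dataset; values are standard Gaussian with
    missing cells injected at ``missing_rate``.  Returns the written
    paths and the exact value matrices (NaN marks missing) as ground
    truth.
    """
    if not 0 < coverage_fraction <= 1:
        raise ValueError("coverage_fraction must be in (0, 1]")
    rng = random.Random(seed)
    os.makedirs(out_dir, exist_ok=True)
    candidates = sorted(node_ids if node_ids is not None else net.node_ids())
    n_rows = round(coverage_fraction * len(candidates))
    headers = [f"t{i}" for i in range(n_columns)]
    paths: List[str] = []
    truth: Dict[str, Dict[str, List[float]]] = {}
    for d in range(n_datasets):
        ds_id = f"ds{d + 1}"
        chosen = sorted(rng.sample(candidates, n_rows))
        matrix: Dict[str, List[float]] = {}
        for nid in chosen:
            row = [
                float("nan") if rng.random() < missing_rate else rng.gauss(0.0, 1.0)
                for _ in range(n_columns)
            ]
            matrix[nid] = row
        # guarantee at least one observed value per table
        if not any(v == v for row in matrix.values() for v in row) and matrix:
            first = next(iter(matrix))
            matrix[first][0] = rng.gauss(0.0, 1.0)
        path = os.path.join(out_dir, f"{ds_id}.csv")
        with open(path, "w", newline="") as handle:
            writer = csv.writer(handle)
            writer.writerow(["id"] + headers)
            for nid in chosen:
                writer.writerow(
                    [nid] + [("" if v != v else repr(v)) for v in matrix[nid]]
                )
        paths.append(path)
        truth[ds_id] = matrix
    return paths, truth


def three_pathway_spec(seed: int = 42) -> ToyModelSpec:
    """A small three-pathway model emulating the central-carbon demo:
    glycolysis/TCA/PPP analogues joined by two shared junction
    metabolites per pathway pair, with two co-factor hubs.  Two shared
    metabolites keep every pathway pair linked even when one junction is
    declared non-linking (the NADPH scenario)."""
    return ToyModelSpec(
        n_pathways=3,
        reactions_per_pathway=5,
        shared_metabolites_per_pathway_pair=2,
        n_cofactors=2,
        genes_per_reaction=(1, 3),
        seed=seed,
        pathway_names=["Glycolysis", "Citric Acid Cycle", "Pentose Phosphate Pathway"],
    )


def paper_scale_spec(seed: int = 42) -> ToyModelSpec:
    """Parameters sized to a genome-scale network of roughly 10,000
    nodes and 25,000 edges once gene nodes are attached (~4,000
    reactions, ~4,600 species, ~1,500 genes)."""
    return ToyModelSpec(
        n_pathways=25,
        reactions_per_pathway=160,
        shared_metabolites_per_pathway_pair=2,
        n_cofactors=10,
        genes_per_reaction=(1, 2),
        seed=seed,
        cofactor_fraction=0.15,
        gene_pool_size=1500,
    )
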