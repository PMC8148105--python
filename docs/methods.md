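# Methods

This note documents the models and procedures implemented in
`glyphnet`, the defaults that matter, what the synthetic generators do
and do not emulate, and the design choices made where the design was
genuinely open.

## Network model

The core container is a typed multi-partite graph. Nodes are species,
reactions, genes, proteins or linker placeholders; edges carry a
biochemical role (substrate, product, modifier, catalyzes, encodes,
gpr, link). Identifiers are case-sensitive and matched exactly — silent
namespace normalisation is a classic source of wrong data mappings.
Parallel edges with distinct roles are allowed (a metabolite can be
substrate *and* product of one reaction, as SBML's listOfReactants /
listOfProducts permit); identical (source, target, role) triples
collapse. Direction is stored but degree, adjacency and the subnetwork
logic treat the graph as undirected: the decomposition serves visual
navigation, where an edge is traversable either way. Stoichiometric
coefficients are kept only as edge-attribute strings; no flux-balance
semantics are computed.

`subsystems` is list-valued: a reaction may belong to several pathways,
and each listed value is treated independently by the grouping logic.

## SBML annotation

SBML Level 2 (COBRA notes dialect) and Level 3 (+fbc) are read through
libsbml. COBRA notes are parsed from the XHTML note bodies as
`TAG: value` lines; tag matching is case-insensitive, both
`GENE_ASSOCIATION` and `GENE ASSOCIATION` are accepted, the first
matching line wins, and `SUBSYSTEM` values split on `";"`. fbc
`geneProductAssociation` trees are translated into the same boolean GPR
representation, so downstream code sees a single dialect.

GPR expressions are parsed by a recursive-descent grammar with
precedence parentheses > AND > OR; keywords match case-insensitively
and `&&`/`||` are accepted, while gene tokens keep their case. The
boolean semantics (AND = complex, OR = isoenzymes) are recorded but
never evaluated: visualisation needs the gene set and the edges, not a
truth value. Serialisation parenthesises every nested operator, which
makes the round trip `parse ∘ serialize` the identity on trees without
relying on precedence conventions.

Species classification: a species becomes a protein node if its SBO
term is 0000014 (enzyme) or 0000252 (polypeptide chain) — matching
compares the 7-digit numeric part, so `SBO:0000014` and bare `0000014`
agree — or if it carries a biological qualifier `isEncodedBy`
annotation. Modifier edges from proteins to reactions are retyped
`catalyzes`. Gene nodes live in the id namespace `gene:<token>` to
avoid collisions with species sharing the token; the displayed label is
the bare token. `attach_genes` is idempotent and skips (with a logged
warning) reactions whose GPR fails to parse.

## Subnetwork decomposition

Given a bipartition (member class with the grouping attribute, bridge
class spanning groups), the split builds, per group value *v*:

1. all member nodes carrying *v* (members with several group values are
   copied into each; members with none are pooled into
   `"(unassigned)"` rather than dropped, which would silently violate
   edge conservation);
2. a local copy of every non-removed bridge node adjacent to one of
   them, with its edges into the group — local copies keep each pathway
   view self-contained;
3. companion gene/protein nodes adjacent to included nodes (two passes,
   so genes of included proteins follow); companions never generate
   linkers;
4. one linker node per (bridge, foreign group) adjacency for bridges
   that are neither non-linking nor duplication replicates, attached to
   its anchor by a `link` edge.

Per-anchor linkers are the default because they preserve *where*
connectivity leaves the pathway; a `collapse_linkers` flag merges them
into one linker per target group. Linker ids derive from sorted
(anchor, target) pairs, and groups are processed in sorted order, so
the decomposition is deterministic. Degenerate configurations (all
bridges removed) are legal and yield disconnected islands with no
linkers.

`validate_split` re-derives the expected membership, conserved edges
and linker set directly from these definitions and reports violations;
`subnetwork_graph` builds the navigation meta-graph (one node per
subnetwork, one edge per linked group pair, anchors recorded on the
edge).

Suggestions for the removed / non-linking sets are connectivity-based:
bridge nodes with degree ≥ `max(30, P98)` of the bridge degree
distribution are removal candidates, those between `max(8, P90)` and
the removal threshold are non-linking candidates. The exact heuristic
used by earlier interactive tools is not published; this percentile
rule is this package's documented choice, and both thresholds are
overridable.

## Hub duplication

`duplicate_node` replaces a node by replicates `<id>#k` (k in
sorted-edge order), either one per incident edge (default — maximal
hairball removal) or one per distinct neighbour (keeps
substrate+modifier parallel edges together). Replicates carry
`duplication_group` and `data_id` = the original id, so omics data maps
onto every replicate without touching the dataset, attribute updates
propagate group-wide, and the subnetwork logic treats them as
non-branching. The duplication record stores the original node and the
exact edge assignment, so `remerge` restores the graph exactly
(verified as graph equality including attributes).

## Omics data and node types

Tables (CSV/TSV/XLSX; first sheet unless named) must have an id column
and numeric value columns; empty cells are missing values; duplicate
ids and non-numeric cells are hard errors with row/column context. The
decimal separator is fixed to `"."` — thousands separators are rejected
rather than silently misparsed.

A node's *node type* is the set of datasets with at least one observed
value for it. `uniform` mode (default) puts all datasets in one
signature whose members are all nodes with any data — missing data
renders blank, keeping the representation consistent. `per_subset` mode
creates one signature per distinct presence pattern, partitioning the
data-bearing nodes. Nodes without any data get no image. Dataset order
everywhere is registration order, which fixes glyph layouts and legend
order deterministically.

Default colour scale: symmetric diverging around 0 (blue–white–red)
when both signs occur, else sequential over `[min, max]`;
interpolation is linear in RGB, quantised to 256 steps so exact colours
are reproducible and testable. Missing values always render blank
(white).

## Rendering

Layout rule: array datasets each occupy a full-width row (one cell per
column); single-value datasets pack left-to-right into shared rows of
up to four cells; a label band (16 px) sits on top. Default cell size
is 40×20 px. All nodes of one node type share the layout, hence
identical image dimensions. A manual layout may be supplied as JSON and
is validated against the signature.

Both SVG and PNG are produced by the same drawing code through a
canvas abstraction: the SVG backend emits plain SVG 1.1 with fixed
number formatting, generic `sans-serif` font names and no timestamps
or generated ids — identical inputs give byte-identical documents —
and the PNG backend draws the same primitives through Pillow at
`dpi/96` scale, so raster dimensions equal the SVG canvas at the
configured DPI. Text metrics are approximated with a fixed 0.6 em
per-character advance to stay platform-independent. Legends list one
entry per dataset (name, description, style swatch, numeric scale
endpoints). Styles are pluggable through a registry; duplicate names
and unregistered styles are errors.

## Synthetic generators

`generate_toy_sbml` emulates the skeleton of a bacterial core network:
each pathway is a linear reaction chain over its own metabolites;
pathway pairs share a configurable number of junction metabolites (the
future linker anchors); co-factor species attach to a seeded fraction
of all reactions, creating realistic hubs; reactions carry SUBSYSTEM
and GENE_ASSOCIATION notes with random and/or trees over a shared gene
pool. The same seed yields byte-identical SBML and CSV outputs.

What it does **not** emulate: realistic stoichiometry, reversibility,
compartments beyond a single one, flux feasibility, branching pathway
topologies, or the identifier conventions of curated reconstructions.
Passing tests therefore demonstrate structural and algorithmic
correctness — membership, linker, conservation and round-trip
properties — not biological fidelity of any particular model.

Problem sizes: the demo model uses 3 pathways × 5 reactions, 2 shared
junction metabolites per pathway pair (so one can be declared
non-linking while every pair stays linked) and 2 co-factors touching
60 % of reactions. The genome-scale configuration uses 25 pathways ×
160 reactions, 2 junctions per pair, 10 co-factors at 15 % attachment
and a 1,500-gene pool, yielding ~10,100 nodes and ~21,200 edges after
gene attachment, with omics tables covering 3,400 nodes; the full
split + render pipeline on it completes in seconds on one CPU. Omics
tables default to standard Gaussian values with 5 % missing cells.

## Numerical and degenerate-input choices

* Percentiles in the suggestion rule use linear interpolation (numpy
  default) and are floored by the fixed constants 30 / 8.
* Colour quantisation snaps the interpolation parameter to 256 levels
  before mixing, so scale endpoints are hit exactly.
* An isolated node duplicates into a single replicate (degree 0);
  remerging restores it.
* Empty GPR strings, unbalanced parentheses and dangling operators are
  syntax errors reporting the offending position; unparseable note
  lines are ignored and logged.
* A dataset whose rows are all missing is rejected at construction; an
  all-missing row counts as "no data" for node-type membership.
* Ties in suggestion candidate ordering break by node id; subnetworks
  sort by group name; replicate numbering follows sorted edge keys.

## Known limitations

* GraphML/CYJS exports flatten multi-valued subsystems with `";"`,
  replacing literal `";"` in pathway names by `","`.
* The Pillow raster backend approximates text placement; PNG output is
  geometrically faithful but not glyph-exact against the SVG.
* `validate_split` checks the decomposition invariants, not layout or
  rendering properties.
* XLSX reading uses the first sheet unless a sheet name is given.
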