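"""Render multi-omics glyph images (metanodes) with a legend.

Two synthetic datasets — a heat-mapped expression table and a
line-plotted metabolite time course — are mapped onto the network.
Under the uniform node-type mode every data-bearing node gets the same
layout, with blank cells where its data are missing, and one legend
explains all images.
"""

import os
import tempfile

from glyphnet.fixtures import generate_omics_tables, generate_toy_sbml, three_pathway_spec
from glyphnet.omics import derive_node_types, match_nodes, read_table
from glyphnet.render import auto_layout, export_images, render_legend, render_node
from glyphnet.sbml import annotate_sbml

workdir = tempfile.mkdtemp()
path, _ = generate_toy_sbml(three_pathway_spec(seed=42), os.path.join(workdir, "core.xml"))
net = annotate_sbml(path)

tables, _ = generate_omics_tables(
    net, n_datasets=2, coverage_fraction=0.6, n_columns=4, seed=42,
    out_dir=os.path.join(workdir, "data"),
)
datasets = [
    read_table(tables[0], style="heatmap", name="expression"),
    read_table(tables[1], style="line", name="metabolites"),
]
for ds in datasets:
    coverage = match_nodes(ds, net)
    print(f"dataset {ds.name}: {coverage.n_matched} of {net.n_nodes()} nodes matched")

(signature,) = derive_node_types(datasets, net, mode="uniform")
layout = auto_layout(signature, datasets)
print(f"node type {signature.id!r}: {len(signature.member_ids)} members, "
      f"canvas {layout.canvas_width:.0f}x{layout.canvas_height:.0f} px")

images = [render_node(net.node(n), signature, datasets, layout) for n in signature.member_ids]
legend = render_legend(signature, datasets, layout)
out = os.path.join(workdir, "images")
manifest = export_images(images, [legend], out, formats={"svg", "png"})
print(f"wrote {len(manifest['nodes'])} node images and {len(manifest['legends'])} legend to {out}")
# Each SVG/PNG pair shares identical geometry; rendering the same node
# twice yields byte-identical SVG, so images are safe to cache or diff.
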