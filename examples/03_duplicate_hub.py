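"""Duplicate a highly connected co-factor and merge it back.

Hub duplication replaces one hairball-forming node by linked
replicates (one per incident edge) that share the original's identity
for data mapping; attribute edits propagate to all replicates, and the
original graph is restored exactly on remerge.
"""

import os
import tempfile

from glyphnet.duplication import duplicate_node, propagate_attributes, remerge
from glyphnet.fixtures import generate_toy_sbml, three_pathway_spec
from glyphnet.sbml import annotate_sbml

workdir = tempfile.mkdtemp()
path, truth = generate_toy_sbml(three_pathway_spec(seed=42), os.path.join(workdir, "core.xml"))
net = annotate_sbml(path)
before = net.copy()

hub = max(truth.cofactor_ids, key=net.degree)
print(f"co-factor {hub!r} has degree {net.degree(hub)}")

record = duplicate_node(net, hub, mode="per_edge")
degrees = [net.degree(r) for r in record.replicate_ids]
print(f"duplicated into {len(record.replicate_ids)} replicates, degrees {set(degrees)}")
print(f"replicate degree sum {sum(degrees)} == original degree")

propagate_attributes(net, record.group_id, {"label": hub.upper()})
print("after propagation all replicates are labelled", net.node(record.replicate_ids[0]).label)

remerge(net, record.group_id)
print(f"remerged; network identical to the original: {net == before}")
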