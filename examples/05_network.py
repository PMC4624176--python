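"""Extract a one-linker interaction subnetwork around candidate genes.

Keeps candidate-candidate edges and admits a non-candidate gene only when
it directly bridges two candidates — every connection in the output is
direct or spans exactly one linker.
"""

from aipqtl.network import extract_subnetwork, graph_from_edges, summarize_network
from aipqtl.simulate import make_fixture_network

edges, candidates = make_fixture_network(
    n_candidates=8, n_other=30, n_edges=60, seed=7, planted_linkers=3
)
graph = graph_from_edges(edges)
print(f"global graph: {graph.number_of_nodes()} genes, "
      f"{graph.number_of_edges()} interactions; {len(candidates)} candidates")

sub = extract_subnetwork(graph, set(candidates), allow_missing=1)
s = summarize_network(sub, set(candidates))
print(f"subnetwork: {s['n_candidates']} candidates + {s['n_linkers']} linkers "
      f"= {s['n_genes']} genes in {s['n_components']} component(s)")
for comp in s["components"]:
    print("  component:", ", ".join(comp))
# Planted linkers (link0..link2) each bridge two candidates and must appear.
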