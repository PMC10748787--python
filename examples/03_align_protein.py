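"""Align amino-acid queries to a graph with the partial-order local DP.

One query is an exact path spelling (perfect identity); the second carries
a substitution. The score is a BLOSUM62 local-alignment score with linear
gaps; identity counts identical columns over all alignment columns.
"""

from proteograph import AlignConfig, align_protein, build_graph_from_msa, compact_graph
from proteograph.fixtures import example_msa

graph = compact_graph(build_graph_from_msa(example_msa()))
cfg = AlignConfig()  # BLOSUM62, gap -3

for query in ("MSETQSTQ", "MSETWSTQ"):
    aln = align_protein(query, graph, cfg)
    print(f"query {query}:")
    print(f"  score={aln.score}  identity={aln.identity:.3f}  cigar={aln.cigar}")
    print(f"  node path {aln.node_path} spells "
          f"{''.join(graph.nodes[v] for v in aln.node_path)}")
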