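"""Graph Alignment Format (GAF) records.

One tab-separated line per alignment: query name/length/start/end (0-based
half-open), strand, the node path as ``>id>id...`` (orientations are always
forward in a DAG), path length/start/end, residue matches, alignment block
length and mapping quality (255 = unavailable), followed by typed tags:

``AS:i`` DP score, ``id:f`` alignment identity, ``gi:Z`` graph id,
``fr:Z`` reading frame (DNA mode), ``fs:i`` frameshift count, ``bm:i`` 1 on
the query's best-scoring alignment, ``cg:Z`` CIGAR over alignment columns.
"""

from __future__ import annotations

from .align import GraphAlignment
from .graph import ProteinGraph

GAF_HEADER_COMMENT = (
    "# qname\tqlen\tqstart\tqend\tstrand\tpath\tplen\tpstart\tpend\t"
    "matches\tblocklen\tmapq\ttags"
)


def gaf_line(aln: GraphAlignment, query_len: int, graph: ProteinGraph) -> str:
    """Format one alignment as a GAF record."""
    path = "".join(f">{v}" for v in aln.node_path)
    plen = sum(len(graph.nodes[v]) for v in aln.node_path)
    fields = [
        aln.query_name,
        str(query_len),
        str(aln.query_interval[0]),
        str(aln.query_interval[1]),
        aln.strand,
        path,
        str(plen),
        str(aln.path_interval[0]),
        str(aln.path_interval[1]),
        str(aln.matches),
        str(aln.n_columns),
        "255",
        f"AS:i:{aln.score}",
        f"id:f:{aln.identity:.4f}",
        f"gi:Z:{aln.graph_id}",
        f"fr:Z:{aln.frame}",
        f"fs:i:{aln.frameshift_count}",
        f"bm:i:{1 if aln.is_best else 0}",
        f"cg:Z:{aln.cigar}",
    ]
    return "\t".join(fields)
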