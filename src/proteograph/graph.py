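"""Protein DAGs built from MSAs, and their compaction.

Each MSA becomes one directed acyclic graph: one node per (column, distinct
non-gap character) pair, edges between characters that are consecutive in
some row once gaps are skipped, and one named path per row spelling that
row's degapped sequence. Linear stretches are then compacted, subject to the
constraint that every merged adjacency is traversed by the identical set of
paths — otherwise some row could no longer be written as a path over the
compacted nodes.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

from .msa import GAP, Msa


class GraphError(ValueError):
    """Raised for structurally invalid graphs (cycles, empty paths...)."""


@dataclass
class ProteinGraph:
    """A sequence-labeled DAG with one embedded path per source MSA row.

    Attributes
    ----------
    graph_id:
        Identifier, equal to the source MSA id.
    nodes:
        Map node id -> amino-acid label (one or more characters).
    edges:
        Set of ordered (from_id, to_id) pairs. Unweighted: many rows may
        share a transition but the edge appears once.
    paths:
        Map row name -> ordered list of node ids whose concatenated labels
        spell the degapped row.
    column_of:
        Map node id -> 0-based source-MSA column of the node's first
        character (narrative descriptions of the construction count columns
        from 1; internally everything is 0-based).
    """

    graph_id: str
    nodes: dict[int, str]
    edges: set[tuple[int, int]] = field(default_factory=set)
    paths: dict[str, list[int]] = field(default_factory=dict)
    column_of: dict[int, int] = field(default_factory=dict)

    def successors(self) -> dict[int, set[int]]:
        out: dict[int, set[int]] = {u: set() for u in self.nodes}
        for a, b in self.edges:
            out[a].add(b)
        return out

    def predecessors(self) -> dict[int, set[int]]:
        inc: dict[int, set[int]] = {u: set() for u in self.nodes}
        for a, b in self.edges:
            inc[b].add(a)
        return inc

    def spell_path(self, row_name: str) -> str:
        """Concatenate node labels along a path (equals the degapped row)."""
        return "".join(self.nodes[v] for v in self.paths[row_name])

    def topological_order(self) -> list[int]:
        """Kahn's algorithm with a min-heap for deterministic order.

        Raises :class:`GraphError` if the edge relation has a cycle.
        """
        indeg = {u: 0 for u in self.nodes}
        for _, b in self.edges:
            indeg[b] += 1
        out = self.successors()
        heap = [u for u, d in indeg.items() if d == 0]
        heapq.heapify(heap)
        order: list[int] = []
        while heap:
            u = heapq.heappop(heap)
            order.append(u)
            for v in sorted(out[u]):
                indeg[v] -= 1
                if indeg[v] == 0:
                    heapq.heappush(heap, v)
        if len(order) != len(self.nodes):
            raise GraphError(f"graph {self.graph_id!r} contains a cycle")
        return order


def build_graph_from_msa(msa: Msa) -> ProteinGraph:
    """Construct the uncompacted DAG of an MSA.

    Sweeps the columns left to right. Each column contributes one node per
    distinct non-gap character; an edge a->b is drawn whenever the two
    characters are consecutive in some row after skipping gaps, including
    transitions that bridge a run of gaps. All-gap columns contribute
    nothing. Node ids are positive integers in construction order.
    """
    nodes: dict[int, str] = {}
    column_of: dict[int, int] = {}
    edges: set[tuple[int, int]] = set()
    paths: dict[str, list[int]] = {name: [] for name in msa.row_names}
    # last non-gap node seen per row; survives gap runs so edges bridge gaps
    pending: list[int | None] = [None] * msa.n_rows

    next_id = 0
    for j in range(msa.n_cols):
        seen: dict[str, int] = {}
        for i, name in enumerate(msa.row_names):
            c = msa.rows[i][j]
            if c == GAP:
                continue
            if c not in seen:
                next_id += 1
                nodes[next_id] = c
                column_of[next_id] = j
                seen[c] = next_id
            node = seen[c]
            if pending[i] is not None:
                edges.add((pending[i], node))
            pending[i] = node
            paths[name].append(node)

    for name, p in paths.items():
        if not p:
            raise GraphError(
                f"MSA {msa.msa_id!r} row {name!r} consists entirely of gaps; "
                "its path would be empty"
            )
    return ProteinGraph(
        graph_id=msa.msa_id, nodes=nodes, edges=edges, paths=paths, column_of=column_of
    )


def _path_sets(g: ProteinGraph) -> dict[int, frozenset[str]]:
    through: dict[int, set[str]] = {u: set() for u in g.nodes}
    for name, path in g.paths.items():
        for v in path:
            through[v].add(name)
    return {u: frozenset(s) for u, s in through.items()}


def compact_graph(g: ProteinGraph) -> ProteinGraph:
    """Merge maximal linear stretches whose adjacencies share one path set.

    Two adjacent nodes u->v are merged only when u has out-degree one, v has
    in-degree one, and the identical set of paths traverses both — the
    constraint that keeps every row representable as a path over compacted
    nodes. Interior nodes of a merged stretch have in-degree = out-degree
    = 1; the first node may have higher in-degree and the last higher
    out-degree. Node ids are renumbered consecutively in topological order.
    """
    out = g.successors()
    inc = g.predecessors()
    pset = _path_sets(g)

    def mergeable(u: int, v: int) -> bool:
        return len(out[u]) == 1 and len(inc[v]) == 1 and pset[u] == pset[v]

    # chain heads: nodes whose unique predecessor cannot absorb them
    chain_of: dict[int, int] = {}  # old id -> chain index
    chains: list[list[int]] = []
    for u in g.topological_order():
        if u in chain_of:
            continue
        preds = inc[u]
        if len(preds) == 1 and mergeable(next(iter(preds)), u):
            continue  # interior/tail of some chain; reached by extension below
        chain = [u]
        while len(out[chain[-1]]) == 1:
            (v,) = out[chain[-1]]
            if not mergeable(chain[-1], v):
                break
            chain.append(v)
        for v in chain:
            chain_of[v] = len(chains)
        chains.append(chain)

    tmp_nodes = {ci: "".join(g.nodes[v] for v in chain) for ci, chain in enumerate(chains)}
    tmp_cols = {ci: g.column_of.get(chain[0], 0) for ci, chain in enumerate(chains)}
    tmp_edges = {
        (chain_of[a], chain_of[b]) for a, b in g.edges if chain_of[a] != chain_of[b]
    }
    tmp_paths: dict[str, list[int]] = {}
    for name, path in g.paths.items():
        squeezed: list[int] = []
        for v in path:
            ci = chain_of[v]
            if not squeezed or squeezed[-1] != ci:
                squeezed.append(ci)
        tmp_paths[name] = squeezed

    tmp = ProteinGraph(
        graph_id=g.graph_id,
        nodes=tmp_nodes,
        edges=tmp_edges,
        paths=tmp_paths,
        column_of=tmp_cols,
    )
    renum = {old: new for new, old in enumerate(tmp.topological_order(), start=1)}
    return ProteinGraph(
        graph_id=g.graph_id,
        nodes={renum[u]: lab for u, lab in tmp_nodes.items()},
        edges={(renum[a], renum[b]) for a, b in tmp_edges},
        paths={name: [renum[v] for v in p] for name, p in tmp_paths.items()},
        column_of={renum[u]: c for u, c in tmp_cols.items()},
    )
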