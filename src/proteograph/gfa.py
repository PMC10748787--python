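"""GFA1 serialization of protein graphs.

The dialect is minimal: ``S`` lines carry node id and label, ``L`` lines use
``+`` orientations and a ``0M`` overlap (nodes never overlap), and ``P``
lines spell each source row as comma-separated ``<id>+`` steps with ``*``
overlaps. Files written here re-parse to an identical graph.
"""

from __future__ import annotations

import os
import warnings

from .graph import GraphError, ProteinGraph


def write_gfa(g: ProteinGraph, path: str | os.PathLike) -> None:
    """Write a graph as GFA1 (S, L and P lines, in sorted node-id order)."""
    with open(path, "w") as fh:
        fh.write("H\tVN:Z:1.0\n")
        for u in sorted(g.nodes):
            fh.write(f"S\t{u}\t{g.nodes[u]}\n")
        for a, b in sorted(g.edges):
            fh.write(f"L\t{a}\t+\t{b}\t+\t0M\n")
        for name, p in g.paths.items():
            steps = ",".join(f"{v}+" for v in p)
            fh.write(f"P\t{name}\t{steps}\t*\n")


def read_gfa(path: str | os.PathLike) -> ProteinGraph:
    """Parse a GFA1 file back into a :class:`ProteinGraph`.

    Graphs with cycles are rejected (the aligner requires a DAG). A file
    without P lines parses with empty paths, with a warning.
    """
    path = os.fspath(path)
    nodes: dict[int, str] = {}
    edges: set[tuple[int, int]] = set()
    paths: dict[str, list[int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            tag = fields[0]
            if tag == "S":
                if len(fields) < 3:
                    raise GraphError(f"{path}:{lineno}: malformed S line")
                nodes[int(fields[1])] = fields[2]
            elif tag == "L":
                if len(fields) < 5:
                    raise GraphError(f"{path}:{lineno}: malformed L line")
                edges.add((int(fields[1]), int(fields[3])))
            elif tag == "P":
                if len(fields) < 3:
                    raise GraphError(f"{path}:{lineno}: malformed P line")
                steps = [s.rstrip("+-") for s in fields[2].split(",") if s]
                paths[fields[1]] = [int(s) for s in steps]
    if not paths:
        warnings.warn(f"{path}: no P lines found; graph has empty paths", stacklevel=2)
    stem = os.path.splitext(os.path.basename(path))[0]
    g = ProteinGraph(
        graph_id=stem,
        nodes=nodes,
        edges=edges,
        paths=paths,
        column_of={},
    )
    g.topological_order()  # raises on cycles
    return g
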