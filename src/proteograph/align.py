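"""Local alignment of queries against protein DAGs.

The aligner generalizes Smith–Waterman to a DAG (partial-order alignment):
the graph is topologically sorted and the node labels concatenated into a
target sequence; a DP cell whose target column begins a node considers the
last column of every predecessor node instead of simply column j-1, so the
recurrence follows all incoming graph edges. Scores use a substitution
matrix (BLOSUM62 by default) and a linear gap penalty, with a 0 floor for
local alignment.

DNA queries can be aligned directly to the amino-acid graphs with a
frameshift-aware recurrence: each nucleotide row is treated as a potential
third codon position (a 3-row jump consumes one codon against one amino
acid), and two extra diagonal jumps consuming 4 or 2 nucleotides model a
single-nucleotide insertion or deletion, each paying a frameshift penalty.
Both strands are attempted; candidate graphs are found from seeds extracted
from all six translated reading frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

from Bio.Align import substitution_matrices
from Bio.Data import CodonTable

from .graph import GraphError, ProteinGraph
from .index import SeedIndex, seeds_of

NEG_INF = float("-inf")

# traceback moves
_STOP, _DIAG, _QGAP, _TGAP, _FS4, _FS2 = 0, 1, 2, 3, 4, 5


class AlignmentError(ValueError):
    """Raised for characters the substitution matrix cannot score, etc."""


@dataclass(frozen=True)
class AlignConfig:
    """Scoring and filtering parameters.

    Attributes
    ----------
    sub_matrix:
        Name of a substitution matrix known to Biopython (e.g. BLOSUM62).
    gap_penalty:
        Linear per-column gap penalty (<= 0).
    frameshift_penalty:
        Penalty for a 4- or 2-nucleotide diagonal jump in DNA mode (<= 0).
    min_identity:
        Alignments below this identity fraction are discarded.
    align_limit:
        Maximum candidate graphs attempted per query (0 = all matches).
    min_len_frac:
        Minimum fraction of the query covered by the alignment.
    unknown_char_score:
        Score for residue pairs the matrix lacks (used for 'X'/'*' only
        when the matrix itself has no entry for them).
    """

    sub_matrix: str = "BLOSUM62"
    gap_penalty: int = -3
    frameshift_penalty: int = -4
    min_identity: float = 0.0
    align_limit: int = 5
    min_len_frac: float = 0.0
    unknown_char_score: int = -4

    def __post_init__(self) -> None:
        if self.gap_penalty > 0 or self.frameshift_penalty > 0:
            raise ValueError("gap and frameshift penalties must be <= 0")
        if not (0.0 <= self.min_identity <= 1.0 and 0.0 <= self.min_len_frac <= 1.0):
            raise ValueError("min_identity and min_len_frac must lie in [0, 1]")


@lru_cache(maxsize=8)
def _matrix_lookup(name: str) -> tuple[frozenset[str], dict[tuple[str, str], int]]:
    mat = substitution_matrices.load(name)
    alphabet = frozenset(str(c) for c in mat.alphabet)
    table = {
        (a, b): int(mat[a, b]) for a in mat.alphabet for b in mat.alphabet
    }
    return alphabet, table


def substitution_score(a: str, b: str, cfg: AlignConfig) -> int:
    """Matrix score for a residue pair; 'X'/'*' fall back to a flat penalty
    only when the chosen matrix has no entry for them."""
    alphabet, table = _matrix_lookup(cfg.sub_matrix)
    if a in alphabet and b in alphabet:
        return table[a, b]
    for c in (a, b):
        if c not in alphabet and c not in ("X", "*"):
            raise AlignmentError(
                f"character {c!r} is absent from substitution matrix {cfg.sub_matrix}"
            )
    return cfg.unknown_char_score


@dataclass
class DpLayout:
    """Topological layout of a graph for the DP.

    ``target`` is the concatenation of node labels in topological order;
    DP columns are 1-based over it. ``incoming_of[j]`` lists the predecessor
    columns of column j: within a node the single column j-1; at a node's
    first column, the last columns of all predecessor nodes (or column 0 for
    source nodes, matching the classical Smith–Waterman boundary).
    """

    order: list[int]
    target: str
    incoming_of: list[list[int]]  # indexed by DP column 1..len(target)
    node_of_col: list[int]  # indexed the same; node id owning each column
    node_start: dict[int, int]  # node id -> its first DP column


def layout(g: ProteinGraph) -> DpLayout:
    """Topologically sort a DAG and precompute the DP column structure."""
    order = g.topological_order()  # raises GraphError on cycles
    preds = g.predecessors()
    target_parts: list[str] = []
    incoming: list[list[int]] = [[]]  # dummy for column 0
    node_of_col: list[int] = [0]
    node_start: dict[int, int] = {}
    end_col: dict[int, int] = {}
    col = 0
    for u in order:
        label = g.nodes[u]
        node_start[u] = col + 1
        for offset in range(len(label)):
            col += 1
            node_of_col.append(u)
            if offset == 0:
                pin = sorted(end_col[p] for p in preds[u]) if preds[u] else [0]
                incoming.append(pin)
            else:
                incoming.append([col - 1])
        end_col[u] = col
        target_parts.append(label)
    return DpLayout(
        order=order,
        target="".join(target_parts),
        incoming_of=incoming,
        node_of_col=node_of_col,
        node_start=node_start,
    )


@dataclass
class GraphAlignment:
    """A scored local alignment of one query against one graph.

    The CIGAR is over alignment columns: ``=``/``X`` (residue vs residue,
    or codon vs residue in DNA mode), ``I`` (query residue/codon vs gap),
    ``D`` (graph residue vs gap) and, in DNA mode only, ``F`` (insertion
    frameshift, 4 nt vs 1 residue) and ``G`` (deletion frameshift, 2 nt vs
    1 residue). Intervals are 0-based half-open; for reverse-strand DNA
    alignments the query interval is reported on the original orientation.
    """

    query_name: str
    graph_id: str
    score: int
    node_path: list[int]
    query_interval: tuple[int, int]
    path_interval: tuple[int, int]
    cigar: str
    identity: float
    matches: int
    n_columns: int
    frame: str = "none"
    strand: str = "+"
    frameshift_count: int = 0
    is_best: bool = False


def _encode_cigar(ops: list[str]) -> str:
    out: list[str] = []
    i = 0
    while i < len(ops):
        j = i
        while j < len(ops) and ops[j] == ops[i]:
            j += 1
        out.append(f"{j - i}{ops[i]}")
        i = j
    return "".join(out)


def compute_identity(aln: GraphAlignment) -> float:
    """Identical columns divided by all alignment columns (gaps included)."""
    if aln.n_columns == 0:
        return 0.0
    return aln.matches / aln.n_columns


def _finish(
    aln: GraphAlignment, query_len: int, cfg: AlignConfig
) -> GraphAlignment | None:
    if aln.score <= 0 or aln.n_columns == 0:
        return None
    if aln.identity < cfg.min_identity:
        return None
    covered = (aln.query_interval[1] - aln.query_interval[0]) / query_len
    if covered < cfg.min_len_frac:
        return None
    return aln


def align_protein(
    query: str, g: ProteinGraph, cfg: AlignConfig | None = None
) -> GraphAlignment | None:
    """Partial-order local alignment of an amino-acid query against a DAG.

    Returns the best local alignment, or None when nothing scores above the
    0 floor or the identity/coverage filters reject it. Traceback ties
    prefer diagonal over target-gap over query-gap, and the smallest
    predecessor column among equals, so output is deterministic.
    """
    cfg = cfg or AlignConfig()
    lay = layout(g)
    target = lay.target
    nq, nt = len(query), len(target)
    for c in set(query):
        substitution_score(c, "A", cfg)  # raises on unknown characters

    H = [[0] * (nt + 1) for _ in range(nq + 1)]
    move = [[_STOP] * (nt + 1) for _ in range(nq + 1)]
    origin = [[0] * (nt + 1) for _ in range(nq + 1)]
    gap = cfg.gap_penalty

    for i in range(1, nq + 1):
        qc = query[i - 1]
        Hi, Hi1 = H[i], H[i - 1]
        for j in range(1, nt + 1):
            best, bmove, borigin = 0, _STOP, 0
            sub = substitution_score(target[j - 1], qc, cfg)
            for pl in lay.incoming_of[j]:
                s = Hi1[pl] + sub
                if s > best:
                    best, bmove, borigin = s, _DIAG, pl
            for pl in lay.incoming_of[j]:
                s = Hi[pl] + gap
                if s > best:
                    best, bmove, borigin = s, _TGAP, pl
            s = Hi1[j] + gap
            if s > best:
                best, bmove, borigin = s, _QGAP, j
            Hi[j] = best
            move[i][j] = bmove
            origin[i][j] = borigin

    # optimum cell: max score, ties to largest i then largest j
    best_score, bi, bj = 0, 0, 0
    for i in range(1, nq + 1):
        row = H[i]
        for j in range(1, nt + 1):
            if row[j] >= best_score:
                best_score, bi, bj = row[j], i, j
    if best_score <= 0:
        return None

    ops: list[str] = []
    cols: list[int] = []
    i, j = bi, bj
    while i > 0 and j > 0 and H[i][j] > 0:
        m = move[i][j]
        if m == _DIAG:
            ops.append("=" if target[j - 1] == query[i - 1] else "X")
            cols.append(j)
            i, j = i - 1, origin[i][j]
        elif m == _TGAP:
            ops.append("D")
            cols.append(j)
            j = origin[i][j]
        elif m == _QGAP:
            ops.append("I")
            i -= 1
        else:
            break
    ops.reverse()
    cols.reverse()

    node_path: list[int] = []
    for c in cols:
        u = lay.node_of_col[c]
        if not node_path or node_path[-1] != u:
            node_path.append(u)
    path_start = (cols[0] - lay.node_start[lay.node_of_col[cols[0]]]) if cols else 0
    matches = ops.count("=")
    aln = GraphAlignment(
        query_name="",
        graph_id=g.graph_id,
        score=best_score,
        node_path=node_path,
        query_interval=(i, bi),
        path_interval=(path_start, path_start + len(cols)),
        cigar=_encode_cigar(ops),
        identity=matches / len(ops) if ops else 0.0,
        matches=matches,
        n_columns=len(ops),
    )
    return _finish(aln, nq, cfg)


# ---------------------------------------------------------------------------
# DNA mode
# ---------------------------------------------------------------------------

_DNA_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _codon_table() -> dict[str, str]:
    table = CodonTable.unambiguous_dna_by_id[1]
    mapping = dict(table.forward_table)
    for stop in table.stop_codons:
        mapping[stop] = "*"
    return mapping


_CODONS = _codon_table()


def translate_codon(codon: str) -> str:
    """Standard genetic code; any codon containing N translates to 'X'."""
    return _CODONS.get(codon, "X")


def reverse_complement(dna: str) -> str:
    return dna.translate(_DNA_COMPLEMENT)[::-1]


def translate_six_frames(dna: str) -> list[tuple[str, str]]:
    """All six reading frames of a DNA sequence as (frame, protein) pairs.

    Frames are labelled +1/+2/+3 (forward offsets 0/1/2) and -1/-2/-3 (same
    offsets on the reverse complement). Trailing partial codons are dropped;
    stop codons appear as '*'.
    """
    dna = dna.upper()
    bad = set(dna) - set("ACGTN")
    if bad:
        raise AlignmentError(f"non-nucleotide characters in DNA query: {sorted(bad)}")
    frames: list[tuple[str, str]] = []
    rc = reverse_complement(dna)
    for label, seq in (("+", dna), ("-", rc)):
        for offset in range(3):
            aa = "".join(
                translate_codon(seq[p : p + 3])
                for p in range(offset, len(seq) - 2, 3)
            )
            frames.append((f"{label}{offset + 1}", aa))
    return frames


def align_dna_frameshift(
    dna: str, g: ProteinGraph, cfg: AlignConfig | None = None
) -> GraphAlignment | None:
    """Frameshift-aware local alignment of a DNA query against a protein DAG.

    Rows are nucleotide positions, columns the topologically laid-out graph
    target. A cell may be reached by: a codon diagonal (3 nt vs 1 residue,
    scored by the substitution matrix on the translated codon), a codon gap
    vs the graph (3 nt, gap penalty), a residue gap vs the query (1 residue,
    gap penalty), or a frameshift jump consuming 4 or 2 nt against 1
    residue at the frameshift penalty. Node-boundary columns take the max
    over all predecessor columns, as in protein mode. Both strands are
    attempted and the better alignment returned ('+' wins ties).
    """
    cfg = cfg or AlignConfig()
    dna = dna.upper()
    bad = set(dna) - set("ACGTN")
    if bad:
        raise AlignmentError(f"non-nucleotide characters in DNA query: {sorted(bad)}")
    lay = layout(g)
    best: GraphAlignment | None = None
    for strand in ("+", "-"):
        seq = dna if strand == "+" else reverse_complement(dna)
        aln = _align_dna_one_strand(seq, g, lay, cfg)
        if aln is None:
            continue
        if strand == "-":
            n = len(dna)
            lo, hi = aln.query_interval
            aln.query_interval = (n - hi, n - lo)
            aln.strand = "-"
            aln.frame = "-" + aln.frame[1:]
        if best is None or aln.score > best.score:
            best = aln
    if best is None:
        return None
    return _finish(best, len(dna), cfg)


def _align_dna_one_strand(
    seq: str, g: ProteinGraph, lay: DpLayout, cfg: AlignConfig
) -> GraphAlignment | None:
    target = lay.target
    nq, nt = len(seq), len(target)
    gap, fs = cfg.gap_penalty, cfg.frameshift_penalty

    H = [[0] * (nt + 1) for _ in range(nq + 1)]
    move = [[_STOP] * (nt + 1) for _ in range(nq + 1)]
    origin = [[0] * (nt + 1) for _ in range(nq + 1)]

    # precompute translated codons ending at row i (i >= 3)
    codon_aa = [""] * (nq + 1)
    for i in range(3, nq + 1):
        codon_aa[i] = translate_codon(seq[i - 3 : i])

    for i in range(1, nq + 1):
        Hi = H[i]
        aa = codon_aa[i]
        for j in range(1, nt + 1):
            best_s, bmove, borigin = 0, _STOP, 0
            tc = target[j - 1]
            pin = lay.incoming_of[j]
            if i >= 3:
                sub = substitution_score(tc, aa, cfg)
                Hd = H[i - 3]
                for pl in pin:
                    s = Hd[pl] + sub
                    if s > best_s:
                        best_s, bmove, borigin = s, _DIAG, pl
            for pl in pin:
                s = Hi[pl] + gap
                if s > best_s:
                    best_s, bmove, borigin = s, _TGAP, pl
            if i >= 3:
                s = H[i - 3][j] + gap
                if s > best_s:
                    best_s, bmove, borigin = s, _QGAP, j
            if i >= 4:
                Hf = H[i - 4]
                for pl in pin:
                    s = Hf[pl] + fs
                    if s > best_s:
                        best_s, bmove, borigin = s, _FS4, pl
            if i >= 2:
                Hf = H[i - 2]
                for pl in pin:
                    s = Hf[pl] + fs
                    if s > best_s:
                        best_s, bmove, borigin = s, _FS2, pl
            Hi[j] = best_s
            move[i][j] = bmove
            origin[i][j] = borigin

    best_score, bi, bj = 0, 0, 0
    for i in range(1, nq + 1):
        row = H[i]
        for j in range(1, nt + 1):
            if row[j] >= best_score:
                best_score, bi, bj = row[j], i, j
    if best_score <= 0:
        return None

    ops: list[str] = []
    cols: list[int] = []
    n_fs = 0
    i, j = bi, bj
    while i > 0 and j > 0 and H[i][j] > 0:
        m = move[i][j]
        if m == _DIAG:
            ops.append("=" if codon_aa[i] == target[j - 1] else "X")
            cols.append(j)
            i, j = i - 3, origin[i][j]
        elif m == _TGAP:
            ops.append("D")
            cols.append(j)
            j = origin[i][j]
        elif m == _QGAP:
            ops.append("I")
            i -= 3
        elif m == _FS4:
            ops.append("F")
            cols.append(j)
            n_fs += 1
            i, j = i - 4, origin[i][j]
        elif m == _FS2:
            ops.append("G")
            cols.append(j)
            n_fs += 1
            i, j = i - 2, origin[i][j]
        else:
            break
    ops.reverse()
    cols.reverse()
    if not ops:
        return None

    node_path: list[int] = []
    for c in cols:
        u = lay.node_of_col[c]
        if not node_path or node_path[-1] != u:
            node_path.append(u)
    path_start = (cols[0] - lay.node_start[lay.node_of_col[cols[0]]]) if cols else 0
    matches = ops.count("=")
    frame = f"+{(i % 3) + 1}"
    return GraphAlignment(
        query_name="",
        graph_id=g.graph_id,
        score=best_score,
        node_path=node_path,
        query_interval=(i, bi),
        path_interval=(path_start, path_start + len(cols)),
        cigar=_encode_cigar(ops),
        identity=matches / len(ops),
        matches=matches,
        n_columns=len(ops),
        frame=frame,
        strand="+",
        frameshift_count=n_fs,
    )


# ---------------------------------------------------------------------------
# candidate selection & panproteome-level driver
# ---------------------------------------------------------------------------


def select_candidates(
    query: str, idx: SeedIndex, cfg: AlignConfig | None = None
) -> list[str]:
    """Rank graphs by descending count of query-seed hits in the index.

    The query must be amino-acid; DNA queries are six-frame translated and
    their seeds pooled first (see :func:`select_candidates_dna`). Ties break
    on ascending graph id; the list is truncated to ``align_limit`` when
    that limit is positive.
    """
    cfg = cfg or AlignConfig()
    hits: dict[str, int] = {}
    for seed in seeds_of(query, idx.params):
        for msa_id in idx.entries.get(seed, ()):
            hits[msa_id] = hits.get(msa_id, 0) + 1
    ranked = [m for m, _ in sorted(hits.items(), key=lambda kv: (-kv[1], kv[0]))]
    if cfg.align_limit > 0:
        ranked = ranked[: cfg.align_limit]
    return ranked


def select_candidates_dna(
    dna: str, idx: SeedIndex, cfg: AlignConfig | None = None
) -> list[str]:
    """Candidate graphs for a DNA query: seeds from all six frames, pooled."""
    cfg = cfg or AlignConfig()
    hits: dict[str, int] = {}
    for _, aa in translate_six_frames(dna):
        for seed in seeds_of(aa, idx.params):
            for msa_id in idx.entries.get(seed, ()):
                hits[msa_id] = hits.get(msa_id, 0) + 1
    ranked = [m for m, _ in sorted(hits.items(), key=lambda kv: (-kv[1], kv[0]))]
    if cfg.align_limit > 0:
        ranked = ranked[: cfg.align_limit]
    return ranked


def align_query(
    name: str,
    seq: str,
    kind: str,
    graphs: dict[str, ProteinGraph],
    idx: SeedIndex,
    cfg: AlignConfig | None = None,
) -> list[GraphAlignment]:
    """Align one query against its candidate graphs.

    Returns the best alignment per attempted graph that passes the filters,
    in candidate order, with ``is_best`` set on the overall maximum score.
    ``kind`` is 'aa' or 'dna'.
    """
    cfg = cfg or AlignConfig()
    if kind == "aa":
        candidates = select_candidates(seq, idx, cfg)
    elif kind == "dna":
        candidates = select_candidates_dna(seq, idx, cfg)
    else:
        raise ValueError(f"kind must be 'aa' or 'dna', got {kind!r}")
    out: list[GraphAlignment] = []
    for gid in candidates:
        if gid not in graphs:
            raise GraphError(f"index points to graph {gid!r} which was not loaded")
        g = graphs[gid]
        aln = (
            align_protein(seq, g, cfg) if kind == "aa" else align_dna_frameshift(seq, g, cfg)
        )
        if aln is not None:
            aln.query_name = name
            out.append(aln)
    if out:
        best = max(out, key=lambda a: a.score)
        best.is_best = True
    return out
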