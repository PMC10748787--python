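"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package: a textbook
Smith-Waterman, a literal sequence-vs-sequence transcription of the
frameshift recurrence, naive per-window minimizers, and exhaustive
source-to-sink path enumeration for small DAGs.
"""

from __future__ import annotations

from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")


def sub62(a: str, b: str) -> int:
    return int(_B62[a, b])


def smith_waterman(query: str, target: str, gap: int = -3) -> int:
    """Textbook local alignment score with a linear gap penalty."""
    nq, nt = len(query), len(target)
    H = [[0] * (nt + 1) for _ in range(nq + 1)]
    best = 0
    for i in range(1, nq + 1):
        for j in range(1, nt + 1):
            H[i][j] = max(
                0,
                H[i - 1][j - 1] + sub62(query[i - 1], target[j - 1]),
                H[i - 1][j] + gap,
                H[i][j - 1] + gap,
            )
            best = max(best, H[i][j])
    return best


def frameshift_dp(dna: str, protein: str, trans, gap: int = -3, fs: int = -4) -> int:
    """Literal frameshift-aware DP of a DNA query against one protein
    sequence: codon diagonal, codon gap, residue gap, and the 4-nt/2-nt
    frameshift jumps at penalty ``fs``; 0 floor; returns the best cell."""
    nq, nt = len(dna), len(protein)
    H = [[0] * (nt + 1) for _ in range(nq + 1)]
    best = 0
    for i in range(1, nq + 1):
        for j in range(1, nt + 1):
            cands = [0, H[i][j - 1] + gap]
            if i >= 3:
                cands.append(H[i - 3][j - 1] + sub62(trans(dna[i - 3 : i]), protein[j - 1]))
                cands.append(H[i - 3][j] + gap)
            if i >= 4:
                cands.append(H[i - 4][j - 1] + fs)
            if i >= 2:
                cands.append(H[i - 2][j - 1] + fs)
            H[i][j] = max(cands)
            best = max(best, H[i][j])
    return best


def naive_minimizers(seq: str, k: int, w: int) -> list[str]:
    """Per-window minimum by brute force. The minimum of each window is the
    rightmost occurrence of the lexicographically smallest k-mer; windows
    selecting the same instance emit it once."""
    kmers = [seq[i : i + k] for i in range(len(seq) - k + 1)]
    if not kmers:
        return []
    if len(kmers) < w:
        return [min(kmers)]
    out: list[str] = []
    last = -1
    for i in range(len(kmers) - w + 1):
        window = kmers[i : i + w]
        smallest = min(window)
        pos = i + max(j for j, s in enumerate(window) if s == smallest)
        if pos != last:
            last = pos
            out.append(kmers[pos])
    return out


def all_path_spellings(g) -> list[str]:
    """Spellings of every source-to-sink path of a small DAG."""
    out = g.successors()
    inc = g.predecessors()
    sources = sorted(u for u in g.nodes if not inc[u])
    spellings: list[str] = []

    def dfs(u: int, acc: str) -> None:
        acc += g.nodes[u]
        if not out[u]:
            spellings.append(acc)
            return
        for v in sorted(out[u]):
            dfs(v, acc)

    for s in sources:
        dfs(s, "")
    return spellings
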