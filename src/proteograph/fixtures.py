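"""Deterministic synthetic panproteomes and query sets.

The generator emulates a toy panproteome: each protein family is an ancestor
sequence mutated independently per row, with substitutions and short indels
applied *in alignment coordinates*, so the family is aligned by construction
and needs no external MSA tool. Families can be forced pairwise k-mer
disjoint (rejection sampling), which makes the expected wrong-alignment
fraction exactly zero when every seed hit is kept — a toy analogue of
self-realignment validation. DNA queries are codon back-translations (a
fixed most-frequent-codon table, so fixtures are deterministic) with a
configurable number of planted single-nucleotide indels, recorded in the
FASTA headers as ground truth for frameshift-recovery tests.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

from .msa import Msa

_AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: Fixed back-translation table (most frequent codon per residue in
#: enterobacteria); keeps DNA fixtures deterministic.
PREFERRED_CODON = {
    "A": "GCG", "C": "TGC", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGC", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAC", "P": "CCG", "Q": "CAG", "R": "CGC",
    "S": "AGC", "T": "ACC", "V": "GTG", "W": "TGG", "Y": "TAT",
    "X": "NNN", "*": "TAA",
}


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic panproteome.

    Defaults describe a modestly diverged within-species protein family
    collection: 8 families of 6 rows, 80-residue ancestors, 5% per-site
    substitution rate and 2% gap-open probability with geometric (p=0.7)
    indel lengths. ``disjoint_k`` forces families to share no k-mer of that
    length (0 disables the check). DNA indels are separated by at least
    ``dna_indel_spacing`` nucleotides so seed matching survives around them.
    """

    seed: int = 42
    n_families: int = 8
    rows_per_family: int = 6
    length: int = 80
    substitution_rate: float = 0.05
    gap_open_prob: float = 0.02
    indel_extend_prob: float = 0.3
    query_count: int = 20
    dna_indel_count: int = 1
    dna_indel_spacing: int = 20
    disjoint_k: int = 5


def example_msa() -> Msa:
    """The three-row worked-example MSA used throughout the documentation."""
    return Msa(
        msa_id="example",
        row_names=["seq1", "seq2", "seq3"],
        rows=["-MEPTPEQ", "---T--MA", "MSETQSTQ"],
    )


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(_AA20), size=length))


def _geom_len(rng: np.random.Generator, extend_prob: float) -> int:
    n = 1
    while rng.random() < extend_prob:
        n += 1
    return n


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def make_family(
    spec: FixtureSpec, rng: np.random.Generator, family_id: str, ancestor: str | None = None
) -> Msa:
    """One aligned family: ancestor mutated per row in alignment coordinates.

    Substitutions replace a residue, deletions replace it with a gap, and
    insertions splice new columns (gap in every other row). A row that would
    end up all-gap keeps the ancestor instead (degenerate-input guard).
    """
    if ancestor is None:
        ancestor = _random_protein(rng, spec.length)
    rows: list[list[str]] = []
    insertions: list[tuple[int, int, str]] = []  # (row, anchor column, seq)
    for r in range(spec.rows_per_family):
        row = list(ancestor)
        for pos in range(len(row)):
            u = rng.random()
            if u < spec.substitution_rate:
                row[pos] = _AA20[rng.integers(len(_AA20))]
            if rng.random() < spec.gap_open_prob:
                for d in range(pos, min(len(row), pos + _geom_len(rng, spec.indel_extend_prob))):
                    row[d] = "-"
            if rng.random() < spec.gap_open_prob:
                ins = _random_protein(rng, _geom_len(rng, spec.indel_extend_prob))
                insertions.append((r, pos, ins))
        if all(c == "-" for c in row):
            row = list(ancestor)
        rows.append(row)

    # splice insertion columns, rightmost anchors first so positions stay valid
    for r, pos, ins in sorted(insertions, key=lambda t: -t[1]):
        for ri in range(len(rows)):
            block = list(ins) if ri == r else ["-"] * len(ins)
            rows[ri][pos:pos] = block

    return Msa(
        msa_id=family_id,
        row_names=[f"{family_id}_row{r}" for r in range(spec.rows_per_family)],
        rows=["".join(row) for row in rows],
    )


def make_panproteome(spec: FixtureSpec) -> list[Msa]:
    """Generate ``n_families`` families, pairwise k-mer disjoint if requested.

    Disjointness is enforced on the realized rows by rejection sampling; a
    family whose k-mer set intersects any earlier family's is regenerated.
    """
    rng = np.random.default_rng(spec.seed)
    msas: list[Msa] = []
    used: set[str] = set()
    for f in range(spec.n_families):
        for _attempt in range(1000):
            msa = make_family(spec, rng, f"fam{f:03d}")
            if spec.disjoint_k <= 0:
                break
            kset: set[str] = set()
            for row in msa.degapped_rows().values():
                kset |= _kmers(row, spec.disjoint_k)
            if not (kset & used):
                used |= kset
                break
        else:
            raise RuntimeError("could not generate a k-mer-disjoint family")
        msas.append(msa)
    return msas


def back_translate(protein: str) -> str:
    """Deterministic codon back-translation of a protein sequence."""
    return "".join(PREFERRED_CODON[c] for c in protein)


def _plant_indels(
    dna: str, rng: np.random.Generator, count: int, spacing: int
) -> tuple[str, list[str]]:
    """Plant ``count`` single-nucleotide indels separated by > ``spacing`` nt."""
    if count == 0:
        return dna, []
    events: list[str] = []
    positions: list[int] = []
    lo, hi = spacing, len(dna) - spacing
    for _attempt in range(10000):
        p = int(rng.integers(lo, max(lo + 1, hi)))
        if all(abs(p - q) > spacing for q in positions):
            positions.append(p)
            if len(positions) == count:
                break
    positions.sort(reverse=True)
    out = dna
    for p in positions:
        if rng.random() < 0.5:
            base = "ACGT"[rng.integers(4)]
            out = out[:p] + base + out[p:]
            events.append(f"ins@{p}")
        else:
            out = out[:p] + out[p + 1 :]
            events.append(f"del@{p}")
    return out, list(reversed(events))


def make_queries(
    msas: list[Msa], spec: FixtureSpec
) -> tuple[list[tuple[str, str, str]], list[tuple[str, str, str, list[str]]]]:
    """Draw queries from the panproteome rows.

    Returns ``(aa_queries, dna_queries)``. Each amino-acid query is a
    degapped row, as ``(query_name, sequence, source_msa_id)``. Each DNA
    query is its back-translation with planted indels, as ``(query_name,
    dna, source_msa_id, planted_events)``; the header-style name encodes
    the source family and the planted indels.
    """
    rng = np.random.default_rng(spec.seed + 1)
    pool: list[tuple[str, str, str]] = []
    for msa in msas:
        for name, row in msa.degapped_rows().items():
            pool.append((name, row, msa.msa_id))
    take = min(spec.query_count, len(pool))
    picks = rng.choice(len(pool), size=take, replace=False)
    aa_queries: list[tuple[str, str, str]] = []
    dna_queries: list[tuple[str, str, str, list[str]]] = []
    for qi, pi in enumerate(sorted(int(p) for p in picks)):
        row_name, seq, src = pool[pi]
        qname = f"q{qi:04d}|src={src}|row={row_name}"
        aa_queries.append((qname, seq, src))
        dna = back_translate(seq)
        dna, events = _plant_indels(dna, rng, spec.dna_indel_count, spec.dna_indel_spacing)
        dname = f"q{qi:04d}|src={src}|planted={','.join(events) if events else 'none'}"
        dna_queries.append((dname, dna, src, events))
    return aa_queries, dna_queries


def write_fixture_set(spec: FixtureSpec, out_dir: str | os.PathLike) -> dict[str, str]:
    """Materialize MSA FASTA files, query FASTA files and a ground-truth TSV.

    Returns a map of logical name -> written path.
    """
    out_dir = os.fspath(out_dir)
    msa_dir = os.path.join(out_dir, "msas")
    os.makedirs(msa_dir, exist_ok=True)
    msas = make_panproteome(spec)
    for msa in msas:
        with open(os.path.join(msa_dir, f"{msa.msa_id}.fasta"), "w") as fh:
            for name, row in zip(msa.row_names, msa.rows):
                fh.write(f">{name}\n{row}\n")
    aa_queries, dna_queries = make_queries(msas, spec)
    aa_path = os.path.join(out_dir, "queries_aa.fasta")
    with open(aa_path, "w") as fh:
        for qname, seq, _src in aa_queries:
            fh.write(f">{qname}\n{seq}\n")
    dna_path = os.path.join(out_dir, "queries_dna.fasta")
    with open(dna_path, "w") as fh:
        for qname, dna, _src, _ev in dna_queries:
            fh.write(f">{qname}\n{dna}\n")
    truth_path = os.path.join(out_dir, "ground_truth.tsv")
    with open(truth_path, "w") as fh:
        fh.write("query\tsource_msa\tplanted_indels\n")
        for qname, _seq, src in aa_queries:
            fh.write(f"{qname}\t{src}\t0\n")
        for qname, _dna, src, ev in dna_queries:
            fh.write(f"{qname}\t{src}\t{len(ev)}\n")
    return {
        "msa_dir": msa_dir,
        "queries_aa": aa_path,
        "queries_dna": dna_path,
        "ground_truth": truth_path,
    }
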