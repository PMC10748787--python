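"""Multiple sequence alignments as rectangular character matrices.

An :class:`Msa` is the unit of panproteome membership: one aligned protein
family (rows over the 20 amino acids plus ``X``/``*`` and the gap character
``-``), read from an aligned FASTA file.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

from Bio import SeqIO

#: Amino-acid alphabet accepted in MSA rows. ``X`` (unknown residue) and
#: ``*`` (stop) are accepted as ordinary symbols: real proteomes contain
#: them and the graph construction is alphabet-agnostic.
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY") | {"X", "*"}
GAP = "-"
MSA_ALPHABET = AMINO_ACIDS | {GAP}


class MsaError(ValueError):
    """Raised for malformed MSA input (ragged rows, bad characters...)."""


@dataclass
class Msa:
    """A rectangular MSA: ``n`` named rows of length ``m`` over amino acids + gap."""

    msa_id: str
    row_names: list[str]
    rows: list[str] = field(repr=False)

    def __post_init__(self) -> None:
        if not self.rows:
            raise MsaError(f"MSA {self.msa_id!r} has no rows")
        m = len(self.rows[0])
        if m == 0:
            raise MsaError(f"MSA {self.msa_id!r} has zero columns")
        for name, row in zip(self.row_names, self.rows):
            if len(row) != m:
                raise MsaError(
                    f"MSA {self.msa_id!r} is not rectangular: row {name!r} has "
                    f"length {len(row)}, expected {m}"
                )
            bad = set(row) - MSA_ALPHABET
            if bad:
                raise MsaError(
                    f"MSA {self.msa_id!r} row {name!r} contains characters "
                    f"outside the amino-acid alphabet: {sorted(bad)}"
                )
        if len(set(self.row_names)) != len(self.row_names):
            dupes = sorted({n for n in self.row_names if self.row_names.count(n) > 1})
            raise MsaError(f"MSA {self.msa_id!r} has duplicate row names: {dupes}")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0])

    def degapped_rows(self) -> dict[str, str]:
        """Row name -> row with gap characters removed."""
        return {name: row.replace(GAP, "") for name, row in zip(self.row_names, self.rows)}


def read_msa_fasta(path: str | os.PathLike) -> Msa:
    """Read one aligned FASTA file into an :class:`Msa`.

    Records may wrap lines; characters are upper-cased. The MSA id is the
    file stem (extension stripped).
    """
    path = os.fspath(path)
    names: list[str] = []
    rows: list[str] = []
    for record in SeqIO.parse(path, "fasta"):
        names.append(record.id)
        rows.append(str(record.seq).upper())
    stem = os.path.splitext(os.path.basename(path))[0]
    if not rows:
        raise MsaError(f"no FASTA records found in {path!r}")
    return Msa(msa_id=stem, row_names=names, rows=rows)
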