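"""Seed extraction and the seed -> MSA index.

Every MSA row (gaps removed) is decomposed into seeds: either all
consecutive k-mers, or (w,k)-minimizers — the lexicographically smallest
k-mer of each window of w consecutive k-mers, computed with a monotone-deque
sliding-window minimum in linear time.

The global index maps each seed to the list of MSAs containing it, ordered
by descending *normalized count*: occurrences of the seed across all rows of
the MSA divided by the MSA's row count. A per-seed cutoff (``seed_limit``)
optionally truncates each list to the top entries, trading sensitivity for
index size and alignment speed.
"""

from __future__ import annotations

import os
import pickle
import warnings
from collections import Counter, deque
from dataclasses import dataclass, field

from .msa import Msa

_FORMAT_MAGIC = "proteograph-seed-index"
_FORMAT_VERSION = 1


class IndexError_(ValueError):
    """Raised for malformed or incompatible index files."""


@dataclass(frozen=True)
class SeedParams:
    """Seeding scheme: k-mer length, window size and mode.

    ``mode="kmer"`` ignores ``w``; ``mode="minimizer"`` with ``w=1`` is
    equivalent to the plain k-mer index.
    """

    k: int = 5
    w: int = 1
    mode: str = "kmer"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if self.w < 1:
            raise ValueError(f"w must be >= 1, got {self.w}")
        if self.mode not in ("kmer", "minimizer"):
            raise ValueError(f"mode must be 'kmer' or 'minimizer', got {self.mode!r}")


def extract_kmers(seq: str, k: int) -> list[str]:
    """All consecutive k-mers of ``seq``, in order (empty if len(seq) < k)."""
    return [seq[i : i + k] for i in range(len(seq) - k + 1)]


def extract_minimizers(seq: str, params: SeedParams) -> list[str]:
    """(w,k)-minimizers of ``seq`` via a monotone-deque window minimum.

    Consecutive windows selecting the same k-mer instance (position) emit
    it once; ties within a window resolve to the rightmost occurrence.
    With w=1 this reproduces :func:`extract_kmers` exactly, duplicates
    included. Sequences shorter than k+w-1 but at least k long yield their
    single lexicographically smallest k-mer; shorter sequences yield
    nothing. Runs in O(len(seq)) deque operations.
    """
    k, w = params.k, params.w
    n_kmers = len(seq) - k + 1
    if n_kmers <= 0:
        return []
    if n_kmers < w:
        return [min(extract_kmers(seq, k))]
    out: list[str] = []
    last_pos = -1
    dq: deque[int] = deque()  # positions of candidate minima, values increasing
    for i in range(n_kmers):
        kmer = seq[i : i + k]
        while dq and seq[dq[-1] : dq[-1] + k] >= kmer:
            dq.pop()
        dq.append(i)
        if dq[0] <= i - w:
            dq.popleft()
        if i >= w - 1 and dq[0] != last_pos:
            last_pos = dq[0]
            out.append(seq[last_pos : last_pos + k])
    return out


def seeds_of(seq: str, params: SeedParams) -> list[str]:
    """Seeds of a gap-free sequence under the given scheme."""
    if params.mode == "minimizer":
        return extract_minimizers(seq, params)
    return extract_kmers(seq, params.k)


@dataclass
class SeedIndex:
    """Map seed -> ordered (optionally truncated) list of MSA ids."""

    params: SeedParams
    entries: dict[str, list[str]] = field(default_factory=dict)
    seed_limit: int = 0  # 0 = unlimited

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SeedIndex):
            return NotImplemented
        return (
            self.params == other.params
            and self.seed_limit == other.seed_limit
            and self.entries == other.entries
        )


def normalized_counts(msas: list[Msa], params: SeedParams) -> dict[str, dict[str, float]]:
    """Seed -> {msa_id: occurrences across all rows / row count}.

    Occurrences include duplicates within a row. This is the sort key for
    the index value lists; it is computed here and discarded after ordering.
    """
    table: dict[str, dict[str, float]] = {}
    for msa in msas:
        counts: Counter[str] = Counter()
        for row in msa.degapped_rows().values():
            counts.update(seeds_of(row, params))
        for seed, c in counts.items():
            table.setdefault(seed, {})[msa.msa_id] = c / msa.n_rows
    return table


def build_index(msas: list[Msa], params: SeedParams, seed_limit: int = 0) -> SeedIndex:
    """Build the global seed index over a collection of MSAs.

    Each seed's MSA list is sorted by descending normalized count, ties
    broken by ascending msa_id, then truncated to ``seed_limit`` entries
    when the limit is positive.
    """
    if seed_limit < 0:
        raise ValueError(f"seed_limit must be >= 0, got {seed_limit}")
    table = normalized_counts(msas, params)
    entries: dict[str, list[str]] = {}
    for seed, per_msa in table.items():
        ranked = sorted(per_msa.items(), key=lambda kv: (-kv[1], kv[0]))
        ids = [msa_id for msa_id, _ in ranked]
        if seed_limit > 0:
            ids = ids[:seed_limit]
        entries[seed] = ids
    if not entries:
        warnings.warn(
            f"no seeds extracted (k={params.k} may exceed every degapped row)",
            stacklevel=2,
        )
    return SeedIndex(params=params, entries=entries, seed_limit=seed_limit)


def save_index(idx: SeedIndex, path: str | os.PathLike) -> None:
    """Persist an index as a versioned binary container."""
    payload = {
        "magic": _FORMAT_MAGIC,
        "version": _FORMAT_VERSION,
        "params": {"k": idx.params.k, "w": idx.params.w, "mode": idx.params.mode},
        "seed_limit": idx.seed_limit,
        "entries": idx.entries,
    }
    with open(path, "wb") as fh:
        pickle.dump(payload, fh, protocol=pickle.HIGHEST_PROTOCOL)


def load_index(path: str | os.PathLike) -> SeedIndex:
    """Load an index written by :func:`save_index`; rejects other versions."""
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    if not isinstance(payload, dict) or payload.get("magic") != _FORMAT_MAGIC:
        raise IndexError_(f"{os.fspath(path)!r} is not a seed-index file")
    if payload.get("version") != _FORMAT_VERSION:
        raise IndexError_(
            f"index format version {payload.get('version')} unsupported "
            f"(expected {_FORMAT_VERSION})"
        )
    return SeedIndex(
        params=SeedParams(**payload["params"]),
        entries=payload["entries"],
        seed_limit=payload["seed_limit"],
    )
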