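from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("derandomized", derandomize=True, deadline=None)
settings.load_profile("derandomized")

from proteograph import Msa, build_graph_from_msa, compact_graph
from proteograph.fixtures import example_msa

AA20 = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture
def toy_msa() -> Msa:
    """Three-row worked-example MSA (rows -MEPTPEQ, ---T--MA, MSETQSTQ)."""
    return example_msa()


@pytest.fixture
def toy_graph(toy_msa):
    return build_graph_from_msa(toy_msa)


@pytest.fixture
def toy_compacted(toy_graph):
    return compact_graph(toy_graph)


def random_msa(rng: np.random.Generator, n_rows: int, n_cols: int,
               alphabet: str = AA20, gap_prob: float = 0.2) -> Msa:
    """Random rectangular MSA with at least one non-gap character per row."""
    rows = []
    for r in range(n_rows):
        while True:
            row = "".join(
                "-" if rng.random() < gap_prob else alphabet[rng.integers(len(alphabet))]
                for _ in range(n_cols)
            )
            if row.strip("-"):
                break
        rows.append(row)
    return Msa(msa_id="rand", row_names=[f"r{i}" for i in range(n_rows)], rows=rows)


def random_protein(rng: np.random.Generator, length: int, alphabet: str = AA20) -> str:
    return "".join(alphabet[rng.integers(len(alphabet))] for _ in range(length))
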