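import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from proteograph import (
    Msa,
    SeedIndex,
    SeedParams,
    build_index,
    extract_kmers,
    extract_minimizers,
    load_index,
    normalized_counts,
    save_index,
)
from proteograph.index import IndexError_, seeds_of

from conftest import random_protein
from oracles import naive_minimizers

aa_text = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=0, max_size=40)


class TestKmers:
    def test_counts_and_order(self):
        assert extract_kmers("MEPTP", 3) == ["MEP", "EPT", "PTP"]

    def test_short_sequence_yields_nothing(self):
        assert extract_kmers("MT", 3) == []

    def test_k1_is_the_characters(self):
        assert extract_kmers("MEP", 1) == list("MEP")

    @given(seq=aa_text, k=st.integers(1, 8))
    @settings(max_examples=50, deadline=None)
    def test_count_formula(self, seq, k):
        assert len(extract_kmers(seq, k)) == max(0, len(seq) - k + 1)


class TestMinimizers:
    def test_windows_by_hand(self):
        params = SeedParams(k=2, w=2, mode="minimizer")
        assert extract_minimizers("ACDCA", params) == ["AC", "CD", "CA"]

    def test_w1_equals_kmers(self):
        seq = "MSETQSTQMEPTPEQ"
        params = SeedParams(k=3, w=1, mode="minimizer")
        assert extract_minimizers(seq, params) == extract_kmers(seq, 3)

    def test_short_sequence_fallback(self):
        params = SeedParams(k=3, w=4, mode="minimizer")
        # 4 residues -> 2 k-mers < w: emit the single smallest
        assert extract_minimizers("DCBA"[:4].replace("B", "W"), params) == [
            min(extract_kmers("DCWA", 3))
        ]
        assert extract_minimizers("MT", params) == []

    @given(seq=aa_text, k=st.integers(1, 5), w=st.integers(1, 6))
    @settings(max_examples=200, deadline=None)
    def test_deque_equals_naive_oracle(self, seq, k, w):
        params = SeedParams(k=k, w=w, mode="minimizer")
        assert extract_minimizers(seq, params) == naive_minimizers(seq, k, w)

    @given(seq=aa_text, k=st.integers(1, 5), w=st.integers(1, 6))
    @settings(max_examples=100, deadline=None)
    def test_minimizers_subset_of_kmers(self, seq, k, w):
        params = SeedParams(k=k, w=w, mode="minimizer")
        assert set(extract_minimizers(seq, params)) <= set(extract_kmers(seq, k))


def three_msa_example():
    """Three MSAs of 10/7/3 rows in which the seed MEP occurs 2/4/3 times."""

    def msa(msa_id, n_rows, n_with_seed, extra=0):
        rows = []
        for i in range(n_rows):
            base = "WGHKLNQRVY"[i % 10] * 6
            rows.append("MEP" + base if i < n_with_seed else "AAA" + base)
        # 'extra' rows carry the seed twice
        for i in range(extra):
            rows[i] = "MEPMEP" + rows[i][6:]
        return Msa(msa_id, [f"r{i}" for i in range(n_rows)], rows)

    m1 = msa("m1", 10, 2)
    m2 = msa("m2", 7, 4)
    m3 = msa("m3", 3, 3)
    return [m1, m2, m3]


class TestBuildIndex:
    def test_normalized_counts(self):
        msas = three_msa_example()
        table = normalized_counts(msas, SeedParams(k=3))
        assert table["MEP"] == {"m1": 2 / 10, "m2": 4 / 7, "m3": 3 / 3}

    def test_cutoff_two_keeps_top_two(self):
        idx = build_index(three_msa_example(), SeedParams(k=3), seed_limit=2)
        assert idx.entries["MEP"] == ["m3", "m2"]

    def test_unlimited_keeps_all_in_order(self):
        idx = build_index(three_msa_example(), SeedParams(k=3), seed_limit=0)
        assert idx.entries["MEP"] == ["m3", "m2", "m1"]

    def test_single_row_single_seed(self):
        msa = Msa("only", ["r0"], ["MEP"])
        idx = build_index([msa], SeedParams(k=3))
        assert idx.entries == {"MEP": ["only"]}

    def test_ties_break_on_msa_id(self):
        a = Msa("b_msa", ["r0"], ["MEP"])
        b = Msa("a_msa", ["r0"], ["MEP"])
        idx = build_index([a, b], SeedParams(k=3))
        assert idx.entries["MEP"] == ["a_msa", "b_msa"]

    def test_k_too_large_warns_and_is_empty(self):
        msa = Msa("tiny", ["r0"], ["MT"])
        with pytest.warns(UserWarning, match="no seeds"):
            idx = build_index([msa], SeedParams(k=9))
        assert idx.entries == {}

    def test_gaps_removed_before_seeding(self):
        msa = Msa("gappy", ["r0"], ["M-E-P"])
        idx = build_index([msa], SeedParams(k=3))
        assert "MEP" in idx.entries


class TestPersistence:
    def test_worked_example_round_trip(self, tmp_path):
        idx = build_index(three_msa_example(), SeedParams(k=3), seed_limit=2)
        p = tmp_path / "idx.bin"
        save_index(idx, p)
        assert load_index(p) == idx

    def test_empty_index_round_trip(self, tmp_path):
        idx = SeedIndex(params=SeedParams(k=4, w=2, mode="minimizer"), entries={})
        p = tmp_path / "empty.bin"
        save_index(idx, p)
        assert load_index(p) == idx

    def test_large_random_index_round_trip(self, tmp_path):
        rng = np.random.default_rng(7)
        entries = {
            random_protein(rng, 5): [f"m{int(i)}" for i in rng.integers(0, 50, size=3)]
            for _ in range(10_000)
        }
        idx = SeedIndex(params=SeedParams(k=5), entries=entries, seed_limit=3)
        p = tmp_path / "big.bin"
        save_index(idx, p)
        assert load_index(p) == idx

    def test_bad_file_is_rejected(self, tmp_path):
        p = tmp_path / "junk.bin"
        import pickle

        p.write_bytes(pickle.dumps({"magic": "something-else"}))
        with pytest.raises(IndexError_, match="not a seed-index"):
            load_index(p)


@given(seq=aa_text, k=st.integers(1, 5))
@settings(max_examples=50, deadline=None)
def test_kmer_mode_ignores_w(seq, k):
    assert seeds_of(seq, SeedParams(k=k, w=7, mode="kmer")) == extract_kmers(seq, k)
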