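import numpy as np
import pytest

from proteograph import (
    AlignConfig,
    Msa,
    SeedParams,
    align_protein,
    build_graph_from_msa,
    build_index,
    compact_graph,
    compute_identity,
    select_candidates,
)
from proteograph.align import AlignmentError, GraphAlignment, layout
from proteograph.graph import ProteinGraph

from conftest import random_msa, random_protein
from oracles import all_path_spellings, smith_waterman, sub62

CFG = AlignConfig()  # BLOSUM62, linear gap -3


def single_node_graph(label: str) -> ProteinGraph:
    return ProteinGraph(
        graph_id="single", nodes={1: label}, edges=set(), paths={"r0": [1]},
        column_of={1: 0},
    )


class TestLayout:
    def test_single_node(self):
        lay = layout(single_node_graph("MT"))
        assert lay.target == "MT"
        assert lay.incoming_of[1] == [0]
        assert lay.incoming_of[2] == [1]

    def test_chain_of_two_nodes(self):
        g = ProteinGraph("g", {1: "ME", 2: "PT"}, {(1, 2)},
                         {"r0": [1, 2]}, {1: 0, 2: 2})
        lay = layout(g)
        assert lay.target == "MEPT"
        assert lay.incoming_of[3] == [2]  # first column of node 2 <- last of node 1

    def test_diamond_merge_column_has_two_predecessors(self):
        g = ProteinGraph(
            "g",
            {1: "M", 2: "E", 3: "T", 4: "Q"},
            {(1, 2), (1, 3), (2, 4), (3, 4)},
            {"a": [1, 2, 4], "b": [1, 3, 4]},
            {1: 0, 2: 1, 3: 1, 4: 2},
        )
        lay = layout(g)
        q_col = lay.target.index("Q") + 1
        assert len(lay.incoming_of[q_col]) == 2

    def test_edges_go_forward(self, toy_compacted):
        lay = layout(toy_compacted)
        pos = {u: i for i, u in enumerate(lay.order)}
        for a, b in toy_compacted.edges:
            assert pos[a] < pos[b]


class TestProteinAlignment:
    def test_exact_path_query(self, toy_compacted):
        """A query equal to a full path spelling aligns at identity 1.0 with
        score equal to the sum of its diagonal substitution scores."""
        aln = align_protein("MSETQSTQ", toy_compacted, CFG)
        assert aln.identity == 1.0
        assert aln.score == sum(sub62(c, c) for c in "MSETQSTQ")
        spelled = "".join(toy_compacted.nodes[v] for v in aln.node_path)
        assert spelled == "MSETQSTQ"
        assert aln.node_path == toy_compacted.paths["seq3"]

    @pytest.mark.parametrize("seed", range(25))
    def test_single_node_reduces_to_smith_waterman(self, seed):
        rng = np.random.default_rng(seed)
        target = random_protein(rng, int(rng.integers(5, 25)))
        query = random_protein(rng, int(rng.integers(3, 20)))
        aln = align_protein(query, single_node_graph(target), CFG)
        expected = smith_waterman(query, target, gap=CFG.gap_penalty)
        got = aln.score if aln else 0
        assert got == expected

    @pytest.mark.parametrize("seed", range(60))
    def test_graph_dp_equals_best_path_smith_waterman(self, seed):
        """On small DAGs the graph-aware score equals the max classical
        score over all source-to-sink path spellings."""
        rng = np.random.default_rng(1000 + seed)
        msa = random_msa(rng, int(rng.integers(2, 4)), int(rng.integers(4, 9)),
                         alphabet="ACDEF", gap_prob=0.25)
        g = compact_graph(build_graph_from_msa(msa))
        query = random_protein(rng, int(rng.integers(3, 12)), alphabet="ACDEFGH")
        aln = align_protein(query, g, CFG)
        got = aln.score if aln else 0
        assert got == max(
            smith_waterman(query, s, gap=CFG.gap_penalty) for s in all_path_spellings(g)
        )

    def test_local_floor_monotonicity(self):
        """Extending a path's label never decreases the optimal local score."""
        rng = np.random.default_rng(5)
        base = random_protein(rng, 12)
        query = random_protein(rng, 8)
        s_short = align_protein(query, single_node_graph(base), CFG)
        s_long = align_protein(query, single_node_graph(base + "WYK"), CFG)
        short_score = s_short.score if s_short else 0
        long_score = s_long.score if s_long else 0
        assert long_score >= short_score

    def test_unknown_query_character_raises(self, toy_compacted):
        with pytest.raises(AlignmentError, match="J"):
            align_protein("MJT", toy_compacted, CFG)

    def test_min_identity_filter(self, toy_compacted):
        # internal mismatch (W for Q) caps identity at 7/8
        strict = AlignConfig(min_identity=0.95)
        assert align_protein("MSETWSTQ", toy_compacted, strict) is None
        assert align_protein("MSETWSTQ", toy_compacted, CFG) is not None

    def test_min_len_frac_filter(self, toy_compacted):
        # only half of the query can align
        q = "MSETQSTQ" + "W" * 8
        assert align_protein(q, toy_compacted, AlignConfig(min_len_frac=0.9)) is None
        assert align_protein(q, toy_compacted, AlignConfig(min_len_frac=0.4)) is not None

    def test_deterministic_output(self, toy_compacted):
        a = align_protein("MSETQSTQ", toy_compacted, CFG)
        b = align_protein("MSETQSTQ", toy_compacted, CFG)
        assert a == b


class TestIdentity:
    def make(self, cigar, matches, n_columns):
        return GraphAlignment(
            query_name="q", graph_id="g", score=1, node_path=[1],
            query_interval=(0, 1), path_interval=(0, 1), cigar=cigar,
            identity=matches / n_columns, matches=matches, n_columns=n_columns,
        )

    def test_perfect_match(self):
        assert compute_identity(self.make("10=", 10, 10)) == 1.0

    def test_half_mismatched(self):
        assert compute_identity(self.make("5=5X", 5, 10)) == 0.5

    def test_gap_columns_count_in_denominator(self):
        assert compute_identity(self.make("8=1X1D", 8, 10)) == 0.8


class TestCandidateSelection:
    def build(self):
        msas = [
            Msa("m1", ["r0"], ["MEPTPWKV"]),
            Msa("m3", ["r0"], ["HNQRYCDG"]),
        ]
        return build_index(msas, SeedParams(k=4), seed_limit=0)

    def test_ranked_by_hits_and_truncated(self):
        idx = self.build()
        # query shares 4 seeds with m1 and 1 with m3
        query = "MEPTPWK" + "XXX" + "HNQR"
        cfg1 = AlignConfig(align_limit=1)
        assert select_candidates(query, idx, cfg1) == ["m1"]
        cfg0 = AlignConfig(align_limit=0)
        assert select_candidates(query, idx, cfg0) == ["m1", "m3"]

    def test_no_hits_is_empty(self):
        idx = self.build()
        assert select_candidates("WWWWWWWW", idx, CFG) == []
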