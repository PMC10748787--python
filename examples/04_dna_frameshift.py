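"""Align DNA directly to a protein graph, recovering a planted frameshift.

A path spelling is back-translated to DNA and aligned: clean DNA aligns at
identity 1.0 with zero frameshift jumps. Inserting one nucleotide breaks
the reading frame; the frameshift-aware DP absorbs it as a single 4-nt
diagonal jump (cigar op F) instead of losing the downstream alignment.
"""

from proteograph import AlignConfig, align_dna_frameshift, build_graph_from_msa, compact_graph
from proteograph.fixtures import back_translate, example_msa

graph = compact_graph(build_graph_from_msa(example_msa()))
cfg = AlignConfig()  # frameshift penalty -4

dna = back_translate("MSETQSTQ")
print(f"clean back-translation ({len(dna)} nt):")
aln = align_dna_frameshift(dna, graph, cfg)
print(f"  score={aln.score}  identity={aln.identity:.3f}  "
      f"frameshifts={aln.frameshift_count}  cigar={aln.cigar}")

mutated = dna[:10] + "A" + dna[10:]
print("with one inserted nucleotide:")
aln = align_dna_frameshift(mutated, graph, cfg)
print(f"  score={aln.score}  identity={aln.identity:.3f}  "
      f"frameshifts={aln.frameshift_count}  cigar={aln.cigar}")
print("  the single F op is the insertion frameshift jump (4 nt vs 1 residue)")
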