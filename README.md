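# proteograph

Panproteome graphs for prokaryotes: build one directed acyclic sequence
graph per protein family from its multiple sequence alignment, index all
families by k-mer or minimizer seeds, and locally align amino-acid — or,
frameshift-aware, DNA — queries against the best-matching graphs.

## Why

Bacterial genomes are too diverse for a single linear DNA reference:
non-reference alleles cause missing or wrong alignments, and between
genera DNA similarity often collapses entirely. Amino-acid sequences are
far more conserved (synonymous codons hide many DNA mutations, and the
20-letter alphabet carries more signal), and coding regions cover most of
a prokaryotic genome. A *panproteome* — a collection of small graphs, one
per protein or protein cluster — therefore supports comparisons across
much larger phylogenetic distances than a DNA pangenome, while losing
little of the genome.

`proteograph` is for anyone who has protein-family MSAs (e.g. from
clustering annotated proteomes) and wants to align new protein sequences,
or raw DNA reads, against the whole collection.

## The method

**MSA → DAG.** For an MSA `M ∈ {A ∪ -}^{n×m}` each column `j` contributes
one node per distinct non-gap character `c` (node_j(c)); an edge
`node_{j1}(c1) → node_{j2}(c2)` is drawn iff `c1, c2` are consecutive in
some row once gaps are skipped (so edges may bridge gap runs). Each row
becomes a named path; construction is O(n·m) and the graph is acyclic by
the left-to-right sweep. Linear stretches are compacted into single nodes,
but only where the identical set of paths traverses every merged
adjacency — otherwise some row could no longer be written as a GFA path.
Graphs are stored as GFA1 with one `P` line per original sequence.

**Seed index.** Seeds are all k-mers of every degapped row, or
(w,k)-minimizers (the lexicographically smallest k-mer per window of `w`
k-mers, via a linear-time monotone deque). The index maps each seed to the
MSAs containing it, ordered by the seed's occurrence count in the MSA
normalized by the MSA's row count, optionally truncated to the top
`seed_limit` entries.

**Alignment.** Candidate graphs per query are ranked by seed-hit count.
Each graph is topologically sorted; concatenating node labels gives the
target `N`, and a local DP (score floor 0, substitution matrix `sub`,
linear gap `Δ`) generalizes Smith–Waterman: where a target column starts a
node, the recurrence maximizes over the last columns `p_l` of all
predecessor nodes,

```
H[i,j] = max over p_l of max( H[i-1,p_l] + sub(N[p_l..j-1], q[i-1]),
                              H[i-1,j] + Δ,  H[i,p_l] + Δ,  0 )
```

For DNA, rows are nucleotides: a codon diagonal consumes 3 nt against one
residue (scored on the translated codon), and two extra jumps consuming
4 or 2 nt against one residue — each at frameshift penalty `σ` — absorb a
single-nucleotide insertion or deletion without losing the downstream
alignment. Both strands are tried; candidates come from seeds of all six
translated frames. Alignments are reported as GAF records with score,
identity, frame and frameshift-count tags.

## Worked example

`python examples/01_build_graph.py` builds the toy MSA

```
seq1: -MEPTPEQ
seq2: ---T--MA
seq3: MSETQSTQ
```

into 15 single-residue nodes / 15 edges, which compact to 8 nodes
(`{1: 'MS', 2: 'M', 3: 'E', 4: 'PTPE', 5: 'T', 6: 'QST', 7: 'MA', 8: 'Q'}`)
whose paths spell exactly the degapped rows (`seq2: 5 -> 7 = TMA`). The
stretch P→T→P→E merges into the single node `PTPE`; seq2's T at column 4
connects straight to the M at column 7, bridging the gap run.

`python examples/02_seed_index.py` indexes three MSAs of 10/7/3 rows in
which the seed `MEP` occurs 2/4/3 times: normalized counts 0.20, 0.57 and
1.00, so with a cutoff of two the entry for `MEP` is `['m3', 'm2']` — the
small MSA where every row carries the seed outranks the large one where it
is rare.

`python examples/04_dna_frameshift.py` back-translates the path spelling
`MSETQSTQ` (24 nt) and aligns it: score 38, identity 1.000, 0 frameshifts.
With one inserted nucleotide the aligner reports score 29, identity 0.875,
`frameshifts=1`, cigar `2=1F5=`: the `F` op is a 4-nt diagonal jump paying
the frameshift penalty while keeping the rest of the alignment in frame.

## Command line

```bash
proteograph build_gfa   --in-dir MSAS/ --out-dir GFAS/
proteograph build_index --in-dir MSAS/ --seeding minimizer -k 5 -w 3 --seed-limit 0 -o index.bin
proteograph align       --in-dir GFAS/ --index index.bin -q queries.fa --type aa -o out.gaf
proteograph fixtures    --spec spec.yaml --out-dir fixtures/
```

Outputs are deterministic: identical inputs and flags give byte-identical
GFA, index and GAF files, regardless of thread count.

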