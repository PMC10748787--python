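# Methods

## Model and assumptions

A panproteome is modeled as a collection of independent sequence graphs,
one per protein family, each derived from that family's MSA. The MSA is
trusted as given: the graph encodes exactly the homology statements the
alignment makes (characters in one column are alternatives; consecutive
non-gap characters in one row are adjacent). No realignment, trimming or
consensus-calling is performed. Graphs are acyclic by construction —
duplications or rearrangements within a family are not representable, and
each row must spell as a simple path.

### MSA → DAG construction

Columns are swept left to right (0-based internally; narrative
descriptions of such constructions often count columns from 1 — the
mapping is column `j` here = column `j+1` there). Per column, one node per
distinct non-gap character; per row, an edge between each pair of
consecutive non-gap characters, bridging gap runs. Properties relied on
elsewhere:

- all-gap columns produce no nodes; all-gap rows are an error (their path
  would be empty);
- `X` (unknown) and `*` (stop) are ordinary alphabet symbols — real
  proteomes contain both and the construction is alphabet-agnostic;
- edges form a set: an adjacency shared by many rows appears once;
- node ids are positive integers in construction order, renumbered
  consecutively (topological order) after compaction, so outputs are
  byte-stable for golden-file comparison.

### Compaction

Adjacent nodes `u → v` merge when `u` has out-degree 1, `v` in-degree 1,
and the identical set of paths traverses both. The path-set condition is
strictly stronger than degree linearity and is what preserves the GFA
path encoding: in the chain built from rows `MTQT`, `--QT`, `MT--`, all
four single-character nodes are degree-linear, but only `M+T` and `Q+T`
may merge — a four-way merge would leave rows 2 and 3 unwritable as
paths. Compaction is idempotent and never increases node, edge or
path-step counts; maximal chains are found in one topological sweep.

## Seeding and the index

Seeds are extracted from degapped rows. Two schemes:

- **k-mer**: all `m−k+1` consecutive k-mers;
- **minimizer**: per window of `w` consecutive k-mers, the
  lexicographically smallest (plain byte order on upper-case letters, no
  alphabet reweighting), computed with a monotone deque in O(m).

Minimizer convention: ties within a window resolve to the rightmost
occurrence, and consecutive windows selecting the same k-mer *instance*
emit it once. Deduplicating by instance rather than by string is what
makes `w=1` reproduce the k-mer stream exactly, duplicates included, so
the two schemes coincide at `w=1` all the way down to occurrence counts.
Sequences shorter than `k+w−1` but at least `k` long contribute their
single smallest k-mer (short proteins remain indexable); shorter ones
contribute nothing.

The index value list for a seed is ordered by descending *normalized
count* — occurrences of the seed across all rows of an MSA (duplicates
within a row included) divided by the MSA's row count — with ties broken
by ascending MSA id for determinism. Normalized counts are computed by
`normalized_counts()` and discarded after ordering; only the ordered,
optionally truncated id lists are stored. Persistence is a versioned
stdlib-pickle envelope with a magic key; version mismatches are rejected
on load.

## Alignment

### Protein mode

The graph is topologically sorted (Kahn, min-heap on node id —
deterministic); concatenated labels form the target. DP columns that
start a node take predecessors `P_in` = last columns of all predecessor
nodes (column 0 for source nodes, matching the classical boundary);
interior columns take `j−1`. Each cell maximizes, over `p_l ∈ P_in`:
diagonal `H[i−1,p_l] + sub`, target gap `H[i,p_l] + Δ`, query gap
`H[i−1,j] + Δ`, and the 0 floor. On a one-node graph this is exactly
classical Smith–Waterman, and on any DAG the optimum equals the best
classical score over all source-to-sink path spellings (asserted against
a brute-force path-enumeration oracle in the tests).

Traceback follows stored per-cell provenance (move type + predecessor
column). Determinism choices where the optimum is not unique: the best
cell is the one with largest `i`, then largest `j`; tied moves prefer
diagonal > target-gap > query-gap (> frameshift jumps in DNA mode); tied
predecessor columns prefer the smallest index.

### DNA mode

Rows are nucleotide positions; every row is treated as a potential third
codon position. Moves per cell, with `j−1` generalized to `p_l` at node
boundaries exactly as in protein mode:

| move | consumes | score term |
|---|---|---|
| codon diagonal | 3 nt + 1 residue | `H[i−3,p_l] + sub(trans(nt[i−3..i]), res)` |
| codon gap | 3 nt | `H[i−3,j] + Δ` |
| residue gap | 1 residue | `H[i,p_l] + Δ` |
| insertion frameshift | 4 nt + 1 residue | `H[i−4,p_l] + σ` |
| deletion frameshift | 2 nt + 1 residue | `H[i−2,p_l] + σ` |

plus the 0 floor. The frameshift jumps carry no substitution term: a
4-nt jump pays `σ` *instead of* the skipped residue's diagonal score, so
one planted insertion in an otherwise exact back-translation scores
(exact score − that residue's self-substitution + σ). Out-of-range row
indices (`i < 2, 3, 4` per move) simply disable the move. Stop codons do
not terminate the alignment — the DP may align through `*` at its matrix
score (frameshift mode exists precisely because frames are unreliable).
Both strands are aligned and the better one reported ('+' wins ties);
reverse-strand query intervals are mapped back to the input orientation.
The reported frame (+1/+2/+3, −1/−2/−3) is derived from the alignment's
start offset on its strand.

Candidate selection for DNA pools seeds from all six translated frames
before ranking. Translation uses the standard genetic code; codons
containing `N` become `X`; trailing partial codons are dropped.

### Scoring defaults

| parameter | default | notes |
|---|---|---|
| substitution matrix | BLOSUM62 | any matrix Biopython ships can be named |
| gap penalty Δ | −3 | linear (per column); affine gaps are out of scope |
| frameshift penalty σ | −4 | must exceed the cost of faking the jump with gaps (here: Δ-based alternatives cost ≤ −6), else frameshifts are never chosen |
| min identity | 0.0 | report everything; raise to filter |
| align limit | 5 | graphs attempted per query; 0 = all matches |
| min length fraction | 0.0 | query-coverage filter |
| unknown-pair score | −4 | used only when the matrix lacks an `X`/`*` entry |

Identity = identical columns / all alignment columns, *including* gap and
frameshift columns — the stricter of the common conventions. CIGARs are
written over alignment columns (`=`, `X`, `I`, `D`, plus `F`/`G` for the
4-nt/2-nt frameshift jumps in DNA mode; an `I` column in DNA mode is one
skipped codon). One alignment is reported per attempted graph that
survives the filters, with a `bm` tag flagging the query's best.

## Synthetic data generator

`fixtures` emulates a toy panproteome: per family, an ancestor sequence
mutated independently per row with per-site substitutions (default 5%),
gap openings (2%) with geometric lengths (extension 0.3), and insertions
spliced as new columns — all in alignment coordinates, so families are
aligned by construction and need no external aligner. Defaults (8
families × 6 rows × 80 residues) describe modest within-family divergence
typical of single-species protein clusters. Families can be forced
pairwise k-mer-disjoint by rejection sampling, which makes "every query's
best alignment lands on its source family" hold exactly rather than
statistically. DNA queries are deterministic most-frequent-codon
back-translations with planted single-nucleotide indels at recorded,
well-separated positions (default spacing 20 nt > 3k for k=5, so seeding
survives around each indel).

What the generator does *not* emulate: phylogenetic correlation between
rows (rows are i.i.d. around one ancestor), domain architecture, indel
hotspots, sequencing-error profiles beyond single planted indels, or
realistic codon usage variation. Passing the fixture suites therefore
demonstrates algorithmic correctness (recurrences, traceback, ranking,
round-trips), not recall on real diverged proteomes.

## Problem sizes in the test and acceptance suites

The oracle-equivalence suite checks 1,000 random compacted DAGs of at
most 12 nodes against exhaustive path enumeration, and frameshift
recovery checks 200 back-translated queries with 0/1/2 planted indels —
sizes at which the brute-force oracles are exact and the whole suite runs
in seconds. The reference index computation uses the 10/7/3-row
three-MSA collection with 2/4/3 tracked-seed occurrences.

## Known limitations

- Linear gap model only; no affine gaps, banding, X-drop or bit-parallel
  acceleration — the full DP table is filled (substitution-matrix scoring
  rules out edit-distance bit tricks), so run time scales with query
  length × total graph label length.
- One DP table per (query, graph) pair; the align limit, not graph count,
  bounds work per query.
- Cyclic graphs are rejected; GFA dialects beyond plain GFA1 S/L/P lines
  (GFA2, rGFA, overlaps other than 0M) are not parsed.
- The frameshift model handles isolated single-nucleotide indels; two
  indels closer than a codon are resolved as whatever combination of
  jumps scores best, which may not match the mutational history.
- Threading in the CLI preserves output determinism (records are buffered
  and sorted by query then graph id) but, being pure Python, is not a
  throughput feature.
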