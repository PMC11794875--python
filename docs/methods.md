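# Methods

This note documents the models and procedures implemented in `azescan`,
their assumptions, the parameters that matter, and the choices made where
the design was genuinely open.

## Screening and dereplication

Hits are filtered on three inclusive thresholds (defaults: identity ≥ 27%,
coverage ≥ 0.60 on both query and subject, E ≤ 1e-5). Coverage is the
alignment span divided by the respective full sequence length; with the
plain 12-column BLAST tabular dialect the qlen/slen columns (or explicit
length maps) are required, since coverage is not derivable otherwise.
Duplicate subject ids are collapsed to the best (smallest) E-value before
downstream use; whether a published homolog count refers to before or after
such deduplication is generally ambiguous, so the rule is stated here and
applied consistently.

Dereplication follows CD-HIT-style greedy incremental clustering:

* **identity** = exact matches of a global Needleman–Wunsch alignment
  (BLOSUM62, gap open 11 / extend 1) divided by the *shorter* sequence
  length. The shorter-length denominator is the dereplication convention —
  a fragment fully contained in a longer protein counts as identical — and
  is fixed package-wide in `azescan.align`.
* **order**: length-descending, ties by input order. The first sequence
  seeds cluster 1; each subsequent sequence joins the *first* cluster whose
  seed it matches at ≥ the cutoff (default 0.95), else seeds a new cluster.
  Greedy clustering is order-dependent by construction; determinism comes
  from the fixed ordering rule.
* **representative**: re-picked per cluster as the member on the longest
  contig; ties fall to the longer protein, then the smallest id, making the
  choice total.

## Phylogeny stand-in

The tree stage is a distance method chosen for reproducibility and zero
model-fitting machinery, not for statistical efficiency:

* columns with gap fraction > 0.5 (parameterizable) are dropped — a simple,
  explicit surrogate for automated trimming heuristics whose exact rules
  are not published in closed form;
* p-distance `d = 1 − identity` over mutually ungapped columns (pairs with
  no comparable columns are an error naming the pair);
* classic Saitou–Nei neighbor joining. Negative branch-length estimates
  are clamped to zero with the deficit moved to the sibling branch, which
  preserves all leaf-to-leaf path lengths through the parent; on additive
  matrices the generating tree is recovered exactly (tested to 1e-9);
* plain nonparametric bootstrap (default 100 replicates): columns resampled
  with replacement, support = percentage of replicate NJ trees containing
  the same leaf bipartition, bipartitions canonicalised as the side not
  containing the lexicographically smallest leaf.

Sequence alignment, when not supplied, is delegated to MAFFT
(`--maxiterate 1000 --localpair`) via subprocess — the standard accurate
aligner for sets of this size, and deterministic for fixed input. The
pipeline equally accepts a precomputed alignment (`msa_path`) or a finished
newick tree (`tree_path`), which is the recommended route when a
maximum-likelihood tree is wanted instead.

Maximum-likelihood inference (LG+G, ultrafast bootstrap) is deliberately
out of scope; NJ on p-distances will differ in topology on hard datasets,
and trimmed-column counts from other tools are heuristic-specific, so
neither is asserted anywhere.

## Genomic-context analysis

**Windows.** For each anchor, every CDS overlapping
`[anchor.start − flank, anchor.end + flank]` (default flank 20 kb) is
collected, clipped at position 1 and at the contig end when a contig length
is known. Gene distance is counted in CDS rank — the absolute difference in
ordinal position along the contig, strand-ignorant — because co-transcribed
neighbors matter by gene count, not base pairs; base-pair gaps are carried
alongside for the delineation step only. GFF3 coordinates (1-based,
inclusive) are converted at the parsing boundary; internal arithmetic uses
the parsed integers directly.

**Similarity graph.** With external all-vs-all search results, edge weight
is `−log10(E)` capped at 200 (E = 0 maps to the cap), symmetrized by
maximum. Without them, the weight is the global alignment score normalized
by the smaller self-score — a scale-free similarity in [0, 1] for related
pairs — keeping edges at ≥ 0.2, which is far below any planted-family
signal but above random-sequence scores. No self-edges are added here.

**MCL.** Markov clustering is implemented directly (dense matrices):
self-loops at each node's maximum incident weight (1 for isolated nodes),
column normalization, then alternating expansion (matrix square) and
inflation (elementwise power, default 1.3, renormalized), pruning entries
below 1e-5, until the largest entry change is below 1e-6 or 200 iterations
(non-convergence warns and returns the current state). Clusters are read
off attractor rows (positive diagonal); attractors supporting each other
are merged; a node attracted to several clusters joins the one with the
largest total attraction, ties to the smallest cluster index. These
numerical details are fixed here because only the inflation value is a
scientific parameter; on graphs whose components are uniform cliques the
output provably coincides with connected components, which the tests assert
against networkx.

**Relevance score.** `r_f = n_f / d_f` with `n_f` the number of windows
containing ≥ 1 member of family *f* (per-context presence, not a member
count) and `d_f` the median CDS-rank distance over **all** member
occurrences across windows (even counts: mean of the central pair). The
alternative reading — median over each window's nearest member — is
implemented behind `distance_mode="per_window_min"`; both are tested, the
default is the simpler all-occurrences reading, and neither is claimed to
be uniquely correct. The anchor family has `d_f = 0`; it is flagged, its
score reported as infinite, and it bypasses thresholding (always marked).
Marking uses `r_f ≥ 2` inclusive by default. The score is deliberately
scale-free in window count: duplicating every window doubles it.

**Region delineation.** Published neighborhood boundaries are typically
narrowed by hand; the automation here is a parameterized heuristic, not a
reconstruction of any manual choice. Growing outward from the anchor, a
gene is *supported* if its family occurs in ≥ 25% of windows or its gap to
the previously retained gene is ≤ 500 bp; extension stops after 2
consecutive unsupported genes (`patience`), which are then excluded, while
unsupported genes rescued by a supported successor within patience are
retained. `patience = 0` stops at the first unsupported gene. The anchor is
always retained.

## Structure geometry

PDB files are parsed with gemmi; model 1 only; alternate locations resolve
to the highest-occupancy conformer (ties to identifier 'A'); waters are
kept but flagged. Atom selections are (chain, residue name-or-number, atom
name) and must be unique — ambiguity is an error listing the matches.
Distances are reported to 0.1 Å (crystallographic convention; full
precision available).

Superposition is the SVD form of the Kabsch least-squares fit with the
determinant correction that forbids reflections. Same-protein comparisons
pair Cα atoms by residue identity (chain, number, insertion code), which is
exact for two crystal forms of one protein; cross-protein RMSDs require an
externally supplied residue correspondence, since those are conventionally
derived from structure alignment, and are out of scope. Published Cα counts
for such comparisons depend on which residues the authors' alignment kept,
so a residue-identity pairing can differ by a few residues; the RMSD is the
meaningful check, at 1-decimal precision.

## Chemistry calculators

Monoisotopic masses (u): C 12 exactly, H 1.00782503207, N 14.0030740048,
O 15.9949146196, S 31.97207100, P 30.97376163. Adducts add/subtract a
*proton* (1.007276467 u) rather than a neutral hydrogen atom, making the
electron-mass convention explicit; this reproduces printed [M+H]+ values at
4 decimals for the compounds tested (one published value differs by 1 in
the 4th decimal from any convention we evaluated and is asserted nowhere).
Printed-value comparisons round half-up at printed precision (4 decimals
for m/z, 1 for ppm); the conventional Δppm uses the rounded calculated
mass, matching how such figures are reported.

The Eyring rate `k = (k_B T/h)·exp(−ΔG‡/RT)` uses CODATA constants and
transmission coefficient 1. At 298.15 K a 16.6 kcal/mol barrier gives
4.2 s⁻¹; literature rate statements sometimes assume other temperatures or
prefactors, so the formula — monotonically decreasing in ΔG‡, increasing in
T — is the tested contract, not any particular printed rate.

## Synthetic fixtures

`synthfix` emulates exactly the statistical structure the context analysis
assumes, not biological realism:

* **Substitution model**: uniform replacement from the 19 alternative
  residues, length-preserving. Identity control is what downstream stages
  consume; realism of the substitution process is irrelevant to them.
* **Homolog groups** are star-shaped: member 0 is the group base; others
  are mutated to the target identity *against the base* (so member–member
  identity is ≈ 1 − 2(1 − w)). Greedy dereplication recovers the truth
  because the base seeds its cluster under the longest-first, ties-by-input
  ordering. Contig lengths are log-uniform on 5–200 kb so longest-contig
  representative selection is exercised.
* **Neighborhoods**: one contig per context; one anchor CDS; planted
  families occupy fixed slot offsets with fixed probabilities, mutated from
  a family base (default 0.80 to base, i.e. ≥ ~0.6 pairwise — far above the
  similarity-graph cutoff); decoys are context-private random proteins
  (pairwise identity well under 0.25). Planted/anchor slots use small
  intergenic gaps (100 bp), decoy slots large ones (2 kb), so conserved
  regions are also compact in base pairs. Note that the realized CDS-rank
  distance of a planted gene can be *smaller* than its slot offset when
  intervening slots happen to be empty; relevance-score assertions on
  generator output therefore use inequalities or explicit layouts.
* **Determinism**: all randomness flows from one integer seed through a
  single `numpy.random.Generator`; same seed ⇒ byte-identical FASTA/GFF3.

Default study conditions mirror the analysis the package implements: 88
contexts, 97% within-group identity vs ≤ 40% between, 95% dereplication
cutoff, inflation 1.3, relevance threshold 2. Property tests that iterate
over many seeds run at desk scale (12 contexts, 4-gene flanks, decoy rate
2, 120-residue proteins), which preserves every contract being tested —
family purity, threshold behaviour, exact planted-set recovery — at a
fraction of the alignment cost.

What passing synthetic tests do **not** show: behaviour on real annotation
noise (missed or chimeric gene calls), compositionally biased proteins,
paralog interference within a window, or E-value distributions of real
search tools (synthetic hit tables carry assigned E-values). Conclusions
about real data rest on the correctness of the stage contracts, not on the
generator's realism.

## Numerical and degenerate-input conventions

* Alignment scoring: BLOSUM62, gap open 11 / extend 1, global mode with
  penalized end gaps; fixed in one module so every identity in the package
  means the same thing.
* NJ tie-breaks: the first minimal Q pair (row-major) joins; branch-length
  clamping as above.
* MCL: pruning 1e-5, convergence 1e-6 on the max entry change, 200
  iterations, tie-break to the smallest cluster index.
* Empty inputs, unknown ids, all-gap overlaps, ambiguous atom selections,
  and out-of-range parameters raise typed errors (`ParameterError`,
  `DataError`, `ParseError`, `FormatError`, `SelectionError`) naming the
  offending entity; stages never silently drop inconsistent input.
* Pipeline exit codes (CLI): 0 success, 2 configuration error, 3 data
  error; the failing stage and artifacts written so far are reported.
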