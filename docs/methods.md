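# Methods

## Scope and data model

The unit of input is a per-genome annotation table: one row per feature with
1-based inclusive coordinates on a circular genome, a strand (J = majority
reading strand, N = minority; `+`/`-` accepted as aliases), and an anticodon
for tRNAs. Gene names use the 37-gene metazoan mt vocabulary with the
leucine/serine paralogs split by anticodon (trnL1 = CUN/TAG, trnL2 = UUR/TAA,
trnS1 = AGN/TCT, trnS2 = UCN/TGA). The control region (CR) is carried as
positional metadata, not as a gene. Tables are sorted by (start, end, name)
on parsing; this matters for *E. sabinae*, whose published table prints trnK
and the CR out of coordinate order.

## Annotation arithmetic

- **Gaps.** The intergenic count attributed to a feature is the gap to its
  *coordinate* predecessor: `gap = downstream.start − upstream.end − 1`, with
  the origin-wrapping pair using `downstream.start + genome_length`. Negative
  values are overlaps. This attribution (rather than printed row order) is
  what reproduces every parenthetical in the source tables, including the
  −10 between atp8 and trnK in *E. sabinae*. Conservation
  `Σ lengths + Σ gaps = genome_length` is asserted for every genome parsed.
- **Genome length.** From the FASTA when a sequence is given; otherwise
  inferred as `max(end) + wrap_gap − (first.start − 1)` where `wrap_gap` is
  the intergenic count printed for the first feature. A conflict between the
  two sources is an error.
- **Codons.** N-strand genes are reverse-complemented before reading. A gene
  whose length is not a codon multiple has an incomplete stop (trailing T or
  TA, completed by polyadenylation); in-frame internal stops are warnings,
  not errors. The packaged tables carry the annotated start/stop codons as
  metadata; the direct tally gives 8×TAA per genome, which the pipeline
  reports as computed (the source text's prose counts of 9 and 10 do not
  match its own table; we report our tally and leave the discrepancy
  visible rather than forcing either number).
- The shared *E. sabinae* cox1/cox2 boundary at 1533 is parsed as printed
  (a 1-nt overlap).

## Gene-order comparison

Orders are circular signed permutations read along the J strand.

- **Default convention: `signed-circular`.** Adjacencies are oriented
  junctions with the strand-reading equivalence (x, y) ≡ (−y, −x); the CR is
  excluded; an n-gene circle has n adjacencies. The breakpoint distance
  |A(target) \ A(reference)| under this convention, with the Limulus-type
  arthropod ancestral arrangement as reference (cox1 adjacent to cox2;
  trnL2–trnL1 tandem between nad1 and rrnL), reproduces the published counts
  13 / 16 / 0 exactly. The convention is orientation-aware, which it must be:
  several eriophyoid differences from the ancestor are pure changes of a
  block's reading direction relative to its flanks, invisible to unsigned
  counting.
- **Alternative: `unsigned-linear-cox1`.** Unordered name pairs after
  linearizing at cox1 (reading canonicalized so cox1 is on +, making the set
  invariant to rotation and strand reading); n−1 pairs. Documented to give
  smaller distances (10 and 13 on the fixtures).
- **Shared derived clusters.** Candidate adjacencies are strictly ordered-
  orientation pairs (no folding) present in every target and absent from the
  reference; a pair whose genes are separated by the CR in some target is
  not counted as present there. When a screen panel is given, candidates
  found in any screened arrangement are removed before chaining — a
  character shared with outside taxa is not a shared derived character.
  Chaining is strict so that a relocated-and-inverted block (trnY–trnQ–
  rrnS–trnV–rrnL in the eriophyoids) chains as a single run; runs are
  reported 5'→3' on the first target's reading strand.

## Ancestral inference

Each signed-circular adjacency is an independent binary character. Two-pass
Fitch parsimony runs per character on the user's rooted tree (polytomies
allowed; change counts are computed by a unit-cost Sankoff DP, which is
exact on polytomies where counting downpass union events is not). Root
ambiguity is resolved toward a flagged outgroup's state, otherwise reported
as ambiguous — never silently picked. Arrangement assembly treats each
confidently present junction as an edge between gene extremities (5'/3');
an extremity touched twice is a conflict, and conflicting or isolated genes
are listed as unplaced. Correlations between adjacency characters are
ignored; the assembled fragments are a per-character summary, not a joint
reconstruction under a rearrangement model.

On the packaged panel and tree this yields the expected picture for the
acariform ancestor: the arthropod backbone as one fragment, the
rrnS–trnV–rrnL block as a separate fragment with ambiguous flank junctions
(translocated-vs-inverted alternatives are left as reported support, not
adjudicated), and trnQ/trnY unplaced.

## tRNA folding and classification

No thermodynamic model is used; folding is a constrained template search:

- acceptor stem from terminal complementarity, up to 7 positions, ≤2
  mismatches tolerated;
- anticodon arm anchored on a 7-nt loop (anticodon at loop positions 3–5)
  closed by 2–5 pairs (candidates ranked by stem strength, then centrality;
  an expected anticodon, when given, ranks matching candidates first);
- D- and T-arms searched in the regions between acceptor and anticodon stem:
  an arm is present iff a hairpin with ≥2 WC/GU pairs, ≤1 internal mismatch
  and a 3–9 nt loop fits; ties broken longest-stem-first, then 5'-most;
  otherwise the region is a replacement loop.
- Scoring: +2 per pair, −1 per mismatch. Mismatches are recorded but do not
  flip arm presence. Classification: cloverleaf (both arms), D-armless,
  T-armless, armless. Inputs outside 40–100 nt are rejected.

Thresholds live in `FoldingThresholds` and are calibrated on the generator,
not on published structure figures (whose exact presence criterion is not
stated). On 1,000 generated tRNAs with clean margins (stems ≥3 pairs, ≤1
mismatch) classification recovery is ≥95% (measured: 100%); with 2
mismatches per stem it degrades gracefully (~87%).

## Synthetic data

- **Rearrangements.** Events are inversions, transpositions and inverse
  transpositions on the circular element list (the CR rides along as an
  inert marker). Spans are uniform; block moves that amount to a pure
  rotation of the circle (a span dropped at the complementary end) are
  excluded from the draw, so every drawn event changes the arrangement.
  Default mix 0.6/0.3/0.1. Scenarios evolve a root order down a tree with a
  fixed event count per edge; per-edge RNGs are spawned from one seed, and
  the logged history replays exactly.
- **Genomes.** PCGs get valid invertebrate-mt (translation table 5) start
  codons, stop codons (or a bare T on request) and stop-free bodies of
  50–150 codons; tRNAs are generated cloverleafs carrying their family
  anticodon; rRNAs 250–400 nt; intergenic gaps 0–3 nt. Sizes are scaled
  down from real mt genes for fast tests; the coordinate arithmetic they
  exercise is size-independent.
- **tRNAs.** Stems are G/C WC pairs (mismatches injected on the 3' side),
  replacement loops are unpairable poly-A, loops avoid G/T so no spurious
  stems arise. What the generator does *not* emulate: real sequence
  composition, post-transcriptional editing, and borderline arms (e.g. a
  1-pair vestigial stem); passing round-trip tests therefore demonstrates
  correctness of the classifier's logic under its own definitions, not
  performance on real acariform sequences, which additionally require the
  deposited genome records.

## Fixture provenance and limits

The two annotation tables are transcriptions of the published per-genome
tables. The arrangement panel contains the Limulus-type ancestor and the
two eriophyoid orders (exact), plus three screen arrangements headed
`provenance: figure-transcription`: best-effort reconstructions of other
acariform arrangement tracks constrained by the study's verbal statements
(trnQ/trnY relocated in every acariform lineage at varying positions;
rrnS/rrnL translocated-not-inverted variants exist; none of the four
eriophyoid clusters occurs elsewhere). Their individual breakpoint counts
are *not* asserted anywhere, and cluster results against the screen are
fixture-dependent. The comparison tree is likewise a transcription of the
study's topology (eriophyoids at the base of Acariformes; horseshoe crab
outgroup).

Problem sizes used by the shipped tests and the acceptance script: 37-gene
fixtures for all exact checks; 1,000 random ≤10-gene order pairs for the
breakpoint oracle; exhaustive Fitch oracles on ≤6-leaf trees; 8-leaf
scenarios at 0–10 events/edge for recovery; 1,000 generated tRNAs for
classification recovery. These sizes keep the whole suite in seconds while
covering every code path; all are set in the tests themselves.
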