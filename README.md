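# mitoarch

Comparative analysis of mitochondrial (mt) genome architecture, built around
the two eriophyoid mites *Phyllocoptes taishanensis* and *Epitrimerus
sabinae* — the least rearranged mt genomes known in the Acariformes — and the
question of what the acariform ancestor's gene arrangement looked like.

The package is for researchers working on mt genome evolution in arthropods
(and metazoans generally) who need to:

- parse per-genome annotation tables and recompute the derived statistics
  (genome length, intergenic gaps/overlaps including the origin-wrapping
  pair, strand usage, start/stop codons, tRNA size ranges);
- compare circular signed gene orders by **breakpoint distance** and extract
  **shared derived adjacency clusters** (candidate synapomorphies);
- infer ancestral arrangements on a user-supplied rooted tree by **Fitch
  parsimony** over adjacency presence/absence characters;
- classify mt tRNAs as cloverleaf, D-armless, T-armless or armless by
  **template-constrained folding** — the truncated forms that dominate
  acariform mitochondria;
- generate seed-deterministic synthetic data (rearrangement scenarios along
  trees, annotated genomes, tRNAs of known architecture) so every stage is
  testable without downloads.

## The core quantities

A circular mt genome with gene set *G* (|G| = 37: 13 protein-coding genes,
2 rRNAs, 22 tRNAs) is a circular signed permutation π. Its **adjacency set**
A(π) is the set of oriented junctions (x, y), with (x, y) ≡ (−y, −x) because
a junction reads the same from either strand; the control region is excluded.
The **breakpoint distance** to a reference arrangement ρ is

    d(π, ρ) = |A(π) \ A(ρ)|

which is 0 iff π equals ρ up to rotation and strand reading. Against the
Limulus-type hypothetical arthropod ancestor this reproduces the published
counts: 13 for *P. taishanensis*, 16 for *E. sabinae*, 0 for soft ticks
(Argasidae). An unsigned variant (`unsigned-linear-cox1`: unordered name
pairs after linearizing at *cox1*) is provided for comparison and yields
smaller values (10 and 13 on the same data) because it cannot see pure
inversions of a block's reading direction.

A **shared derived cluster** of a set of target genomes is a maximal run of
strictly ordered-orientation adjacencies present in every target, absent
from the reference, and (optionally) absent from every arrangement in a
screen panel. Chaining is orientation-strict so that a relocated-and-
inverted block chains as one run.

For ancestral inference, each adjacency is an independent binary character;
two-pass Fitch parsimony (with a Sankoff check for polytomies) gives
per-node state sets, and an adjacency graph assembles the confidently
present junctions into ordered fragments — genes with conflicting or no
junctions are reported as unplaced rather than guessed.

## Worked example

The study's annotation tables, arrangement panel and comparison tree ship
with the package:

```sh
mitoarch stats --table src/mitoarch/data/pt_table.tsv \
               --table src/mitoarch/data/es_table.tsv --out out/stats
mitoarch breakpoints --out out/bp
mitoarch clusters --out out/cl
mitoarch ancestor --node acariformes --out out/anc
```

`stats` prints (stderr) and writes `genome_stats.json`:

```
pt_table: 13475 bp, strands 27/10, tRNAs 47-61 nt
es_table: 13531 bp, strands 27/10, tRNAs 47-67 nt
```

i.e. both genomes are ~13.5 kb with 27 genes on the majority strand and 10
on the minority strand; tRNAs run down to 47 nt. The JSON adds the control
region lengths (47 and 94 bp), the largest non-CR spacer (12 and 16 bp) and
the stop-codon tally (8×TAA in each genome by direct count).

`breakpoints.tsv` (signed-circular convention, vs the arthropod ancestor):

```
taxon	ancestral_arthropod
ancestral_arthropod	0
Argasidae	0
P_taishanensis	13
E_sabinae	16
```

`clusters.tsv` — the four derived gene clusters shared by both eriophyoid
mites, absent from the ancestor and from the packaged screen panel:

```
trnY-trnQ-rrnS-trnV-rrnL
trnW-nad2-trnM-trnC
nad6-trnT-cob
trnS1-trnI-trnE
```

`ancestor` reconstructs the acariform ancestral arrangement on the packaged
tree. The output keeps the arthropod backbone as one fragment, leaves the
`rrnS-trnV-rrnL` block as a separate fragment (its orientation relative to
the flanks is ambiguous), and marks `trnQ?` and `trnY?` as unplaced — their
positions vary across acariform lineages, so no single position is
parsimony-supported.

Synthetic data for benchmarking:

```sh
mitoarch simulate --seed 7 --events-per-edge 2 --genomes --out out/sim
```

## Layout

- `src/mitoarch/annotation.py` — tables, gaps, codons, order extraction
- `src/mitoarch/gene_order.py` — adjacency algebra, distances, clusters
- `src/mitoarch/ancestral.py` — Fitch states, arrangement assembly
- `src/mitoarch/trna.py` — template folding and truncation classes
- `src/mitoarch/synth.py` — simulators and generators
- `src/mitoarch/cli.py` — `mitoarch` subcommands (`full` runs a config)
- `src/mitoarch/data/` — packaged tables, arrangements, tree
- `docs/methods.md` — models, conventions, thresholds, limitations
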