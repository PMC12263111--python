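# Methods

This note records the models, conventions and design choices behind
`orthoqc`, in the order data flows through the pipeline.

## Data model and formats

Internal coordinates are 0-based half-open everywhere; the GFF3 boundary is
the only place 1-based inclusive coordinates exist, and the conversion is
exact in both directions. GFF3 dialects (`ensembl`, `ncbi`, `augustus`,
`generic`) differ only in which attribute key carries the gene biotype
(`biotype`, `gene_biotype`, or none for purely protein-coding predictors);
a gene is kept when no biotype key is present or its value is
`protein_coding`. Transcripts without `exon` children fall back to their
`CDS` children, which is how ab initio predictors usually write GFF3.

Isoform-map (".splice") files have no published grammar; the reader accepts
an optional leading `gene<TAB>` field and otherwise derives the gene key as
the longest common prefix of the isoform ids (falling back to the first
id). Pairwise-ortholog tables likewise vary, so the two protein-id columns
are configurable (defaults 0 and 1); extra columns are ignored and the pair
set has set semantics (duplicates and order swaps collapse). Newick trees
may have unlabeled internal nodes (NCBI-taxonomy exports often do); these
are auto-labeled `node1, node2, ...` in traversal order with a warning
rather than rejected.

## Gene-model agreement

A transcript pair is a *complete match* iff same chromosome, same strand,
and identical intron chains; the outer boundaries of the first and last
exon are unconstrained. Mono-exonic versus mono-exonic requires any exon
overlap (the intron criterion is vacuous there); mono- versus multi-exonic
is never complete, and CDS phase and UTRs are ignored — the criterion
lives entirely at the splice-site level. The gene-level index is

    ji = (|matched query genes| + |matched ref genes|) / (n_query + n_ref)

which is symmetric, equals 1 on identical annotations, and counts every
gene involved in one-to-many matches on both sides. Published descriptions
of the analogous index do not print the exact numerator/denominator, so
this formula is a documented choice of this package, not a claim about any
external tool. Matching is implemented as a hash join on full intron
chains (exact-identity criterion) plus an overlap sweep for mono-exonic
models; tests assert equality with brute-force all-pairs comparison.

## Ortholog proportions and HOG metrics

All per-proteome statistics use canonical isoforms only: the longest
isoform per gene, ties broken by the lexicographically smallest protein id
(a flag switches to all-isoform denominators for sensitivity analysis).
Protein length is the residue count excluding a trailing `*`. HOG size
counts genes, not species, so within-species duplicates contribute their
copy count. Completeness of a root HOG is (species present) / (species in
the clade at the HOG's level). Phyletic patterns use strict equality per
species with a `"*"` wildcard; species absent from a profile count zero.

`hogs_from_pairs` groups an ortholog-pair graph into flat root HOGs
(connected components with ≥ 2 members, level = species-tree LCA of the
members). It exists to summarize *observed* pair sets as families when no
hierarchical grouping is available, e.g. for simulator output.

## Discordance benchmark

Gene trees are built from pairwise global alignments (BLOSUM62, gap open
−11, extend −1) scored as p-distances, 1 − identities/aligned-columns with
gap columns excluded from both counts, followed by neighbor joining with
deterministic tie-breaking (smallest representative-label pair in the
Q-matrix) and negative branch lengths clamped to zero. The original
benchmark's alignment/tree toolchain is not fixed by this package's
sources; this dependency-light stand-in is an explicit choice and the
distance function is pluggable.

Per trial, a seed protein is drawn uniformly (with replacement across
trials) from the union of canonical proteins; the trial *succeeds* iff its
ortholog star covers ≥ `min_species` species (default 10) and the distance
matrix carries signal (an all-zero matrix — e.g. from substitution rate
0 — counts as a failed trial, since its topology would be arbitrary). A
failed seed is not redrawn; it counts against recall. Accuracy averages
the scaled RF over successful trials only. RF is normalized by
|B1| + |B2| of the two trees actually compared, which stays well-defined
for multifurcating species trees, rather than by the binary-tree maximum.
Each trial has its own RNG stream derived from (seed, trial index), so
results are bit-reproducible and trials are independent of each other.

## The simulator

The simulator defines the package's study conditions; its defaults are
fixed once and the tests run against them.

* **Species tree** — a synthetic 20-leaf chordate-like tree (teleosts with
  their characteristic WGD-prone lineage, birds, mammals, an outgroup
  tunicate), ultrametric-ish with root depth 1.0 and labeled internal
  clades. It is a plausible stand-in, not a published phylogeny.
* **Families** — each family is born at the root; along every branch each
  lineage duplicates at rate 0.1 and dies at rate 0.1 per unit branch
  length (Gillespie simulation). A WGD registered at a node fires at the
  end of its stem branch: every surviving copy duplicates and each new
  copy is retained with the configured probability. All-extinct families
  are regenerated from a fresh substream. Two extant genes are true
  orthologs iff their family-tree LCA is a speciation node; nested HOGs
  mirror the family tree, with the root HOG defined at the tree root
  (where every family originates).
* **Sequences** — root length is discretized lognormal (median 300 aa,
  sigma 0.45, floor 30); sites substitute independently at rate 0.3 per
  site per unit branch length, replacement uniform over the other 19
  residues. There are no indels, deliberately: family members keep equal
  lengths, so any downstream length effect is attributable to the
  annotation error model. Toy gene models place one ~200-codon exon per
  started 200 residues with 200-nt introns on a shared chromosome.
* **Error model** — independently per gene (one RNG substream per
  (family, species)): missed with `miss_prob`; fragmented with `frag_prob`
  into `n_fragments` (default 2) contiguous pieces at distinct uniform
  interior residues, the gene model split at the matching CDS offsets;
  otherwise kept. Spurious genes (random sequence, lognormal length,
  median 120 aa) are injected per true gene at `spurious_rate`; terminal
  exon ends of surviving models jitter by up to `boundary_jitter` nt
  (which preserves intron chains, hence complete-match agreement).
* **Observed orthology** — a pair between two emitted units is observed
  iff their source genes are true orthologs and the units' *alignable
  overlap* — the intersection of their residue spans in the indel-free
  family coordinate system — covers at least `overlap_threshold`
  (default 0.6) of the longer unit. Against a full-length partner this
  reduces to "a fragment keeps its parent's pairs iff it spans ≥ τ of the
  protein". The positional part matters: fragments covering the same
  region of orthologous parents still match each other, while
  non-overlapping fragments never do. This reproduces both failure modes
  of fragmented annotations — short singletons, and separate shallow
  groups composed of gene fragments (observed root-HOG counts grow with
  fragmentation). A pure length-ratio rule cannot produce such splits:
  removing whole genes from an ortholog graph provably never cuts a
  component in two, because within-family ortholog components are
  complete multipartite graphs.

One consequence worth knowing: under the overlap rule, fragment–fragment
rescue grows roughly with the square of the fragmentation rate, so the
ortholog proportion is not strictly monotone in `frag_prob` alone at high
rates. The degradation sweeps used in the tests raise fragmentation and
spurious rates together, as a degrading annotation does, and are strictly
monotone.

## What the simulation does and does not show

The simulator emulates the *inputs* of an annotation-quality study
(proteomes, gene models, pairs, HOGs, a species tree) and the
annotation-driven failure modes of orthology inference. It does not
emulate any particular inference algorithm's sequence-similarity errors,
indel evolution, rate heterogeneity across sites or lineages, horizontal
transfer, or real intron/exon statistics. Passing tests therefore
demonstrate that the metrics measure what they claim and respond to
annotation errors in the documented directions — not that any specific
real annotation source would score identically.

## Numerical conventions and degenerate inputs

Even-length medians are the midpoint of the central order statistics. The
KS statistic is used as a distance (no p-values); averages are over
unordered pairs. Pearson correlation requires ≥ 3 pairs and non-constant
series. Empty annotations give agreement 0 with a warning; alignments with
no non-gap columns give distance 1 with a warning; RF needs ≥ 4 shared
leaves. Report JSON is written with sorted keys, fixed rounding (9
decimals) and no timestamps, so identical configurations and seeds produce
byte-identical reports.

## Problem sizes

The packaged demo and the acceptance script run 100–150 families over the
20-species tree with 100–300 benchmark trials, chosen so a full run
completes in a few minutes on one CPU while keeping binomial noise well
below the effect sizes being checked. The same statistics scale to real
proteome-sized inputs; the benchmark's alignment step dominates cost and
caches pairwise distances across trials.
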