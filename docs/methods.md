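# Methods

`symred` re-implements, as a tested pipeline, the comparative-genomics
workflow used to ask how host-dependent a clade of young endosymbiont
genomes has become: which ancestral proteins were lost under symbiosis,
whether the losses are shared, what metabolic capability remains, and
where the clade sits relative to its free-living relatives.

## Orthology

Orthologs are operationally defined as reciprocal best hits: proteins A
(genome X) and B (genome Y) are paired when A's best hit in Y is B, B's
best hit in X is A, and the worse of the two directional E-values is
better than the applicable cutoff. The cutoff is 1e-10, relaxed to 1e-3
when a partner is shorter than 100 residues — short proteins cannot
achieve strong E-values even when genuinely homologous, so a fixed
strict cutoff would silently delete them from every downstream set.
Design points:

* *Relaxation scope.* The relaxed threshold applies when **either**
  partner is below the 100-residue cutoff (configurable to query-only).
  The length rule names the protein, not a direction, and a pair is a
  symmetric object; either-partner keeps the table symmetric.
* *Direction-independence.* The E-value tested is the worse (larger) of
  the two directions, so the pair set cannot depend on which genome is
  called "query".
* *Ties.* Best hits rank by bitscore, then E-value, then lexicographic
  subject id; a query decided by the final rule is flagged ambiguous
  (the duplicate-gene situation that otherwise requires manual
  curation). Ambiguous pairs are kept but marked, and the classifier
  can be run with or without them.

### Built-in search

For desk-scale work the package carries its own deterministic search:
exact k-mer seeding (k = 3, seed word BLOSUM62 self-score ≥ 11)
followed by Smith-Waterman extension under BLOSUM62 with affine gap
penalties 11/1. The bitscore is the raw alignment score and
`E = m · n · 2^(−bitscore)` with m the query length and n the summed
subject length — a simplified Karlin-Altschul form that is monotone in
the score and reproducible to the last bit. On proteome pairs of ≤20
proteins this search provably agrees with brute-force all-pairs
Smith-Waterman reciprocal-max (tested on 100 random instances).

Whole-panel runs (36 genome pairs × ~1,600 proteins) use a second
scorer: global edit-distance alignment (edlib), bitscore = 2 × matches
with matches = maxlen − edit distance, long seeds (k = 6) for normal
proteins and short seeds (k = 3) against a short-subject index for
queries under 100 residues. Because a global edit alignment against any
comparable-length subject scores proportionally to length, the edit
scorer also requires 30% identity over the longer sequence: unrelated
pairs sit near 23-25%, genuine orthologs at the divergences this scorer
is built for (substitution-only, ≤ ~50% diverged) sit well above. The
edit scorer is a performance mode for substitution-dominated data such
as the synthetic clade; externally computed hit tables (12-column
tabular format) can be substituted for real proteomes.

At the default study conditions the panel search recovers planted
ortholog pairs essentially perfectly (precision = recall = 1.0 at the
reference seed; at arbitrary seeds an occasional tiny protein is
honestly rejected — a 30-residue ortholog at ~50% identity has
E ≈ 3e-3 > 1e-3 — and an occasional pair of unrelated sub-100-residue
proteins passes the relaxed cutoff, the documented false-positive risk
of relaxing BBH thresholds for short proteins).

## Protein-set algebra

Sets are anchored the way small-panel comparative studies anchor them:

* **core** — proteins of a designated reference relative with orthologs
  in every other free-living relative (ancestral-repertoire proxy);
* **All-RE** — families present in all endosymbionts, evaluated through
  a pivot endosymbiont's proteins having orthologs in the other five
  (the pivot convention matches how such tables list one prototype id
  per family);
* **No-RE** — reference-relative proteins with no ortholog in any
  endosymbiont: the candidate "lost under symbiosis" set, and its
  intersection with core is the headline count;
* **unique** — no ortholog in any other panel genome;
* **small** — length < 100 residues.

Each proteome is partitioned four ways for stacked counts:
core-present, conserved non-core (All-RE-linked but not core),
non-conserved shared, and unique. The partition is exhaustive and
disjoint by construction, so stacked counts always sum to proteome
size.

**Gene density** is the fraction of an entity's nucleotides covered by
coding plus non-coding genes, overlaps counted once (interval union;
strand ignored — the quantity is nucleotides, not features). Entities
are the chromosome, all plasmids pooled, and unresolved replicons.
Pseudogene spans are excluded from the numerator by default: density is
read as a proxy for how thoroughly broken genes have been purged, so
counting them would erase the signal; a `count_pseudogenes` flag
reverses the choice. Coordinates are 1-based inclusive throughout (the
GFF3 convention) and converted to half-open only inside the union sweep
— one conversion site, no off-by-one surface.

## Pathway completeness

A pathway is an ordered list of reaction slots; a slot is satisfied if
any alternative enzyme is present or if a declared bypass slot-set is
fully satisfied (fixpoint iteration, so chained bypasses resolve).
Completeness = satisfied / total slots, reported to 3 decimals; state
is `present` at exactly 1, `absent` at 0 only when the genome also
lacks the initial substrate (substrate availability is a per-genome
boolean input, default true), else `partial`. Two orthogonal
annotations: `supplemented` marks presence of marker enzymes that
exceed the free-living reference's capability (e.g. GapN, the
light-independent protochlorophyllide reductase, an alternative
terminal oxidase), and `holes_filled_by_import` records whether adding
host-encoded imported proteins closes all, some, or none of the
genome's holes. Ten definition files ship with the package (glycogen,
glycolysis, Entner-Doudoroff, pentose phosphate, TCA, chlorophyll,
biotin, folate, pantothenate/CoA, pseudocobalamin) carrying
representative enzyme slot lists from standard cyanobacterial
metabolism; the file schema, not this particular curation, is the
contract, and users supply their own curation for real analyses.

## Habitat enrichment

Genomes are classified from lower-cased isolation-habitat labels under
a fixed controlled vocabulary: saline labels {marine, saline lake,
coastal, brackish, intertidal, estuary} and excluding labels
{freshwater, bog, hot springs, halo-intolerant, terrestrial, rock,
paddy, sand, soil, root}; any excluding label dominates. Genomes
matching neither vocabulary are excluded from denominators (a config
switch counts them non-saline instead) — diluting fractions with
unknowable labels seemed worse than shrinking the denominator. A
protein's saline fraction is the saline share among classified
ortholog-bearing genomes; the panel baseline is the same fraction over
the whole panel. Matching is exact-string on the vocabulary, no fuzzy
matching.

## Residue rules

Two inspection rules are mechanized through global BLOSUM62 alignment
to an annotated reference:

* α-glucosidase linkage specificity from the residue adjacent to the
  universally conserved catalytic aspartate: Ala/Thr → α(1→4),
  Val → α(1→6), anything else undetermined. "Adjacent" defaults to the
  C-terminal (+1) non-gap alignment column; the direction is
  configurable to −1 since the prose convention is ambiguous. A query
  with a gap or a non-Asp residue at the anchor column is undetermined
  with a stated reason, never guessed.
* C-terminal conserved-residue counting for chlorophyll-binding-like
  tails (Scp/extended HemH): the query's C-terminal region is aligned
  to a reference region carrying 1-based conserved positions; matches
  are exact-residue counts, and queries whose extension is shorter than
  a configurable minimum report no extension and zero matches. The
  motif content is user-supplied data, not hard-coded biology.

## Phylogeny

The tree pipeline is the classic quick-tree recipe: progressive
alignment of each conserved family, informative-column filtering,
concatenation into a supermatrix (29 families by default), pairwise
distances, neighbor joining, bootstrap supports. Maximum-likelihood
inference is deliberately out of scope; NJ over Poisson-corrected
distances is the implemented method, and NJ's guarantee — exact
reconstruction of any additive distance matrix — is the property the
tests lean on (200 random additive matrices, 4-10 taxa, exact topology
recovery).

Numerical choices: progressive alignment computes pairwise global
alignments (BLOSUM62, 11/1), builds a UPGMA guide tree on identity
distances, and realizes each profile merge by aligning the two
profiles' consensus sequences (majority residue per column, ties
alphabetical) and copying induced gaps into member rows — a
deterministic simplification of profile-profile alignment that is exact
for the substitution-only families the simulator produces and adequate
for modestly gapped real families. Taxa are canonicalized by name
before alignment, so results are independent of input order. Column
filtering keeps columns with gap fraction ≤ 0.0 (strict default) lying
in runs of ≥ 10 qualifying columns. Distances use pairwise deletion;
the Poisson correction is −ln(1−p) and a saturated pair (p = 1) is an
error rather than an infinity. NJ breaks Q-matrix ties by the smallest
node-index pair; negative branch lengths are clamped to zero with the
deficit moved to the sister edge, preserving the joined path length.
Bootstraps resample supermatrix columns with replacement (a
family-block mode is exposed for sensitivity), re-run NJ, and report
the percentage of replicates containing each internal bipartition of
the reference tree; a replicate whose resampled matrix is degenerate is
skipped and carries no signal.

## Synthetic clade generator

The generator is the package's study-conditions oracle: everything it
emits is derivable from its recorded `CladeTruth`, and the whole bundle
is a pure function of (config, seed). Defaults model a young
endosymbiotic clade:

| parameter | default | rationale |
|---|---|---|
| taxa | 6 endosymbionts + 2 relatives + 1 outgroup | the smallest panel exercising every set definition |
| universal families | 1,500 | typical conserved backbone of a ~1,700-protein cyanobacterium |
| stem-deleted families | 200 | the planted "lost under symbiosis" set; exactly the expected core∩No-RE |
| divergence/branch | 0.05 subs/site | orthologs stay 75-90% identical, as expected a few tens of My after acquisition |
| per-lineage loss rate | 0.01 (terminal branches only) | sporadic ongoing loss; terminal-only so a family is never coincidentally lost in all six lineages |
| invented proteins | 120/endosymbiont, 90% < 100 aa | the unique-small bias produced by inconsistent gene calling on reduced genomes |
| pseudogene retention | 0.3 of lost loci | depresses gene density the way lingering broken genes do |
| intergenic spacer | 150 nt | compact bacterial layout |
| plasmids | 4 bearers × 5 shared genes | mirrors the small shared plasmids reported in such clades |

Sequences evolve along a fixed ladderized topology by i.i.d.
substitutions: each site changes with probability 1 − e^(−d) per
branch, uniformly to one of the 19 alternatives — no rate matrix, no
indels, no GC dynamics. That is deliberate: it keeps closed forms
simple (expected proportion of changed sites on a path of length d is
≈ 1 − e^(−d)), makes exact-sequence matching a valid orthology oracle
at divergence 0, and suffices for BBH and NJ recovery tests. It also
bounds what passing tests show about real data: no alignment stress
from indels, no compositional bias, no rate variation across sites or
lineages. Alignment behavior under indels is exercised by separately
constructed fixtures, not by the simulator.

Annotations lay genes end-to-end with the fixed spacer, append three
non-coding genes (rRNA/tRNA-scale lengths), and retain a sampled subset
of lost loci as pseudogene features, so each genome's exact gene
density is an integer closed form recorded in the truth file; the
pipeline's density must match it to 1e-9 (in practice exactly).
Pathway holes are planted only in slots whose enzymes belong to a
single pathway and participate in no bypass, so expected completeness
fractions remain simple counts. Habitat labels plant one marine
endosymbiont, freshwater/paddy relatives and a marine outgroup.

## Problem sizes

The default test suite runs the full study-scale clade once (9 genomes,
~14,700 proteins, 36 genome-pair searches, 29-family supermatrix, 100
bootstraps; about 2-3 minutes), the orthology oracle on 100 random
20-protein proteome pairs, 200 random additive matrices for NJ, 100
random pathway definitions, and exhaustive habitat label combinations.
`scripts/acceptance.py` repeats the study-scale run from scratch at the
given seed.

## Known limitations

* The edit-distance scorer assumes substitution-dominated divergence;
  for indel-rich real proteomes use the Smith-Waterman scorer or an
  external search tool's hit tables.
* The internal E-value is a simplified Karlin-Altschul form; absolute
  E-values are not comparable to BLAST's, only the thresholds' ordering
  logic is.
* Progressive alignment by consensus merging degrades on deep, gappy
  families; the package is not a general MSA tool.
* NJ is the implemented tree method; concordance of real-data
  topologies with likelihood-based trees is not guaranteed and not
  claimed.
* Habitat classification is exact-string on a fixed vocabulary;
  free-text metadata needs cleaning before it is usable.
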