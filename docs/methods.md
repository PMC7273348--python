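# Methods

This note documents the models behind `gablocks`, the parameter choices
that matter, the design decisions taken where the design was genuinely
open, and the limits of what the synthetic studies demonstrate.

## The event model

Orthologous gene blocks are compared through three event characters:

* **deletions** — the number of gene families present in exactly one of
  the two blocks (an unordered presence change; gains and losses are not
  distinguished in a pairwise comparison);
* **duplications** — the summed absolute copy-number difference over the
  families present in both blocks;
* **splits** — the absolute difference in the number of sub-blocks after
  restricting each block to the families the pair shares (a sub-block is a
  maximal run of genes separated by ≤ 500 bp on one strand; the `|`
  character in the string notation marks a boundary).

The event-based distance is the sum of the three minimized counts.  The
restriction in the split character matters: a family present on only one
side must not drag its sub-block into the segmentation comparison, since
its presence difference is already charged once as a deletion.

`events.oracle_distance` re-derives the counts by uniform-cost search and
exists to certify the "minimized" semantics of the closed formulas.  The
search operates on exactly the information the characters carry — the copy
vector over shared families plus the restricted sub-block count, with the
structural invariant 1 ≤ sub-blocks ≤ total genes — with atomic moves
add/remove-one-copy (never emptying a sub-block or removing a family) and
split/join.  Presence changes are forced, one per family in the symmetric
difference.  Searching over concrete gene arrangements instead would
smuggle in information the distance is defined not to see, and provably
disagrees with the character definitions in both directions.  Two caveats
are documented behavior: the distance is zero for blocks with equal family
multisets and equal restricted sub-block counts even when the genes are
arranged differently (within-block order is not an event type), and the
duplication component is not a metric (a family absent from an
intermediate block hides its copy difference), so only the deletion
component is asserted to satisfy the triangle inequality.

Pseudogenes are excluded from distance computation by default — a cyp115
fragment is not a functional gene copy — and switchable with
`include_pseudo=True`.

## Ancestral reconstruction

`ancestors.reconstruct` assigns a block to every internal node of a rooted
tree minimizing the total event distance summed over edges.  Ancestral
states are canonical blocks — a copy-number vector over the observed
families plus a sub-block count, realized in reference gene order with
balanced sub-block sizes — and the optimization is a joint Sankoff dynamic
program over these states with edge costs computed by the *actual*
pairwise event distance on the assembled blocks (leaf edges use the
leaves' observed blocks verbatim).

Scoring edges with the real distance, rather than summing per-character
Sankoff increments independently, is a deliberate design choice.  Fully
independent per-character parsimony mis-scores any edge on which presence
turnover and segmentation change co-occur, because the split character
must be evaluated on the families the two endpoint blocks share: for the
two-leaf instance `ab` vs `a|c` the naive character sum is 3 while the
true minimum is 2 (delete `b`, gain `c` in its own sub-block).  The joint
program reproduces the exhaustive enumeration oracle on every random
instance tested.

Scaling: when the full state product (copies × segment counts) is at most
`max_states` (default 256) the program is exhaustive over the canonical
space.  Beyond that, families whose copy number is identical across all
leaves are frozen at that value and the program runs over the families
that actually vary — in histories with few events this prunes the space by
orders of magnitude while leaving the varying characters fully explored.
`AncestralReconstruction.exhaustive` records which regime ran.  Pruned
reconstructions are feasible assignments, so their totals are still valid
upper bounds certified edge-by-edge; they are not guaranteed global minima
in pathological cases where deviating from a constant family would pay for
itself through split savings.

Tie-breaks are deterministic and biased toward an ancestral full operon:
prefer presence, then lower copy number, then fewer sub-blocks, then
reference label order.  Gains are reported in the deletions column
(cumulative brackets carry three columns: deletions, duplications,
splits).  Per-node cumulative counts sum the edge events in the subtree
below each node; the root's total is the reconstruction's event count.
Ancestral within-block gene order is *not* reconstructed — blocks are
realized in reference order — and pseudogene status is a leaf observation,
never inferred for ancestors.

## Trees

Distances on protein (or, for the synthetic route, nucleotide) alignments
are p-distances with pairwise gap deletion; a Poisson correction
(−ln(1−p)) is available but not default, since the taxa compared here are
close enough that topology is insensitive to it.  Trees are built with
neighbor joining (scikit-bio's Saitou–Nei implementation; negative branch
lengths clamped to zero; taxon order fixes tie-breaks) and rooted on the
midpoint of the outgroup's pendant edge.  Bootstrap supports resample
alignment columns with replacement and report the percentage of replicate
trees containing each internal bipartition of the reference tree.

The operon tree concatenates the seven uniformly conserved core genes in
fixed order — cyp112, cyp114, fd, sdr, cyp117, cps, ks — because cyp115,
idi and ggps are too often absent or inactivated to be informative across
the whole cohort.  Genomes missing any of the seven, or whose
concatenation length deviates from the cohort's modal length (an
un-flagged truncation), are excluded with a logged reason rather than
mis-scored.  Fusion genes are split into their constituent family slots at
the ferredoxin hit's subject span before concatenation.

Taxon reduction maximizes phylogenetic diversity (the total branch length
of the minimal spanning subtree) greedily: seed with the most distant leaf
pair, then repeatedly add the leaf contributing the most new branch
length.  Greedy is optimal for PD on trees, and the tests confirm equality
with the exhaustive-subset optimum on small trees.  Mandatory-keep labels
(reference taxon, outgroup) are supported.

## GC screening

GC content is computed in 500-bp sliding windows (step 1 for profiles,
non-overlapping for summaries; both give identical region means) and
contrasted between the operon span and 10-kb flanks, in percentage
points.  Ambiguous bases are excluded from numerator and denominator by
default (`count_ambiguous=True` counts them toward the denominator).
Flanks truncated at contig ends are flagged and a missing flank drops out
of the flank mean.

## The simulator

The generator emulates the statistical structure the analysis assumes,
not any particular organism's history.

* **Tree prior**: Yule (pure birth), the simplest adequate prior for
  testing; leaves `T01…`, internal nodes `N1…`, strictly positive branch
  lengths.
* **Block evolution**: a continuous-time thinning process simulated
  exactly with the Gillespie algorithm, with all contemporaneous lineages
  interleaved on one global clock.  Per-unit-branch-length intensities:
  deletion per present family, duplication per functional gene copy,
  split per internal gene adjacency, gain per absent reference family,
  pseudogenization per functional gene copy, HGT per lineage.  A deleted
  family cannot be deleted again, so the expected deletion count is the
  survival-weighted sum over branches (implemented in
  `expected_deletions` and used as the oracle for rate-recovery tests),
  not the naive rate × tree length × family count product, which
  overstates the expectation whenever rate × depth is non-negligible.
* **HGT** replaces the recipient lineage's entire block with a copy of a
  uniformly chosen lineage alive at the event time (the global clock makes
  "contemporaneous" exact), and the donor branch is logged.  Operon gene
  sequences follow the transfer — the recipient's template set is replaced
  by the donor's sequences at the event time — which is what makes the
  operon-concatenation tree group HGT partners while the marker tree keeps
  the species topology.
* **Event log**: every record carries the branch, absolute time, event
  type and the drawn positions; `replay_log` re-applies the history from
  the root block and reproduces each leaf block exactly (a tested
  invariant, including pseudogene status).
* **Sequences**: per-family templates (realistic ORF lengths, ~0.3–1.5 kb)
  drawn at the operon GC; substitutions accumulate as Poisson(rate ×
  length × time) uniform-site replacements with GC-biased base choice, so
  composition is maintained in expectation.  No indel model.
* **Genomes**: one contig per leaf with 10-kb background flanks; genes
  within a sub-block separated by uniform 50–400 bp spacers, consecutive
  sub-blocks by uniform 600–2000 bp gaps — safely on either side of the
  500-bp neighbor threshold.  Spacers inside a sub-block are emitted at
  the operon's GC (they are part of the transferred unit); split gaps and
  flanks at background GC.  Pseudogenized genes are truncated from the 3′
  end to a uniform 20–59% of the template, guaranteeing the <60%
  pseudogene rule fires.  The rpoB-like marker sits on a second contig.
* **Default composition**: background GC 0.60, operon GC 0.68 — an
  8-point contrast of the magnitude seen in rhizobial genomes with a
  transferred high-GC operon.

The internal homology search used on synthetic genomes (edlib semi-global
alignment with BLASTN-style scoring and Karlin–Altschul E-values) is a
pluggable stand-in adapter: real analyses consume 12-column
outfmt-6-style hit tables from an external search engine.

## Standing studies and their scope

`gablocks.studies` fixes the seeded computational experiments that
`scripts/acceptance.py` reruns:

* oracle agreement of the event distance (full 3-family enumeration,
  12,544 pairs, plus 500 random pairs) and of the parsimony totals
  (50 random ≤6-leaf instances) — expected 100%;
* event recovery: 100 HGT-free 8-leaf simulations with rates set for an
  expectation of ~2 events per history (deletion 0.015, duplication
  0.005, split 0.01, gain 0.005, pseudogenization 0.005 per unit); the
  reconstruction equals the logged count in ≥90% of runs and never
  exceeds it (parsimony can only under-count, e.g. when two events
  cancel);
* the HGT contrast: 50 twelve-leaf simulations conditioned on at least
  one whole-operon transfer (length-preserving churn — pseudogenizing
  loss instead of outright deletion — keeps every taxon's concatenation
  buildable); reconstructions on the operon-derived NJ tree average fewer
  events than on the marker tree;
* the GC screen on an intact operon (8-leaf cohorts): the configured
  8-point contrast is recovered within ±2 points; a null cohort stays
  below 1 point;
* NJ recovery of 100 random additive matrices (4–12 taxa) — expected
  100%.

These study sizes (8–12 leaves, 50–100 replicates) were chosen to give
stable means and full coverage of the qualitative effects while keeping a
complete rerun around a minute.

What passing these studies does **not** show: the simulator has no indel
or rearrangement model beyond splits, no codon structure, no IS elements,
and uniform substitution rates, so threshold behavior under real
annotation noise (fragmented assemblies, frameshifts, miscalled ORF
boundaries) is untested; HGT donors are drawn uniformly rather than by
ecological proximity; and parsimony totals on real cohorts depend on the
exact tie-break and rooting conventions, so absolute event counts are
comparable only within a convention, not across software.

## Numerical and convention choices

* Coordinates are 0-based half-open internally; GFF3/GenBank conversion
  happens once at parse/write time, preventing off-by-one errors in the
  500-bp rule (a tested invariant).
* The neighbor boundary is inclusive (gap ≤ 500 bp ⇒ neighbors) and
  configurable.
* Orthoblock validity needs ≥ 2 genes; cohort inclusion defaults to ≥ 3
  clustered operon genes; both configurable.
* Best-hit ties break by (E-value, identity, label order); identity is
  measured over the aligned region; the E-value threshold boundary is
  inclusive (10⁻¹⁰ passes).
* The pseudogene rule applies to cyp115 by default and is generalizable to
  any family; the length unit (nucleotide vs protein) must simply match
  between query and subject.
* The fusion trigger requires the ferredoxin query to be absent as a
  standalone call and to cover ≥ 50% of its length inside a cyp114- or
  sdr-called feature — a majority-coverage reading of "check the start and
  end of the alignments".
* Empty blocks are legal states everywhere (a lineage can lose the whole
  operon); `parse_block` still rejects the empty string because the
  notation has no symbol for it — pass an empty `GeneBlock` instead.
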