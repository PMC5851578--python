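# Methods

`carp` discovers low-divergence repeat families in a genome assembly ab
initio, builds per-family consensus sequences with a full audit trail,
classifies them against reference libraries, separates segmental
duplications (SDs) from novel transposable elements (TEs) by
copy-number/length analysis, and flags potentially active LINE-type
elements by ORF/reverse-transcriptase scanning.  This note records the
model, the parameters that matter, and the numerical choices made where
the design was open.

## Self-alignment model

Repetitive DNA is identified by all-vs-all local self-alignment.  The
aligner is seed-and-extend in the PALS/PILER tradition:

1. **Seeding.** Canonical k-mers (k = 12 by default; the minimum of a
   k-mer and its reverse complement) are indexed over the whole assembly;
   k-mers containing N are excluded, and multi-record assemblies are
   joined with N spacers so no k-mer spans a boundary.  Every pair of
   positions sharing a canonical k-mer is a seed; matching canonical
   strands give a same-orientation seed, mismatching strands an
   opposite-orientation one.
2. **Occurrence capping.** When a k-mer occurs more than
   `occ_all_pairs_max` (30) times, each occurrence is paired only with its
   `occ_neighbor_links` (4) nearest neighbours in genome order rather than
   all-vs-all.  Single-linkage clustering needs connectivity, not the
   complete pair set, so high-copy families (thousands of copies) remain
   tractable while low-copy loci still get every pair.
3. **Chaining.** Seeds sorted by (orientation, diagonal, position) are
   chained greedily; a chain breaks at a diagonal jump larger than
   `band_width` (32) or a positional gap larger than `chain_gap` (200 bp).
   Chains with fewer than `min_chain_seeds` (3) seeds are dropped — an
   alignment long enough to pass the length gate carries dozens to
   hundreds of seeds, while random 12-mer coincidences carry one.
4. **Extension.** Each chain is extended by banded affine-gap local
   dynamic programming (match +1, mismatch −2, gap open −4, gap extend
   −1; band = chain diagonal range ± `band_width`, region = chain
   bounding box ± 200 bp).  The scores are chosen so a 94%-identity
   alignment scores well above zero.

An alignment is reported iff identity ≥ `min_identity` (-dpid, default
0.94) and both genomic images are ≥ `min_length` (-dplen, default 250 bp).
Identity is matches / alignment columns *including gap columns*, the
strictest common convention, so the gate is conservative.  Pairs whose two
images overlap each other (tandem self-overlaps) are discarded — the
pipeline targets dispersed families.  Duplicate alignments of one locus
pair collapse to the highest-scoring one.  The -dpid/-dplen thresholds are
the published interface of this stage; the seeding and chaining knobs
above are implementation choices, exposed as configuration.

## Families and the audit trail

Alignment images are merged into **element instances** ("piles"): two
images join the same instance iff, transitively, they overlap by at least
`pile_min_overlap` (0.5) of the shorter image.  Any-overlap merging chains
adjacent distinct elements; 0.5 tolerates boundary jitter.  Nested
insertions that pass the overlap threshold merge into one instance — this
is inherent to single-linkage behaviour and is documented rather than
patched.

**Families** are the connected components of the graph whose nodes are
instances and whose edges are alignments linking two distinct instances;
singleton components are dropped.  The edge list is retained per family,
and members are exported with ids that encode family, instance and genome
interval — the audit trail that lets every consensus be traced back to the
exact genomic sequences behind it.  Member orientation is resolved by
propagating relative strand over the alignment graph (opposite-orientation
edges flip sign) and flipping the family to make '+' the majority.

## Consensus construction

Per family, members within `length_fraction` (0.95) of the longest member
are eligible; at most `max_sample` (100) are drawn uniformly without
replacement (explicit seed; the longest member is always included, since
it defines the length constraint).  The sample is multiple-aligned by
center-star progressive alignment with the longest member as center —
members passing a ≥94% pairwise gate make star alignment adequate, and an
external MSA program can be swapped in behind the same contract.  The
consensus takes the most frequent base per column (ties A<C<G<T, fixed);
columns where the gap is a strict majority are dropped, and consensus
length is capped at 1.05× the longest sampled member — together these
prevent indel-driven consensus expansion.  N is emitted only when a column
is entirely N.

## Cleaning, classification, genome annotation

Consensuses are removed when (a) ≥ `ssr_cov_max` (0.8) of their length
lies in simple-sequence-repeat tracts (tandem unit ≤ 6 bp, ≥ 4 copies,
≥ 12 bp run), or (b) they hit the host protein set (six-frame translated
local alignment, BLOSUM62, ungapped Karlin–Altschul E-value with λ = 0.318,
K = 0.13, search space = frame length × total database length) at
E ≤ 1e−5 *without* any equally significant hit to the
retroviral/reverse-transcriptase protein set.  The second clause keeps
autonomous elements whose coding sequence legitimately appears in curated
protein databases while removing host gene families with many paralogs.

Survivors are classified against a nucleotide TE library
(Repbase-dialect `name#class/subclass` headers or a TSV class map):
**well annotated** when hits to a single reference jointly cover
≥ `well_annotated_cov_min` (0.8) of the consensus — the operationalisation
of "almost full length", config-exposed since no published number exists;
**partially annotated** when some hit is ≥ `partial_hit_min_bp` (50 bp);
otherwise **unannotated**.  Partial ∪ unannotated form the *unclassified*
set.

The combined library (kept consensuses + TE references) is then aligned
back to the genome at a relaxed identity floor (`annotate_min_identity`,
0.80) — this recovers copies more diverged than the self-alignment gate.
Overlapping genome hits are resolved best-hit-first: a lower-scoring hit
is trimmed to its longest unannotated stretch and discarded below 30 bp,
so no genome position contributes to two classes.  Per-class coverage
percentages summarise the result.

## SD vs novel-TE triage

SDs are long, low-copy, high-identity duplicates, so among unclassified
consensuses copy number is the discriminator: one record per unclassified
consensus counts its resolved (post-trim) genome hits.  Records with
copies > `high_copy_threshold` (2,000, strict) go to high-copy review as
novel/partial TE candidates, with per-position coverage profiles (peaks =
maximal runs ≥ `peak_frac` (0.5) × max depth and ≥ 30 bp — both invented
knobs, config-exposed) to distinguish uniform full-length coverage (novel
TE) from localised peaks (conserved fragments).  Everything else is an SD
candidate.  An OLS regression of log10(copies) on log10(length) via the
closed-form normal equations (zero-copy records excluded — forced by the
log transform — and reported separately) summarises the copy-number/length
relationship; standard errors, t and p come from the usual s²(XᵀX)⁻¹.

## Active-element scan

An element is potentially active iff it has an intact long ORF
(ATG→stop, no internal stops, ≥ `min_orf_nt` = 1,500 nt, all six frames)
whose protein carries a reverse-transcriptase domain: best local BLOSUM62
alignment against user-supplied RT reference proteins with envelope
≥ `min_rt_aa` (200 aa) and E ≤ 1e−5.  ORF1 state is deliberately ignored.
Profile-HMM domain search is replaced by local protein alignment against
explicit RT references, keeping the 200-aa envelope rule; an HMM backend
can be plugged in behind the same contract.  The E ≤ 1e−5 gate is a
stand-in default (no published threshold), config-exposed.
"No inactivating mutations" is operationalised as ORF contiguity:
frameshifts and nonsense mutations both break the ATG→stop walk.

## Synthetic genomes and what the tests show

The generator plants, on an i.i.d. background of configurable GC
(default 0.42; Markov structure is unnecessary because spurious 12-mer
sharing is already negligible at these sizes): dispersed TE families
(ancestor mutated per copy by substitutions then short indels, optional
5′-exponential truncation mimicking LINE insertion biology), low-copy
high-identity SDs, host gene families (reverse-translated random
proteins, emitted to the host protein set), SSR tracts, and autonomous
families whose ancestor carries an intact ≥1.5 kb ORF embedding an RT
protein.  Copies are placed uniformly at random on random strands with a
guaranteed 150 bp background gap between insertions — without the gap,
abutting copies create chimeric junction alignments that falsify the
truth table's own intervals.  Every copy's location, strand, identity and
truncation are recorded; generation is deterministic given the seed.

Two reference scenarios (in `carp.scenarios`) define the benchmark
conditions: a ~1.07 Mb assembly with five families spanning 20–200 copies
and ~95–99% pairwise identity (one 5′-truncated), three SDs (8–18 kb,
2–3 copies), a host paralog family and an RT-carrying family; and a
~1.27 Mb assembly with a 2,500-copy novel element plus three SDs.  These
sizes keep a full pipeline run under ~1 minute each while exercising every
stage at realistic repeat densities.

What passing these tests does *not* show: real assemblies have nested and
fragmented insertions, CpG-biased mutation, gap runs, tandem arrays and
assembly artefacts that the generator does not emulate; the i.i.d.
background understates k-mer collisions in low-complexity regions; and
SSR/host fixtures are idealised.  The synthetic results validate the
machinery and its contracts, not genome-scale annotation accuracy.

## Known limitations

- The center-star MSA is adequate at ≥94% member identity but inferior to
  iterative MSA for diverged families; the consensus contract allows an
  external aligner.
- Occurrence capping means the alignment list for very high copy
  families is a connectivity-preserving subset, not the complete pair set;
  family membership and consensus quality are unaffected, but exhaustive
  pair lists for >30-copy families require raising `occ_all_pairs_max`.
- Best-hit trimming rescales trimmed hits' query coordinates linearly,
  an approximation inside gapped alignments.
- E-values use ungapped Karlin–Altschul constants with gapped scores — a
  standard, deterministic approximation that is conservative at the 1e−5
  gate used here.
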