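# carp

Ab initio discovery, clustering and annotation of **low-divergence repeat
families** — recently or currently active transposable elements (TEs) and
segmental duplications (SDs) — in genome assemblies.

## The problem

Most of a vertebrate genome's repetitive DNA descends from mobile
elements.  Library-based annotators only find what a curated library
already knows, and the widely used ab initio consensus builders emit broad
consensus sequences without recording which genomic copies produced them,
which makes it impossible to study the evolutionary dynamics of young TE
families — or to notice that a "repeat family" is actually a segmental
duplication or a host gene family with many paralogs.

`carp` targets exactly that niche.  The pipeline is five steps:

1. **Self-alignment** — all-vs-all seed-and-extend local alignment of the
   assembly, reporting pairs with identity ≥ *dpid* (default 0.94) over
   ≥ *dplen* bp (default 250).
2. **Clustering** — overlapping alignment images merge into element
   instances ("piles"); instances linked by alignment are single-linkage
   clustered into families, keeping the full edge list (the audit trail).
3. **Consensus** — per family, members within 95% of the longest member
   (at most 100, sampled with a fixed seed) are star-aligned and a
   majority-vote consensus is called, with gap-majority columns dropped to
   prevent indel-driven expansion.
4. **Cleaning & classification** — SSR-dominated consensuses and host
   gene families (translated hit to the host protein set at E ≤ 1e−5 with
   no retroviral/RT hit) are removed; survivors are classified against a
   TE reference library as well annotated / partially annotated /
   unannotated.  Partial ∪ unannotated form the *unclassified* set.
5. **Genome annotation & SD triage** — the combined library (consensuses
   + TE references) is aligned back to the genome at a relaxed 0.80
   identity floor, overlaps resolved best-hit-first; among unclassified
   consensuses, low genome-hit copy number marks SD candidates while
   copy number > 2,000 flags novel-TE candidates for coverage-profile
   review.  A log10–log10 regression of copy number on consensus length
   summarises the relationship.

A separate scan flags **potentially active** LINE-like elements: an
intact ORF ≥ 1,500 nt (ATG→stop, no internal stops) whose protein carries
a reverse-transcriptase domain (local BLOSUM62 alignment to RT references,
envelope ≥ 200 aa, E ≤ 1e−5) — regardless of ORF1's state.

A built-in synthetic-genome generator plants TE families, SDs, host
paralog families, SSR tracts and RT-carrying elements with a
machine-readable truth table, so the whole pipeline is testable without
external data.  See `docs/methods.md` for the full model description.

## Worked example

Simulate a 120 kb assembly with two planted TE families and one 6 kb
segmental duplication, then run the pipeline using the planted ancestors
as the TE reference library:

```bash
carp simulate --out sim --seed 11 --background 120000 \
  --family teA,1200,15,0.01,LINE --family teB,700,25,0.005,SINE \
  --sd sd1,6000,2,0.97
carp run --genome sim/genome.fasta --te-lib sim/te_library.fasta \
  --out run --seed 11
```

`run/classification.tsv` shows both planted families recovered with their
full copy counts and classified against the library, while the SD pair —
absent from any library — stays unclassified:

```
consensus	length	class	te_class	n_members_sampled	best_ref
family000001	704	well_annotated	SINE	25	teB#SINE
family000002	1206	well_annotated	LINE	15	teA#LINE
family000003	6003	unannotated	Unclassified	2	
```

`run/repeat_summary.tsv` gives per-class genome coverage after best-hit
overlap resolution (IR = interspersed repeats, SD = the unclassified,
SD-candidate fraction):

```
class	percent_of_genome
SINE	10.4579
LINE	10.7499
...
IR	21.2078
SD	7.0919
Total	28.2997
```

and `run/sd_triage.tsv` places the 2-copy unclassified consensus in the
SD-candidate bin:

```
consensus	length	copies	bin
family000003	6003	2	sd_candidate
```

Every consensus in `run/manifest.json` links to its sampled member
instances and their genome intervals; `run/families/*.fasta` holds the
member sequences themselves, ready for external alignment or tree
building.  Stage subcommands (`carp align`, `cluster`, `consensus`,
`annotate`, `sd`, `activescan`, `simulate`) rerun any stage
independently; `--dpid` accepts a fraction (`0.94`) or percent (`94`).

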