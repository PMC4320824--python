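# Methods

## Scope and model

`varcohort` compares short-variant call sets (SNPs and short insertions /
deletions) from several resequenced lines of one cultivar against a
common reference genome. The scientific question it serves is whether a
treatment group of lines (e.g. *Agrobacterium*-transformed transgenic
rice) differs genome-wide from untreated wild-type lines of the same
cultivar. The unit of comparison is the **variant site**, identified by
the full allele tuple `(chrom, pos, ref, alt)`; a variant is *shared*
between lines only when that tuple is identical, and *line-specific*
when exactly one line of the cohort carries it. Upstream read alignment
and variant calling are out of scope: the pipeline starts from per-line
VCFs, per-line bedgraph depth tracks, and a chromosome name/length
index.

## Filtration

Calls covered by more than `max_site_depth` reads (default 10,000,
strict inequality) are excluded first — extreme depth marks collapsed
repeats. Three criteria follow, in a fixed order:

1. **Quality** — the phred-scaled call quality must be at least
   `min_quality` (default 30, i.e. a false-positive probability of at
   most 0.001). Inclusive threshold; applied per call; a site left with
   no carrier is dropped.
2. **Coverage in all lines** — the variant position must be covered by
   at least `min_reads_all_lines` reads (default 4, inclusive) in
   *every* line, whether or not that line carries the variant.
   Otherwise absence of the variant in a poorly covered line could not
   be distinguished from failure to observe it. Depth comes from the
   per-line coverage track (post-deduplication), not from the VCF `DP`
   of the carrier. For a deletion, every deleted base (plus the anchor)
   must meet the threshold in every line; `deletion_span="anchor"`
   relaxes this to the anchored position only.
3. **Type consistency** — if different lines carry variants of
   different alteration type (SNP vs insertion vs deletion) at the same
   position, all calls at that position are removed. This makes the
   sharing profile well defined. Two SNPs with different ALT alleles at
   one position are the *same* type and are kept as two distinct,
   unshared sites.

Per-call filters run before the cross-line consistency filter, so a
call removed for low quality cannot create a type conflict. One
consequence worth knowing: the surviving site set is *not* globally
monotone in the thresholds. Tightening `min_quality` can remove one
partner of a type conflict and thereby rescue the other site from
criterion-3 exclusion. The per-call and coverage criteria on their own
are monotone, and the test suite checks exactly that.

Filtration is idempotent and independent of the order in which lines
are supplied.

## Statistics

- **Mutation rate** (per-site divergence, not per-generation):
  line-specific variant count divided by the line's *covered length*
  (bases with depth ≥ 1). Displayed at 3 significant digits; full
  precision retained everywhere.
- **Substitution spectrum**: the 12 directed single-base substitutions
  of the line-specific SNPs; transitions are A↔G and C↔T. Group
  spectra pool per-line counts; the group Ts/Tv ratio is the ratio of
  pooled transition to pooled transversion counts (equivalent to the
  ratio of per-line means, since every line is divided by the same
  group size).
- **Alignment summary**: mapping rate = mapped/total reads × 100;
  coverage rate = covered length / genome length × 100; depth =
  mapped reads × read length / covered length. For the bundled example
  data this formula yields 101.1× for line 50A while the source table
  prints 101.3×; adapter or quality trimming that shortened effective
  read length would explain the difference. The implementation follows
  the stated formula.
- **Windowed density**: counts in consecutive non-overlapping windows
  (default 500 kbp) anchored at position 1; a variant at position *p*
  falls in window ⌊(p−1)/window_size⌋; the final partial window is not
  length-normalized. Group profiles are element-wise means over lines;
  the per-chromosome contrast is the maximum over windows of the
  absolute difference of the two group means. By default the window
  profiles are computed on all post-depth-exclusion variants (the
  population behind the "total detected" counts), since density peaks
  near centromeres are dominated by calls the consistency filter later
  removes; a flag switches to the fully filtered set.

## Effect classification

Each line-specific variant receives exactly **one** of 23 effect types,
so per-line effect counts sum exactly to the line-specific totals. The
types map onto four impact categories (HIGH 6, MODERATE 5, LOW 5,
MODIFIER 7). Candidates are collected per overlapping transcript and
the most severe is kept, under a fixed severity ordering (splice sites,
then start/stop changes, frameshift, the in-frame codon changes,
the LOW-impact coding effects, then the non-coding MODIFIER types);
with several genes or transcripts the most severe across all of them
wins.

Conventions: up/downstream extends 5,000 bp from the gene span; splice
donor/acceptor are the first/last 2 intronic bases of each intron
(strand-aware); the splice region covers intronic bases 3–8 and the
outermost 3 exonic bases of a junction; START_GAINED is a 5′-UTR SNP
creating an ATG; NON_SYNONYMOUS_START is a start-codon SNP producing an
alternative initiation codon (CTG/GTG/TTG), START_LOST any other
start-codon change; in-frame indels are CODON_INSERTION/DELETION when
the affected coding coordinates align with codon boundaries, and the
CODON_CHANGE_PLUS_* variants otherwise; INTRAGENIC covers positions
inside a gene but outside its transcript features (and exons of
non-coding transcripts). UTRs are derived from exons minus CDS, so GFF3
inputs without explicit UTR features work. Gene models are read with
`gffutils`; codon translation uses Biopython.

The classifier deliberately omits what the analysis does not need:
no multi-effect output, no codon-usage or protein-domain reasoning, no
transcript biotype hierarchy, no transgene-integration breakpoint
detection.

## Synthetic cohorts

The generator emulates the structure the analysis assumes, with exact
truth: a common block present in all lines, configurable shared
patterns, per-line private blocks, and planted violations of each
filter (sub-threshold quality, a depth-3 non-carrier position,
SNP-vs-insertion conflicts, over-depth calls, complex substitutions).
Violations are planted by explicit assignment, never by sampling, so
per-filter removal counts are exact. Default parameters are the study
conditions at one-tenth scale: privates 80/62/84/52/83, common 1,037,
SNP/ins/del fractions 0.58/0.10/0.32, group Ts/Tv 1.12 (transgenic,
with G>T/C>A excess) and 1.65 (wild type), quality ~ truncated normal
(mean 60, sd 15, floor 30), baseline depth 50× with two 5-kbp
uncovered gaps per line. Positions are drawn uniformly per chromosome
without replacement, with a minimum spacing of 8 bp so variant spans
and planted coverage overrides never interact; an optional
centromere-peak mode concentrates part of the common block near the
chromosome midpoints. One seed drives everything through deterministic
sub-streams, and output files are byte-identical across runs.

What the simulation does *not* emulate: linkage and haplotype
structure, mapping-error hotspots near repeats, genotype-likelihood
noise, multi-allelic sites beyond planted conflicts, and real gene
density. Passing the recovery tests therefore demonstrates correctness
of the bookkeeping and statistics, not robustness to every artefact of
real short-read data.

The toy gene generator writes a two-chromosome FASTA and GFF3 pair: a
plus-strand three-exon gene whose planted variants cover all 23 effect
types by construction (designed codons, junction bases, UTR contexts),
and its reverse-complement mirror on the minus strand. Mirrored SNPs
must receive identical labels (strand symmetry); anchored-indel mirrors
are planted only where the VCF anchor convention maps cleanly across
strands (frameshift, whole-codon deletion).

## Numerical and design choices

- Boundary readings: depth > 10,000 excluded (strict); quality ≥ 30 and
  coverage ≥ 4 retained (inclusive).
- Multi-allelic VCF records are split into one call per ALT allele;
  equal-length multi-base substitutions are counted separately as
  complex and excluded from SNP/ins/del tallies.
- Positions are 1-based internally; bedgraph 0-based half-open
  conversion happens only at the I/O boundary. Chromosome names match
  exactly (an explicit alias table may be supplied; no fuzzy matching).
- VCF QUAL survives a round trip only to float32 precision (the
  underlying htslib representation); tests compare it at rel. 1e-5.
- Ts/Tv is undefined (reported as NA) when the transversion count is
  zero.
- Problem sizes in the test suite — the default ~1,700-site cohort,
  100 random toy cohorts for the sharing oracle, 10,000-draw spectrum
  recovery — were chosen as the smallest scales at which the checks are
  statistically meaningful; the whole suite runs in a few seconds.

## Known limitations

- The effect classifier indexes transcripts with per-base dictionaries;
  fine for cohort-scale line-specific sets (hundreds of variants,
  kilobase transcripts), not tuned for annotating millions of variants
  against a full genome annotation.
- The all-lines coverage criterion reads the whole bedgraph into
  memory per line.
- Sharing treats allele tuples exactly; no normalization of equivalent
  indel representations (left-alignment is assumed done upstream).
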