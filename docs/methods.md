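# Methods

## Scope and coordinate conventions

`miredit` analyzes mutation/editing (M/E) sites of miRNAs in a
tumor/normal small-RNA cohort and the downstream retargeting of
seed-edited miRNAs. The internal alphabet is DNA (`T`); `U` appears
only in displayed site and variant names (`hsa-mir-29c_59_C_u`,
`hsa-mir-29c_59u`), mirroring the field's mixed usage. Genomic
intervals are 0-based half-open internally; every user-facing
pre-miRNA position is 1-based, so "the 48th nucleotide" is
`sequence[47]`. Hairpins annotated on the minus strand carry the
reverse-complemented genomic slice, and mature-arm coordinates are
converted to hairpin-local positions, so all site arithmetic happens
in one 5'→3' frame.

## Read processing

A read passes quality control iff every base quality among its first
25 nucleotides is ≥ Q30 (reads shorter than 25 nt are checked over
their full length). The published processing describes the small-RNA
threshold once as "greater than 30" and the PAR-CLIP one as "at least
30"; we use ≥ 30 uniformly. 3'-adapter trimming is exact-match: the
longest read suffix equal to an adapter prefix of ≥ 6 nt is removed.
Reads with no adapter hit are discarded — an untrimmed read could
carry templated genomic 3' bases that would masquerade as untemplated
tails — as are inserts shorter than 18 nt. Survivors are collapsed to
unique tags carrying a multiplicity and position-wise mean qualities;
all downstream counting is tag-based.

## Placement and the untemplated-tail rule

Tags are placed on the hairpin set by pigeonhole k-mer seeding (three
6-mers over the first 18 nt guarantee a hit at ≤ 2 substitutions)
followed by extension; an external aligner would add nothing for a
reference of this size. A placement aligns a tag prefix with at most
`max_mm = 2` substitutions. Bases running past the hairpin 3' end are
necessarily tail; in addition, the contiguous trailing-mismatch run is
classified as tail exactly when it begins within `max_tail = 4` nt of
the read end — trailing mismatches further in remain internal
mismatches. Among competing placements, the longest aligned body wins,
then the fewest mismatches; all tied optima are kept (this is what
feeds the cross-mapping correction). `max_mm` and `max_tail` are
declared defaults, tunable in the configuration: they accommodate a
single editing event plus a short tail without opening the door to
spurious placements.

One consequence worth knowing: a 2-nt tail whose second base happens
to match the genomic continuation is recorded as an internal mismatch
at the first tail offset rather than as a tail, because the mismatch
run no longer touches the read end. The affected (position,
alternative) pair is the same either way, and the positional
classifier assigns the same 3' category, so site-level results are
unchanged.

## Cross-mapping correction and Pseudo evidence

The aligned body of each tag is re-searched exactly against both
genome strands. A tag's unit weight is spread over its genomic loci by
iterative proportional allocation: locus expression is the
count·weight mass of all tags at the locus, and each iteration resets
weight(tag→locus) ∝ expression, to an L∞ fixed point (tolerance 1e-9,
≤ 100 iterations; non-convergence keeps the last iterate with a
warning). On the canonical two-paralog instance with unique support of
90 vs 10 reads, the shared tag's fixed point is exactly 0.9/0.1
regardless of the shared count — including shared tags in the
expression term does not bias the split. Tags with no exact genomic
hit (every read carrying a true editing event) fall back to the loci
implied by their hairpin placements, so weights always sum to 1 per
tag.

The weight a site's supporting tags lose to loci outside the site's
hairpin is its `alt_locus_share`; a share above 0.5 marks the site
Pseudo (its variant reads are better explained by another perfect
genomic locus). This threshold is a declared parameter: the source
analysis names the Pseudo category without publishing a rule.

## Pileups and site significance

Pileups accumulate count·weight coverage at every position a placed
tag occupies — including its tail offsets, which may run past the
hairpin end. Including tail positions in coverage is what makes
editing levels at 3'-addition sites well-defined and keeps the
invariant that edited mass never exceeds coverage at any position.

Every covered (position, alternative) pair is evaluated per sample.
The editing level is edited/total weighted mass; the p-value is the
one-sided binomial tail P(X ≥ k) with k and n the rounded weighted
counts and e = 10^(−Q̄/10) from the mean supporting base quality,
floored at 1e-3 (the Q30 error rate) so that optimistic quality
strings cannot fabricate significance. The published analysis does not
print its significance formula; the binomial sequencing-error null is
our declared choice and matches what the retention criteria are
guarding against. Benjamini–Hochberg adjustment runs over all
evaluated pairs of the sample, including zero-support pairs at p = 1 —
they change m and thus make the adjustment slightly conservative. A
site is significant when simultaneously level ≥ 5%, weighted support
≥ 10 reads and adjusted p < 0.05; we interpret the 10-read rule on
weighted support, since weights are near-integers except at shared
paralog arms. Cohort retention keeps sites significant in at least
⌈0.10 · n_samples⌉ samples — the ceiling convention is forced by the
published arithmetic (10% of 176 → 18). Retained records carry
per-sample levels with an explicit distinction between a measured 0
(coverage, no variant) and missing (no coverage).

## Classification

Pseudo evidence overrides position; then, relative to the mature arms:
mature position 1 or anything upstream of a mature 5' end is
5'-editing; an offset within `max_tail` past a mature 3' end is 3'-A /
3'-U / 3'-Other by the added base; a central mature position (2 to
length−2) gives A-to-I for A→G, C-to-U for C→T, anything else Other;
the last two mature positions fall to Other (a templated mismatch
there is indistinguishable from tail artifacts, so we keep the central
window conservative; the boundary is configurable). SNP status is a
separate reclassification requiring all four published criteria:
identical genomic position to a known SNP, identical alleles
(strand-adjusted on minus-strand hairpins), a 100% level in at least
one sample, and a central mature position. The known-SNP table is a
TSV standing in for dbSNP-style lookups; database mirroring is out of
scope.

## Differential stage

Editing levels are compared tumor vs normal with a two-sided
Mann–Whitney U test: exact enumeration for small tie-free samples,
otherwise the normal approximation with tie correction (scipy's
`method="auto"`); at the study's 154-vs-22 sizes the approximation is
standard. Missing levels are excluded pairwise, never imputed — a
zero with coverage is a real measurement. BH adjustment runs across
all tested sites; direction comes from group means, falling back to
medians on a tie and to "unchanged" if still tied. Under a null cohort
(both groups drawn from the same Beta(2, 8) level distribution, 154 vs
22 samples, 1000 sites) the raw positive rate at α = 0.05 is ≈ 0.05
(0.036–0.054 across seeds in our checks), and BH leaves essentially
nothing significant.

Edited-miRNA expression uses TPTM (count · 10⁷ / mapped reads of the
sample), with a variant's count being the edited weighted mass of its
site. The published analysis fit these with a negative-binomial
package; that dependency is out of scope here and the same
Mann–Whitney machinery is applied to the TPTM rows — a documented
deviation, adequate for rank-based group comparisons though it ignores
count overdispersion modeling.

## PAR-CLIP targets

Reads are placed at their best transcript match in which every
mismatch is a transcript-T → read-C conversion (fewest conversions
wins); candidates come from exact search in a reduced alphabet where T
and C coincide, then verification. Maximal runs of covered positions
form clusters; clusters under 5 reads are dropped. Within each cluster
span ± 10 nt, exact reverse complements of miRNA positions 2–8 are
binding sites — position 1 typically pairs via an A-anchor rather
than by complementarity, so it is excluded from matching by default
(`seed_span` is configurable to 1–8). Sites need at least one
converted read. The Ps score is our declared reinterpretation of the
published per-site value, whose formula is not printed: the binomial
upper tail of the site's converted-read count at the
transcriptome-wide converted-read fraction. It is monotone in
conversion support and lives in [0, 1]. Gained/lost/common target
partitions come from set comparison of the original's and the edited
variant's site lists; "more than 10 converted reads" filtering is
strict, per the published wording; deregulated-gene overlap intersects
the gained targets with every supplied list.

## The synthetic-data generator

The generator emulates the study's inputs, not its biology in full.
Hairpins are 80-nt random sequences with 22-nt arms at fixed offsets,
embedded on both strands of two synthetic chromosomes with random
spacers; paralog pairs differ at exactly ⌈(1−identity)·80⌉ positions.
Random arms are alignment-clean stand-ins — real hairpins fold, share
families, and overlap repeats, so cross-mapping here is exercised only
through the explicit paralog pairs. Cohort reads are drawn per arm at
Poisson depth with uniform 0–2 nt 3' trimming (isomiR end variation
without a citable model), planted variants applied independently per
read at the group's level, per-base errors at the configured rate,
geometric untemplated tails (mean 1.5 nt, capped at 4 — published
figures show single-nucleotide tail categories, and the cap keeps
alignment well-posed), and the exact adapter appended. Base qualities
encode the error rate on the Phred scale (Sanger +33), which is what
makes the Q30 filter meaningful; there is no quality-by-cycle decay,
ligation bias, or realistic expression skew across miRNAs. Cohort
defaults mirror the profiled study (154 tumor / 22 normal); per-sample
seeds are spawned deterministically from the run seed, so identical
configurations are byte-identical. Sequencing depth per library is a
free parameter — the source study does not publish one.

PAR-CLIP fixtures embed seed-complement spans into transcripts that
were scrubbed of both motifs (and re-scrubbed after embedding, since
writing one motif can create a junction occurrence of the other),
pile converted reads over them, and scatter sparse background reads.
Passing tests therefore demonstrate correct recovery under controlled
truth, not performance on real AGO libraries with crosslink biases
and partial-complementarity sites.

## Validation problem sizes

The recovery benchmark runs twenty 12-sample cohorts (8 tumor / 4
normal) of 7 hairpins at coverage 300, error 1e-3, with substitutions
planted at levels 0.05 / 0.1 / 0.3 and tailing disabled — with tails
on, tail sites would be genuine unplanted events and a
false-positive count of zero would be unmeasurable. Level accuracy
uses one sample at coverage 5000, where binomial noise (SD ≈ 0.006 at
level 0.3) sits comfortably inside the ±0.02 acceptance band; at
coverage 500 the sampling noise alone would exceed it. The null
calibration uses 1000 sites at the study's 154/22 split; the PAR-CLIP
benchmark uses ten fixtures of six 1.5-kb transcripts. These sizes
keep the full validation under a minute on one CPU while leaving each
check statistically meaningful.

## Known limitations

Indel sites are represented in the naming scheme (`'-'` alleles) and
the classifier (they fall to Other) but the aligner only models
substitutions and 3' tails, so single-base insertions/deletions are
detected only in constructed inputs. Graphical per-hairpin maps are
out of scope; TSV reports substitute. GO/KEGG enrichment, external
editing databases (DARNED/RADAR) and expression regressions on public
tumor cohorts are likewise out of scope — the known-SNP TSV is the
only annotation lookup. The cross-mapping correction assumes loci
compete only through expression; it has no mapping-quality model.
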