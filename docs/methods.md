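# Methods

This note records the models and procedures `oralcap` implements, the
parameters that matter, what the synthetic-data generators do and do not
emulate, and the numerical and design choices made where the design was
genuinely open. No empirical claim here goes beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## Read QC

Two distinct filters serve the two pipelines.

**Metagenomic pool filter** (`readqc.filter_metagenomic_reads`): a read is
removed if its mean Phred quality is strictly below 25, its length strictly
below 50 bp, it contains any non-ACGT base, or it is an exact sequence
duplicate of an earlier retained read (first occurrence kept). Mean quality
is the arithmetic mean of Phred scores, not the error-probability mean,
matching common QC-tool behavior. The three predicate rules are independent
of each other and of evaluation order; a read failing several rules
increments every violated tally, so per-rule counts can exceed
`n_input − n_passed`. Deduplication applies only among reads that survive
the predicates.

**Locus pair filter** (`readqc.filter_locus_pairs`): a read pair is removed
when more than five bases across both mates have quality ≤ 3. Both bounds
are strict in the directions stated (`> 5`, `≤ 3`).

Exact duplicates here are a different notion from coordinate-based PCR
duplicates: `readqc.capture_metrics` therefore takes duplicate flags as
input rather than re-deriving them. Its on-target rule is configurable
(midpoint, any-overlap, full-containment; default midpoint) because
read-level target membership has no single standard definition.

## Substitution-bias profile

For reads mapped without indels or clipping (CIGAR exactly `<L>M` — any
other CIGAR would shift the positional register and is excluded), every
read-vs-reference mismatch increments a (strand, position, from→to)
counter; the rate is that count divided by the number of retained reads on
that strand. Reads are profiled in stored orientation: reverse-strand reads
are stored reverse-complemented (as in a BAM), so their original 5′ end
appears at the right of the profile. The profile deliberately does not
re-orient them — complementary damage signatures appearing at opposite read
ends on the two strands is the diagnostic signature this representation
makes visible.

## Aligner

`align.align_reads` is a small blastn-like seed-and-extend aligner so the
recruitment stage is testable end to end without an external program: exact
k-mer seeding (default k = 11) against each genome, candidate windows
merged per diagonal, and Smith–Waterman extension with affine gaps. The
dynamic program is Biopython's C pairwise engine in local mode; a gap of
length L costs `gap_open + L·gap_extend` (defaults 5 and 2, with match +1 /
mismatch −3). Traceback ties are resolved by the engine's deterministic
first-reported path; scores, identities and coordinates are unaffected by
tie choice, and the test suite checks score equality against an
independent full-matrix Gotoh implementation.

Significance uses the Karlin–Altschul form E = K·m·n·e^(−λS) with defaults
λ = 1.33, K = 0.621 (ungapped nucleotide values for +1/−3 scoring) and
n = effective database size (default: the summed genome lengths). Reported
hits respect an e-value ceiling of 0.01, mirroring an external aligner's
reporting cutoff; the recruitment tiers then apply their own stricter
ceiling. Reverse-strand hits are reported in read-forward coordinates with
`s_start > s_end`, the m8 convention. Percent identity is matches over
alignment columns, gaps included; read coverage is
`(q_end − q_start + 1)/query_length`, so subject gaps cannot inflate it.
Word size and filtering of production aligners are not modeled; both seeds
and scoring are configuration, and the pipeline's conclusions are checked
for robustness against the exhaustive-alignment oracle rather than against
any particular constant choice.

## Tiered recruitment and abundance

Tier thresholds (identity %, read-coverage floor, e-value ceiling):
lenient (50, none, 10⁻³), stringent (80, 0.75, 10⁻³), species (95, 0.75,
10⁻³). The lenient tier has no coverage floor; the species tier inherits
the 75% floor. Within a tier, a read goes to the passing hit with the best
bit score; exact ties are assigned to the lexicographically smallest genome
id and flagged ambiguous — assigning rather than discarding keeps abundance
deterministic while leaving ambiguity auditable. Reads are classified
independently per tier with no cross-tier reconciliation. Because the
thresholds are nested, assigned-read sets are nested
(species ⊆ stringent ⊆ lenient); this is asserted on every simulation.

Genome-length-normalized abundance is a(g) = (c_g/L_g) / Σ_h (c_h/L_h).
Rollup sums abundances within species, genus or phylum and conserves the
total exactly. The per-genome coverage track raises a localization flag
when ≥ 50% of recruited bases fall within ≤ 1% of the genome — the
heuristic for detections driven by one short conserved or contaminating
subsequence rather than genuine presence.

The m8 dialect has no query-length column; `seqio.read_m8` takes a sidecar
read-length map because the coverage thresholds need it. All intervals are
0-based half-open internally; m8 fields keep their on-disk 1-based
inclusive convention and are converted only where derived quantities need
it.

## Community statistics

Clustering is partition-around-medoids (deterministic BUILD + SWAP,
implemented in-package) on Bray–Curtis distances, both configurable; the
average silhouette width is scanned over k and the maximizing k reported.
No width threshold is imposed for declaring clusters "discrete" — widths
are reported and interpretation left to the analyst, with low maxima read
as evidence of a gradient. When all samples are identical the silhouette
is undefined and the scan returns NaN widths with a warning.

PCA operates on column-centered abundances; within each component the sign
is fixed so the largest-|loading| taxon is positive, making outputs
backend-independent.

The two-population comparison runs a two-sided Wilcoxon rank-sum test per
taxon over the union taxon set (absent = 0; zeros are true zeros, no
pseudocounts — "effectively undetected" reasoning depends on them), exact
for combined n ≤ 40 and asymptotic beyond, with Bonferroni correction over
the number of taxa tested and a differential flag at adjusted p < 0.01. It
also emits each taxon's median/max-normalized abundance per population
(median within the population divided by the population's maximum; 0 when
never observed) and the cross-population Spearman correlation of median
vectors. Spearman correlations use average ranks for ties; for n ≤ 10 the
p-value is an exact enumeration over all rank pairings, otherwise the
t-approximation.

## Locus genotyping

The positive filter keeps a pair when at least one mate has an ungapped
placement on the gene's reference with at most `low_stringency` mismatches
(default 5 per 100 bp read). Ungapped ≤k-mismatch matching was chosen over
a full mapper for the filter role: it is simple, auditable, and the
quantity the filters actually discriminate on is mismatch count.

The negative filter removes a pair when either mate maps to any homologue
or pseudogene within the same stringency **and at least as well as to the
gene's own reference**. The comparison clause matters: an absolute rule
(remove on any homologue hit) deletes genuine target reads whenever a
homologue locally drifts within the stringency radius, and because the two
haplotypes sit at slightly different distances from the homologue the loss
can be haplotype-specific — silently converting true heterozygous sites
into clean, well-covered, wrong homozygous calls. Requiring the homologue
to explain the read at least as well keeps target-exclusive evidence while
still removing every pair that matches target and homologue equally well.
Pairs harvested by two or more *target* genes are ambiguous between
targets and dropped (counted and reported) — a local rule for a situation
with no canonical treatment.

Retained pairs are placed ungapped at their best offset on the matched
reference (when a gene has several candidate allele references, the allele
with maximum mean placement identity of the retained reads is selected).
Per pileup column, alleles with count/depth ≥ 0.2 are retained; one allele
with depth ≥ 20 gives a homozygous call, two with depth ≥ 10 a heterozygous
call, more than two a `no_call(multi_allelic)` — never a forced diploid
call; columns below their floor are `no_call(low_depth)`. The
allele-fraction floor of 0.2 exists because depth floors alone would let a
single error base at depth 20 fabricate a heterozygote; it is configuration,
as is everything above. Variable-content gene presence is mean post-filter
depth ≥ 5 (the threshold value is a package default, configurable).

Phasing connects two heterozygous sites when at least one pair observes
both with a consistent allele pairing; phase sets are the transitive
closure of such links. Sites whose connecting evidence contains both
pairings are left unphased with a conflict flag. Concordance against truth
compares unordered allele pairs; `non_ref_only` restricts to sites whose
truth genotype is not homozygous-reference, and no-calls are excluded from
both numerator and denominator and counted separately.

## Synthetic data: what it emulates, what it does not

`simulate_genomes` draws i.i.d. genomes at a target GC with a nested
species/genus/phylum taxonomy. `simulate_reads` draws read origins
multinomially with probability ∝ weight × genome length — the cell-
abundance convention, chosen so that genome-length normalization downstream
recovers the input weights; that recovery is exactly the property the
normalization exists for. Errors are uniform substitutions (no indels by
default) since the tier thresholds are identity/coverage-based;
`duplicate_fraction` emits exact copies of already-emitted reads; qualities
default to Q40 with knobs to plant low-quality bases for filter tests.
`inject_positional_substitutions` flips from→to at fixed read positions on
one strand's reads, creating profiles the profiler must recover.

`simulate_paralogous_locus` builds, per gene, a mapping reference and two
haplotypes differing at planted heterozygous sites (the alternate allele
lands on a random haplotype, fixing true phase) plus homozygous-alternate
sites; homologues derive from targets by substitution at the divergence
rate; read pairs are drawn from haplotypes and homologues at the stated
mean depth with Gaussian insert sizes. Variant sites are planted at least
one read length away from the reference edges: fragments are drawn fully
inside the reference, so coverage ramps over the first and last read
length, and edge sites would fail depth floors for reasons unrelated to
the filters under test. Genes listed absent emit zero pairs but remain in
the panel.

Not emulated: pangenome structure and shared gene content between community
members, GC and insert-size biases of real capture chemistry, indel errors
(configurable but off by default), quality-score degradation along the
read, and real HLA/KIR allele nomenclature. Passing tests therefore
demonstrate correctness of the computations and their statistical behavior
under the stated generative model, not performance on real libraries —
e.g., recruitment specificity against genomes with horizontally shared
segments is exercised only through the localization heuristic, not through
realistic homology structure.

## Problem sizes and numerical choices

Default analysis and acceptance runs use 5 genomes of 8–15 kb with 20 000
reads at 1% error for abundance recovery; 10 000 reads for profile
recovery; 20 locus simulations (2 genes + 2 homologues, 800 bp, depth 40,
divergence 0.08–0.12) for genotyping; these sizes give binomial standard
errors comfortably inside the tested tolerances while keeping any single
stage under a few minutes on one CPU. Statistical recovery tests use 3–4
standard-deviation bounds from the exact binomial/multinomial error of the
generator, never tuned tolerances. Abundance tables validate to sum 1
within 1e-9; write/read round trips preserve floats to 6 significant
digits; PAM's SWAP accepts improvements larger than 1e-12 to avoid cycling
on float noise.
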