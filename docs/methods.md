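# Methods

## The audit model

A trio design treats the parents' germline genomes as the null model for
the offspring: any well-supported offspring allele found in neither parent
is a candidate de novo mutation (DNM). In a Cas9-edited animal the DNM set
is the union of (a) spontaneous germline mutations, expected at roughly
1–2 × 10⁻⁸ per nucleotide per generation in primates, and (b) any
nuclease-induced off-target edits. The audit therefore has three legs:
count high-confidence DNMs and compare with the spontaneous expectation,
test whether any DNM lies near a predicted guide-binding site, and bound
the probability that a real (possibly mosaic) DNM was missed at the
achieved sequencing depth.

All pipeline operations are deterministic, pure functions over explicit
record types; every random quantity in the package originates in the
synthetic-data generator and is keyed by a single seed.

## Filtering model

**Site filter (SF).** A biallelic site passes when QD > 2.0 and MQ > 30,
the allele-balance rule does not fire, and the strand-bias rule does not
fire. Allele balance is evaluated on the heterozygous call with the lowest
alt fraction: the rule fires only when AB ≤ 0.10 **and** a two-sided
binomial test of the alt count against 0.5 gives p < 0.05. Reading the
balance bound and the significance requirement as a conjunction is an
interpretation (the pass condition is usually stated as "AB > 0.1, p <
0.05"); `ab_require_pval=False` switches to the bound alone. Strand bias
uses Fisher's exact test on the 2×2 ref/alt × forward/reverse table — the
standard choice where no specific test is named. All comparisons are
strict: a value exactly at a cutoff fails.

**Genotype filter (GF).** A call passes when 15 < DP < 100 and GQ > 30.
Indel-specific DP bounds default to the SNV bounds but are separate config
keys, since depth behaves differently around indels. GF failure (or a
missing genotype) in *any* trio member removes the site from that trio's
analyzable set: a trio DNM call requires all three genotypes.

**Missing ≠ failing.** A record lacking an annotation is tagged
*unevaluable* for that rule rather than failed; this surfaces data problems
instead of silently discarding variants.

**Universal mask.** Mappability, low-complexity and repeat components are
union-merged into one interval set (0-based half-open throughout); a
variant is removed when its REF span intersects the mask.

**Caller consensus.** A variant is high-confidence when every caller
reports a matching (chrom, pos, ref, alt) record. Indels are normalised
first — shared-suffix trimming with leftward extension, then shared-prefix
trimming (the standard left-align/parsimony algorithm) — so the same
deletion written right-aligned by one caller still matches. The matching
key deliberately includes ref/alt, because an off-target audit is
allele-specific.

## DNM cascade

Candidates are genotype-configuration Mendelian violations: the offspring
genotype cannot be assembled by drawing one allele from each parent. This
is a deliberately permissive stand-in for a Bayesian trio caller: the final
call set is defined by the downstream filters, and a permissive front end
lets those filters be audited. The cascade stages:

1. **Caller overlap** (`Raw → noStrict`): intersection of candidate keys
   across callers removes caller-specific false positives.
2. **Allele filtering** (`→ AF`): keep only candidates with at least one
   offspring allele absent from *both* parents. Violations whose alleles
   all exist in the parents (parents A/A and G/G, offspring read as A/A or
   G/G instead of A/G) are genotyping errors, the dominant artifact class
   in real trio data, and are removed here. Multi-allelic offspring
   genotypes survive if either allele is novel.
3. **Known-variant filtering** (`→ dbSNPF`): exact-key (chrom, pos, alt)
   lookup against a public-database snapshot; a true DNM should be novel.
   Position-only matching is available but off by default — novelty is a
   property of the allele, not the position.
4. **Cross filtering** (`→ CF`): candidate keys appearing in ≥ 2 offspring
   of the same parents are removed everywhere; independent recurrence of
   the same DNM is vanishingly unlikely, so sharing indicates a systematic
   artifact. Sharing is exact-key; ±1 bp near-duplicates are out of scope.

Stages only shrink the set, so the funnel |Raw| ≥ |noStrict| ≥ |AF| ≥
|dbSNPF| ≥ |CF| is an invariant the selftest checks.

## Off-target model

A site is any 20-mer, on either strand, whose 3′-adjacent trimer on the
same strand matches an allowed PAM (`NGG` canonical, `NAG` tolerated; `N`
matches any base) and whose ungapped Hamming distance to the protospacer
is within budget (5 for the primary screen, 7 for the extended screen).
Gapped ("bulge") matches and activity scores are out of scope. Sites are
stored as a reference-space 23-bp footprint plus strand; the blunt Cas9
cut sits 3 bp 5′ of the PAM (between protospacer positions 17/18). A DNM
counts as "near" a site when it falls within 40 bp of the footprint — the
window is measured from the footprint, not the cut site, and is
config-exposed since the convention varies.

The scanner is vectorised (per-position mismatch accumulation over a
2-bit-encoded genome); its correctness anchor is a brute-force
string-comparison oracle that the tests run on every genome ≤ 50 kb, plus
exact recovery of simulator-planted sites at 0–7 mismatches. Windows
containing ambiguous bases are skipped and counted.

The **on-target ratio** is the fraction of reads overlapping a ±5 bp
window around the cut site that carry a deletion intersecting that window.
"Near the cut" is not quantified in common usage, so the window is a
parameter; the default of 5 bp captures the blunt-cut repair footprint.

## SV model

Short-read call sets pass when PASS, precise-breakpoint, support > 10
reads and length in [50 bp, 2 Mb]; over-length calls fail with a distinct
tag rather than going to manual review. Long-read call sets require ≥ 10
calling reads and support strictly above 5% of the whole-region depth.
Two short-read callers are intersected by strict 50% reciprocal overlap
(same chrom and type; overlap > half of *both* lengths). Insertions have
no interval extent, so consensus for them uses breakpoint distance ≤ 100 bp
plus a length-ratio bound — an extension beyond pure interval logic,
config-gated. De novo SVs are offspring calls with no reciprocal-overlap
match in either parent, the known-SV database, or any sibling.

## Power model

With depth n, mutant-allele fraction p, and calling threshold
m = ⌈min_af · n⌉, the miss probability is the exact binomial CDF
P(X ≤ m − 1). Stage fractions are single-cell = 0.5 and two-cell = 0.25,
assuming a heterozygous mutation and unbiased read sampling. At n = 40,
min_af = 0.10 (m = 4): the two-cell miss probability is 0.0047 (0.005 at
printed precision) and the power 99.53% — reported as ≥ 99.5%; a sometimes
quoted two-cell figure of 99.8% does not follow from this binomial model
and is not reproduced here. The expected-DNM band multiplies the
spontaneous rate range (0.98–2.17 × 10⁻⁸ per nucleotide per generation) by
the callable diploid site count (default 2 × 2.9 Gb, config-required for
reports); published 22–78 per-generation figures come from trio-sequencing
literature with smaller callable fractions, so the model band is wider —
the two are displayed side by side, not reconciled.

## Synthetic families: what they emulate, and what they do not

The generator produces, per seed: a uniform-random genome (default 1 Mb
over 2 chromosomes — large enough to host hundreds of variants and planted
guide sites with realistic spacing, small enough to run in seconds);
parental heterozygous SNVs at 10⁻³/bp with Mendelian transmission; a
configured number of true DNMs per offspring with allele fractions drawn
from {0.5, 0.25}; artifact classes constructed so each is removable by
exactly one cascade stage (parental-allele and "other" violations → allele
filter; sibling-shared → cross filter; database-known → known-variant
filter; caller-specific false positives → caller overlap); a universal
mask (random "mappability"/"repeat" intervals budgeted to the configured
genome fraction, plus genuine homopolymer runs ≥ 10 bp as low-complexity);
a known-variant database seeded with half the parental variants;
target-window reads carrying an exact count of cut-site deletions; and
inherited / shared / known / de novo SV sets for two callers with small
breakpoint jitter.

Read support is sampled once per variant *per sample* — the pile-up is a
property of the sample, shared by all callers — with AD binomial at the
true allele fraction and fixed 40× depth by default (matching the power
model's working depth; a depth-jitter parameter exists). Offspring calls
at true-DNM sites follow the detection rule: the variant genotype is
emitted only when the alt count reaches ⌈min_af · DP⌉.

Two regimes matter:

- **Error-free (default, `condition_detectable=True`)**: annotation draws
  never violate SF/GF thresholds, strand counts are split exactly evenly,
  and true-DNM alt counts are rejection-sampled to meet both the calling
  rule and the allele-balance pass bound. In this regime the pipeline must
  recover exactly the planted DNMs — precision = recall = 1 is an
  invariant, and any deviation is a bug.
- **Stochastic (`condition_detectable=False`)**: alt counts are raw
  binomial draws, so recall equals the analytic detection power up to
  Monte-Carlo noise. The Monte-Carlo recall experiment disables the
  allele-balance site rule for the measurement, because the power model
  describes read-sampling loss only; leaving AB on would conflate two loss
  mechanisms.

Quantitative artifact rates are not published for real data (only that
> 90% of raw candidates are parental-allele violations), so the simulator's
counts (200 parental-allele, 5 shared, 3 database-known artifacts per
offspring) are package defaults chosen to exercise every stage with
non-trivial numbers, exposed in `SimulationConfig`, and not claims about
any real dataset. The generator does **not** model: read-level sequence
errors or alignment (call sets are synthesised directly), genotype
likelihoods (GQ is a two-point high/low distribution — sufficient to
exercise thresholds), linkage or population structure, mutation spectra,
or real mappability tracks. Passing selftests therefore demonstrate the
*logic* of the pipeline — class-filter correspondence, exact recovery,
funnel monotonicity, oracle agreement — not caller behaviour on real
reads.

## Numerical and interface choices

- Coordinates are 0-based half-open internally; 1-based VCF positions are
  converted at the file boundary. Multi-allelic records are split to
  per-ALT biallelic records (AD collapsed to ref + that alt) before any
  filtering, since every downstream rule is per-allele.
- VCF I/O goes through pysam against a declared minimal dialect (INFO
  QD/MQ/SB, FORMAT GT/DP/GQ/AD); undeclared FORMAT keys are ignored with a
  warning; a caller-dialect tag maps differing INFO key names. SV call
  sets use a BED-like TSV dialect.
- The binomial CDF and Fisher/binomial/Pearson tests come from scipy;
  miss-probability enumeration for n ≤ 20 is re-derived exhaustively in the
  tests as an independent oracle.
- Tie-breaks: consensus annotations come from the first (primary) caller;
  SV consensus keeps set-A coordinates, with existence (not one-to-one
  matching) deciding membership.
- Degenerate inputs: empty PAM windows and ambiguous-base windows are
  skipped and counted; a correlation over < 3 pairs or with zero variance
  raises; region depth ≤ 0, empty read sets over the cut window, and
  n ≤ 0 raise rather than returning sentinel values.

## Problem sizes

Default test and selftest sizes — 1 Mb genomes, hundreds of variants,
500-replicate Monte-Carlo — were chosen so the full suite and the
reproduction script each complete in well under a minute on one core while
keeping binomial confidence intervals tight enough (±0.6 percentage points
at n = 500) to be informative.

## Known limitations

- The Mendelian-violation detector ignores genotype likelihoods; it will
  flag any hard-genotype inconsistency, so its raw counts are higher than
  a likelihood-based trio caller's and only the post-cascade set is
  comparable.
- Exact-key matching throughout (DNM sharing, database lookup) misses
  near-duplicate representations beyond indel normalisation.
- The SV module consumes call sets; it does not discover SVs from
  alignments or genotype them.
- The 40-bp proximity rule and the 5-bp cut-site window are conventions,
  exposed as parameters, not biological constants.
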