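# Methods

## Problem setting

Pooling many low-coverage (2–4×) genomes from heterogeneous sequencing
platforms defeats the usual single-sample variant-calling machinery:
per-sample genotype likelihoods are uninformative at depth 2–3, base
qualities are not comparable across platforms, and read-depth-weighted
pooling lets deep samples dominate. `dynaref` implements the alternative
strategy of entropy-filtered, equally weighted per-sample voting, and
builds a population consensus genome from the result.

## Units and the comentropy filter

The atomic object is the *unit*: one sample's nucleotide-count vector at
one position, restricted to detected A/C/G/T types (deleted-base
placeholders, `N` reads, and indel events contribute to depth but never to
the distribution). A unit enters the analysis only if it holds at least
two nucleotide reads; its comentropy `H = −Σ p log₂ p` (bits) is compared
against an inclusive per-arity ceiling:

| arity | ceiling (bits) | interpretation |
|---|---|---|
| 1 | — (always retained) | unambiguous evidence, H = 0 |
| 2 | 0.95 | excludes minor fractions ≳ 0.37 (e.g. 1:1, 2:2, 2:3) |
| 3 | 1.50 | retains the near-uniform (2,1,1) exactly at the boundary |
| 4 | 1.92 | excludes the uniform and (2,1,1,1) quaternary vectors |

Thresholds are inclusive (`≤`); the boundary vector (2,1,1) evaluates to
exactly 1.5 in binary floating point (all terms are dyadic), so the
equality comparison is exact there. Unary units are not mentioned by the
threshold table; they trivially satisfy any ceiling and are retained —
they are the evidence for high-confidence calls.

A retained unit votes its highest-count nucleotide. Top-count ties inside
a retained unit are rare (the uniform cases fail the filter) but possible,
e.g. (3,3,1) ternary; they resolve to the reference base when it is among
the tied maxima, else alphabetically — deterministic and conservative
toward the reference.

## Candidate extraction

Step one scans the multi-sample position stream and keeps every position
with any non-reference evidence in any sample (one mismatching read or one
indel event suffices). This is deliberately a superset: rare variants
supported by a handful of reads must survive this step, and all stringency
is applied downstream. The candidate set is reported with its reduction
ratio (fraction of positions discarded). Extraction is a streaming single
pass; a chromosome-sharded scan produces the identical key set (asserted
by test), so out-of-core sharding is an implementation detail, not a
semantic one.

Positions whose reference base is `N` pass through extraction but can
never be classified dynamic.

## Population statistics and classification

For a population (a named sample subset; unions are concatenated sample
sets), the *covered* samples at a candidate position are those with a
retained unit. Each covered sample contributes one vote; the major allele
is the vote plurality (ties toward the reference, then alphabetical), its
probability is `votes / n_covered`, and every other voted nucleotide is a
minor allele with frequency `votes / n_covered`. An indel event
(insertion sequence, or deletion length) *supports* a sample when that
covered sample shows at least one such indel read; its population
probability shares the `n_covered` denominator. Per-sample indel zygosity
is unknowable at this coverage, so sample presence is the only equal-weight
statistic available.

A position is dynamic when at least one circumstance holds (categories may
co-occur):

* `MAJOR_DIFF` — major allele ≠ reference base;
* `INDEL_HIGH` — an indel with population probability ≥ 0.50 (inclusive);
* `MINOR_COMMON` — a minor allele > 0.05 (exclusive);
* `RARE` — a minor allele in (0, 0.05] (inclusive at 0.05).

The 5% boundary is assigned to `RARE`, making common and rare minors a
partition of the minor alleles. `MAJOR_DIFF ∪ INDEL_HIGH` positions form
the MAIR — the edit set applied to the reference. All three boundaries
are configurable (`ClassificationConfig`; CLI `--rare-max`, `--minor-min`,
`--indel-high-min`).

Design choices that were genuinely open:

* **Rare-frequency denominator**: covered samples, not the full cohort —
  consistent with every other population statistic here; a position's
  estimate should not depend on samples that contributed no evidence.
* **Diploidy is not modeled**: a sample votes one nucleotide. A
  heterozygote resolves to whichever allele dominates its few reads (and
  abstains on ties, which fail the binary filter). Consequences are
  quantified below.
* **Coverage asymmetry across populations**: a position estimable in one
  population and not another is reported per population; comparisons treat
  it as absent, not zero.

### Bias of the dominant-vote frequency estimator

At Poisson(3) coverage the dominant-vote estimate of a minor-allele
population frequency is biased downward, for two compounding reasons:
(i) a heterozygous carrier votes the minor allele only when it dominates
the sample's reads (probability 0.5 among retained units, by symmetry);
(ii) heterozygous units fail the comentropy filter more often than
homozygous ones (tie vectors such as (1,1) and (2,2) sit at or above the
binary ceiling), so carriers are under-represented among covered samples.
Measured in the simulator by conditioning on genotype (4000 samples,
f = 0.5): retention probability ≈ 0.53 for heterozygous units vs ≈ 0.78
for homozygous ones, minor-vote rate 0.50 among retained heterozygotes.
The net effect: a true 10% allele is estimated at ≈ 5–6% of covered
samples on average, i.e. directly on the rare/common boundary, and
individual sites fluctuate across it (binomial sd ≈ 3 percentage points at
100 samples). Frequency classes near the boundary are therefore reliable
in aggregate but not per site at these depths; fixed differences and
high-frequency indels are unaffected (recovered at ~100% sensitivity with
zero false major-allele calls in the end-to-end tests).

## Consensus construction and liftover

MAIR edits follow the pileup convention: substitutions replace their
1-based anchor base, insertions are placed after the anchor, deletions
remove bases from `pos+1`. Overlapping edits are resolved before
application: higher population probability wins; ties prefer deletion over
insertion over substitution, then the leftmost edit, then stable input
order; every dropped edit is reported with its reason. A substitution
whose payload equals the reference base is rejected and logged.
Substitution + insertion at a shared anchor are compatible (they touch the
base and the following gap respectively) and both apply.

The consensus is a hard major-allele sequence — no ambiguity codes — so
standard aligners accept it. Construction yields a segment-based liftover
map (`ref_start, ref_end, offset` per chromosome): reference positions in
deleted stretches map to nothing, consensus positions inside insertions
have no reference image, and forward-then-backward liftover is the
identity on all surviving positions (property-tested against a naive
string-rewriting oracle on random edit sets).

## Synthetic data generator

The generator emulates the pipeline's design conditions: N diploid
samples, per-position depth ~ Poisson(λ = 3 by default, the middle of the
2–4× regime), uniform per-base miscall rate ε = 0.005 (a typical
short-read substitution-error rate), planted SNVs and indels with
genotypes drawn at Hardy–Weinberg proportions, and per-read haplotype
sampling (each read picks one of the two alleles with equal probability).
Deletion-carrying reads appear as `*` placeholders at deleted positions
and as `-n<seq>` events at the anchor; insertions as `+n<seq>` after the
anchor base, matching `samtools mpileup` output (verified against a
samtools run on a crafted alignment). Everything is a deterministic
function of the seed; identical configurations reproduce identical bytes.

What it does **not** emulate — and hence what passing tests do not show
about real data: mapping bias and alignment artifacts, platform-specific
or context-dependent error profiles, indel sequencing errors, read-length
effects, linkage between neighboring variants (each read re-samples its
haplotype per position), and reference-structure complications
(repeats, CNVs). Diploid Hardy–Weinberg sampling is deliberately included
because it is the worst realistic case for the dominant-vote estimator.

## Numerical and procedural choices

* Entropy is computed in double precision; validation requires probability
  vectors to sum to 1 within 1e-9. Correctness is checked exhaustively
  (all count vectors with total ≤ 12) against a 50-digit `decimal`
  evaluation.
* Probability histograms use half-open bins of width 5% over (0, 1] with
  the final bin closed (numpy convention), so probability-1.0 positions
  land in the top bin; the bin width is configurable.
* Indel-length distributions count only events above 50% population
  probability (strictly), while MAIR membership is inclusive at 50%.
* Interval-catalog hits use 1-based inclusive overlap; an insertion
  touches its anchor base, a deletion its removed bases.
* Codon effect tallies translate reference vs edited codons (stdlib
  genetic code via Biopython); substitutions in transcripts without frame
  information, or in incomplete/ambiguous codons, count as `unknown`;
  indel consequences (frameshifts) are out of scope.
* Test and acceptance problem sizes (50 kb genomes, 100 samples for
  end-to-end recovery; 10 kb chromosomes for consensus-oracle sweeps) were
  chosen as the smallest scales at which the measured properties —
  ≥ 99% fixed-difference sensitivity, boundary-exact classification —
  are statistically meaningful.

## Known limitations

* Minor-allele frequencies near the 5% boundary are not reliably
  classified per site at 2–4× coverage (see the bias analysis above).
* The ≥ 2-read rule applies to nucleotide reads only; indel events do not
  count toward it, so an indel observed in a sample with fewer than two
  point reads contributes no evidence at all.
* Upstream mpileup flags (BAQ, mapping-quality floors) change the input
  base strings and therefore the results; the parser accepts any mpileup
  dialect but cannot normalize for them.
* No genotype calling, phasing, Hardy–Weinberg testing, or imputation is
  performed or intended.
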