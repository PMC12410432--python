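# Methods

## The problem

In species with male heterogamety, loci restricted to the Y chromosome
appear in reduced-representation (RADseq) data as presence/absence
signals: reads in males, none in females. Once such markers are found they
can be placed on a linkage map through a pseudo-testcross trick — the
father carries the marker hemizygously (encode him as heterozygous AT),
the mother lacks it (AA), and each offspring's amplification status is an
ordinary testcross genotype. Finally, aligning mapped marker sequences to
a related species' chromosome-scale assembly identifies which chromosome
the sex-linked group corresponds to. This package implements that chain
and a simulator that generates studies with known ground truth.

## Candidate discovery

A locus is *present* in a sample when its read depth is at least
`min_depth_present` (default 1). Candidates must be present in at least
`male_present_frac` of males **and** absent in at least
`female_absent_frac` of females (both default 0.90, inclusive — "at
least"). The paralog screen aligns each candidate against every other
catalog locus (both strands) and counts loci whose best local alignment
exceeds 80% identity (identities / aligned columns, gaps included) at
query coverage above 25% (aligned query span / query length); both
comparisons are strict. Ranking is lexicographic, in this order: total
residual female reads ascending, paralog count ascending, mean male depth
descending, locus id ascending. No weighting is attempted — the three
criteria are applied in the order given, and the final id key makes the
output deterministic.

## Family-genotype filtering and pseudo-SNP encoding

SNP filters (VCFtools-style): drop indels, sites with more than 5% missing
calls, sites with mean depth below 10 reads (applied only when the VCF
carries depth; a GT-only VCF skips this rule and the report says so), and
sites with minor allele frequency below 0.2 (computed over parents plus
offspring, missing calls excluded from the denominator). Thinning then
keeps one SNP per RAD locus — the first by position, ties by marker id, a
deterministic analogue of spacing-based thinning at one-per-locus
granularity. Presence/absence statuses map to genotypes as present → AT,
absent → AA, ambiguous (faint band, failed control) → missing; the father
is always AT and the mother always AA, so every pseudo-SNP is structurally
a valid paternal-testcross marker.

## Two-point linkage mapping

Only paternal meioses are informative in this design (father heterozygous,
mother homozygous at every usable marker), so a single paternal map is
produced; this mirrors a sex-averaged map in which the maternal side
contributes nothing. For markers i, j with calls on n shared offspring and
D discordant calls, the recombinant count is phase-resolved as
R = min(D, n − D), r̂ = R/n, and

    LOD = R·log10(r̂) + (n − R)·log10(1 − r̂) − n·log10(0.5)

with 0·log10(0) = 0, so perfect linkage gives n·log10 2 and r̂ = 0.5 gives
exactly 0. Pairs sharing fewer than `min_informative` offspring (default
20) are ignored during grouping. Linkage groups are connected components
of the thresholded LOD graph at `lod_group` = 20; leftover singletons are
attached in one pass to the group of their best partner when that LOD
reaches `lod_join` = 15 (ties toward the lower group id). These thresholds
follow the original study design and are not re-derived here.

Ordering within a group is greedy seriation — start from the pair with
minimal r̂, repeatedly append the marker closest to either path end — then
single-marker relocation polishing until the sum of adjacent r̂ stops
decreasing. This replaces multipoint HMM ordering with a transparent
procedure whose adequacy is demonstrated on simulations (order recovery up
to reversal), not by matching any external tool marker-for-marker.
Positions are cumulative Haldane distances d = −50·ln(1 − 2r), matching
the no-interference meiosis model; Kosambi is available behind a flag. An
adjacent r̂ of 0.5 would make the distance infinite; it is capped at
`max_gap_cM` (default 100) with a warning.

### Assay error and co-location

Presence/absence pseudo-SNPs are miscalled at a knowable rate: a carrier
whose marker drops out reads absent, a non-carrier can be contaminated.
Chaining raw r̂ through a block of mutually non-recombining markers turns
that noise into fictitious map length (≈100·ε cM per adjacent pair), so
the mapper accepts per-marker error rates ε. For a pair with rates ε_i,
ε_j, the expected discordance at r = 0 is c = ε_i(1−ε_j) + ε_j(1−ε_i); the
distance estimate uses r = (q̂ − c)/(1 − 2c) clipped to [0, 0.5], and the
pair is co-located (r = 0) when q̂ ≤ c + z·√(c(1−c)/n). The significance
multiplier z defaults to 3 (one-sided three-sigma): with tens of adjacent
pairs examined per group, a per-pair 5% rule would manufacture roughly one
phantom distance per map by construction. With ε = 0 the correction
vanishes and co-location requires identical calls, which is the behaviour
for ordinary SNPs. The end-to-end pipeline derives the pseudo-SNP rate
from its own noise configuration as (dropout + contamination)/2, each
noise source affecting half the offspring under 1:1 Y transmission. LOD
scores and grouping always use the uncorrected r̂. This plays the role the
original pipeline delegated to its ordering tool's genotype-error
parameter (0.02); a full error-integrating HMM is deliberately out of
scope. A per-marker segregation-distortion chi-square report is available
as a diagnostic but does not modify LOD scores.

## Synteny and homology

The aligner seeds on exact `word_size` = 11 matches (hash index of the
reference), merges seed-implied windows, and computes the exact affine-gap
local optimum within each window (match +1, mismatch −2, a length-L gap
costs 5 + 2L); subjects under 10 kb are aligned exactly without seeding.
Both strands are searched; coordinates are reported 1-based on the forward
strand. Significance uses the Karlin–Altschul form E = K·m·n·exp(−λS) with
K = 0.46, λ = 1.28 (defaults appropriate for these match/mismatch scores),
floored at 1e-300 so ratios are always defined; m is the query length and
n the total reference length. Hits require E ≤ 1e-20. The uniqueness
filter keeps, per query, only a best hit at least `magnitude_factor` = 1e5
times more significant than the runner-up (inclusive); equal-E ties fail.
The E-value model is internally consistent rather than calibrated to any
external search tool — downstream decisions depend only on rank order and
the orders-of-magnitude ratio, never on absolute E-values.

Homology: accepted hits vote per linkage group; the majority reference
chromosome is the assignment, and the reciprocal flag requires that this
chromosome's own plurality of hits comes from the same group —
formalising the visual reading of an Oxford plot. Groups without accepted
hits are reported unassigned.

## Sex-ratio statistics

The exact two-tailed binomial p-value uses the minimum-likelihood
definition: the probability of all outcomes whose point mass does not
exceed that of the observed count (relative tolerance 1e-12 on the pmf
comparison guards floating-point near-ties). For p₀ = 0.5 this equals the
doubled smaller tail, capped at 1. Log-space evaluation keeps the test
usable to n ≈ 10⁶. Percentages are rounded half-to-even at the requested
precision. The PCR screening panel ships as a packaged TSV with a closed
status vocabulary (+ male-specific, o both sexes, x no amplification,
. untested — the blanks reflect the staged screening design).

## The simulator

`SimConfig` defaults describe the emulated study: 30 males + 30 females,
a 2-parent × 158-offspring family, 12 chromosomes, 140 bp loci, mean
present-locus depth 20 (Poisson truncated at one read, so presence
guarantees signal), dropout 0.05, female contamination 0.01 (residual
female reads drawn as 1 + Poisson(1)), 20 Y-restricted loci in the
terminal 5 cM of chromosome 8, and 10 paralog pairs at 85% identity.
Dropout and contamination rates are plausible round numbers, not
empirical estimates. Each chromosome carries 60 testcross loci at
uniform-random positions on 50 cM — dense enough (mean gap < 1 cM) that
the largest random gap essentially never severs a chromosome at LOD 20
with 158 offspring, which is the regime the high-threshold grouping
design presumes. Meioses are simulated as a Markov chain along the locus
order with Haldane switch probabilities (no interference). The Y region
is modelled as fully non-recombining: one terminal sex-determining
position decides Y inheritance, and every Y locus follows it, subject to
dropout/contamination. Two SNPs per locus (plus occasional
maternal-informative SNPs and a small set of deliberately filterable
records — indels, distorted low-MAF sites, high-missingness sites)
exercise the filtering stage; maternal SNP transmission is drawn iid
rather than through a maternal map, since the paternal map never uses it.
The reference genome embeds every locus in cM order on its homologous
chromosome (random strand, random spacers, optional mutation knob), with
a permuted chromosome naming so homology recovery is non-trivial.

What the simulator does not model: read-level errors, restriction-site
dynamics, shared repeat families, GC composition, population structure,
genotyping-error modes other than dropout/contamination, and maternal
linkage. Passing recovery tests therefore demonstrates the pipeline's
logic under its own stated noise model, not robustness to every artefact
of real RADseq data.

## Determinism and problem sizes

All randomness flows from a single integer seed through per-stage
`SeedSequence` streams, so identical configurations produce byte-identical
TSV/VCF/FASTA outputs. The test suite and the acceptance script use the
default study size (about 740 mapped markers) for single end-to-end runs,
100 replicates for discovery-stage statistics, and small instances
(≤ 200 markers, ≤ 60 bp sequences, n ≤ 500 trials) where brute-force
oracles — direct pmf summation, dense-grid likelihood maximisation,
hand-rolled connected components, full dynamic-programming alignment —
verify the optimised routes.

## Known limitations

- Two-point distances are noisier than multipoint estimates; total map
  length is mildly inflated by sampling variance in adjacent r̂.
- The error-floor co-location rule can absorb genuine sub-centimorgan
  distances between markers whose declared assay error is large.
- The uniqueness filter discards genuinely multi-copy markers rather than
  resolving them; this matches the conservative intent of the original
  screen.
- E-values are model-internal; do not compare them numerically with other
  search tools.
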