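# Methods

## The model

A recessive disease mutation introduced on a single chromosome g
generations ago is flanked by microsatellite markers at recombination
fractions θ from the disease locus.  A present-day mutant chromosome
carries the founder allele at a marker with probability (1 − θ)^g (plus a
small chance of background identity), so the founder haplotype decays
outward from the locus; an intragenic marker (θ = 0) never recombines away
and is expected to be fully conserved.  Mutation homozygotes make the
mutant-chromosome class directly observable: each such patient carries the
mutation on both chromosomes, so marker allele counts on mutant
chromosomes follow from genotypes without pedigree phasing.

The disease–marker LD statistic is

    delta = (PD − PN) / (1 − PN)

with PD the associated-allele frequency on mutant chromosomes and PN on
normal (control) chromosomes.  delta rescales the excess case frequency by
its maximum possible value, so delta = 1 iff every mutant chromosome
carries the allele beyond background; it is negative when the allele is
rarer in cases, and we report negative values rather than truncating.
Under the single-founder model with background frequency p,
PD = r + (1 − r)p with r = (1 − θ)^g, and delta estimates r itself —
which is why the same statistic drives both the LD tables and the
generations-since-founding estimator ĝ = log delta / log(1 − θ) in the
simulator's recovery routine.

## Statistical choices

- **Associated allele**: the allele maximising delta at a marker, scanned
  over every allele seen in either group.  Ties are resolved by higher PD,
  then smaller allele label; the comparison is done in exact rational
  arithmetic so float rounding cannot flip a tie.  Alleles fixed in
  controls (PN = 1, delta undefined) are skipped.
- **Association tests**: Pearson χ² without continuity correction and a
  two-sided Fisher exact test (point-probability rule) on the 2×2 table of
  (associated allele vs all others) × (mutant vs control chromosomes).
  With a zero margin the χ² is reported missing and the exact p is 1.
- **delta confidence interval**: percentile bootstrap, default B = 10,000,
  resampling chromosomes with replacement within each group (equivalently,
  binomial resampling of the single-allele dichotomy), recomputing delta
  per replicate, and redrawing replicates where the allele fixes among
  resampled controls.  Deterministic given a seed.  Published "±95 CI"
  half-widths from the motivating study are *not* reproduction targets:
  the CI method behind them is cited there but not specified, so this
  package documents its own.
- **Rank tests**: Mann–Whitney U and Wilcoxon signed-rank use the exact
  null distribution when the (non-zero) sample size is at most 12 and data
  are tie-free, otherwise the normal approximation with mid-ranks and tie
  correction.  The threshold 12 is our choice; both regimes are checked
  against enumeration oracles in the test suite.
- **Frequencies**: missing marker calls are excluded from both numerator
  and denominator everywhere.  Compound heterozygotes (one copy of the
  index mutation) are excluded from frequency counting entirely: their
  mutant chromosome cannot be identified without phase.
- **Phase**: homozygote tables that print resolved haplotypes are taken as
  reported (`a|b` in the TSV dialect).  Unphased heterozygous marker pairs
  in mutation homozygotes are retained as unordered allele contributions
  with a per-chromosome ambiguity flag — per-marker counts, hence PD,
  delta and founder support, are unaffected by phase.

## Coordinates and maps

Marker panels declare their unit (physical kb or genetic cM) and are never
converted automatically.  Genetic-map positions may tie (the Marshfield
map assigns 6.60 cM to two of the packaged markers and 10.02 cM to two
more), so the panel invariant is non-decreasing rather than strictly
increasing positions.  Decay profiles and the simulator require a genetic
map (or an explicit distance vector); the Haldane map function
θ = (1 − e^(−2d))/2 (d in Morgans) converts distance to recombination
fraction, chosen over Kosambi for its no-interference simplicity.

## Reconstructed control counts

The motivating study reports control allele *frequencies* only in
supplementary material.  The packaged integer control counts were obtained
by inverting delta = (PD − PN)/(1 − PN) for PN at each published delta
(PD being countable from the printed mutant haplotypes), matching PN to an
integer count over the stated control totals (38 and 34 chromosomes), and
keeping only counts that reproduce the printed delta to three decimals.
Five marker/allele pairs pass this check and ship as fixtures.  One
published value (delta = 0.289 for D17S1798) is reproduced by *no* integer
count over 38 chromosomes (18/38 gives 0.287, 17/38 gives 0.321) and is
therefore excluded.  One published LD table labels the D17S1876
associated allele "9" while the printed mutant haplotypes carry allele 7
modally; the delta value is reproduced with allele 7 at 3/34, so the
numeric value rather than the label is treated as authoritative.

## The simulator

`synth_cohort` generates what the analysis assumes, no more: a founder
haplotype transmitted g generations with per-marker retention
(1 − θ)^g, lost positions redrawn from control allele frequencies, then a
symmetric single-step stepwise mutation with per-lineage probability
1 − (1 − mu)^g (steps below allele label 1 reflect upward).  Cases are
mutation homozygotes formed from two *independent* founder-descended
chromosomes — a consanguinity approximation that matches the inbred-
marriage setting of founder isolates without simulating pedigrees.
Controls draw both chromosomes from the population frequencies.  Defaults
mirror the study conditions: five markers on a cM map around the locus,
4 cases against 19 controls (38 control chromosomes), g = 15 (a few
centuries of human generations — the study gives no generative
parameters, so this is an illustrative, fixed choice), mu = 1e-3 per
meiosis (typical dinucleotide microsatellite rate).

For the phylogeny stage every sample also receives a background variant
matrix: each site has a population alternate-allele frequency drawn from
U(0.02, 0.30) and a site-level linkage θ drawn from U(0, 0.05); the
founder's background haplotype is drawn from the *same* population
frequencies (the founder is a population member), and case chromosomes
inherit it per site with probability (1 − θ_site)^g.  Recent founders
(small g) thus leave a shared rare-variant signature that makes cases
cluster in the neighbor-joining tree; ancient founders dissolve into the
background.

What the simulator does not emulate: pedigree structure and allele-sharing
between relatives, population growth or drift in the control frequencies,
mutation at the disease locus itself, genotyping error, and linkage
*between* markers conditional on the founder (markers are transmitted
independently given the locus).  Tests passing on simulated cohorts
therefore validate the estimators under the stated model, not robustness
to those real-data features.

## Phylogeny

Distances between samples are summed absolute dosage differences over
pairwise-complete sites (`diff_count`), optionally normalised to [0, 1] by
twice the compared-site count; no imputation, and a pair with no shared
called sites is an error.  Tree building is canonical Saitou–Nei
neighbor-joining with the Studier–Keppler Q-criterion, deterministic
lowest-index tie-breaking, and negative branch lengths clamped to zero
with the deficit logged.  On additive matrices the generating tree is
recovered exactly (checked to 1e-9 against hand-built trees and
cross-checked against scikit-bio's implementation, which is never used in
the computation path).  Monophyly of a sample subset is assessed on the
unrooted tree: the subset (or its complement) must form one side of an
edge.

## Numerical and degenerate-input conventions

- delta with PN = 1 raises (undefined) everywhere, including bootstrap
  replicates, which are redrawn.
- Founder-call ties at a marker report every tied allele and flag the
  position ambiguous; the haplotype string shows the smallest tied label.
- The VCF reader uses only biallelic SNV records (others are skipped with
  a logged count) and treats half-calls as missing.
- All randomness flows from `numpy.random.default_rng` seeded once per
  operation; identical seeds give byte-identical simulated cohorts.

## Problem sizes

The heavier validation simulations run at deliberately modest scale:
parameter recovery uses 100 replicates of 200 case chromosomes at g = 20
over five markers with θ between 0.02 and 0.17; decay monotonicity and
founder-clustering checks use 100 replicates of study-sized cohorts with
200 background sites.  These sizes give stable pass/fail behaviour for the
stated acceptance bands while keeping the full suite to a few seconds.

## Known limitations

- Single-founder model only; two-founder mixtures (visible in the Chechen
  cohort's split haplotype groups) are detectable by eye in the decay
  profile but not modelled.
- No multi-point LD or likelihood-based mutation-age estimation; ĝ is a
  per-marker moment estimator with no confidence interval.
- The allele-spectrum cohort fixture pairs the 80 published chromosome
  labels into 40 synthetic genotypes (the publication does not print all
  genotypes); only count-based statistics on it are meaningful.
- Consequence-class annotations are inputs, not computed from sequence.
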