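# Methods

This note records the statistical models the package implements, the
estimator variants chosen where several exist, the numerical conventions,
and what the synthetic-data generators do and do not emulate.

## Input model and reconstruction

All single-locus statistics for a biallelic DIP locus are functions of the
genotype counts (n_DD, n_DI, n_II). The bundled Polish panel
(`indelpop.published`) carries only the printed per-locus summaries —
allele frequencies to four decimals, observed heterozygosity, n = 631 — so
`indelpop.reconstruct` inverts the rounding: the heterozygote count is
`round(Ho·n)`, the insertion copy number `round(p·2n)`, homozygotes follow
by subtraction, and the result is accepted only if the recomputed
frequencies land within 5 × 10⁻⁵ (half a unit in the fourth decimal) of the
printed values. At n = 631 that inversion is exact: rounding a true count
to four decimals perturbs it by less than half a count, so the nearest
integer recovers it, and the test suite confirms agreement with an
exhaustive integer search at every locus and on random summaries.

One printed-table quirk is handled explicitly: the two heterozygosity
columns of the published panel are swapped relative to their legend. The
column labelled "observed" equals `2pq·2n/(2n−1)` (Nei's unbiased expected
heterozygosity) at every locus to rounding, while the column labelled
"expected" contains a value (0.5436) above the biallelic
expected-heterozygosity ceiling at this sample size (≈ 0.5004). Internal
numerical consistency outranks the labels, so the loader maps them
accordingly and verifies the identity at load time
(`published.check_heterozygosity_columns`); loading fails if the check ever
stops holding.

Expanding counts to an individual-level table assigns each locus' genotype
multiset to samples by an independent seeded permutation. Per-locus counts
are preserved exactly; the multi-locus phase is arbitrary, which is valid
for every single-locus statistic and for permutation-based LD testing (whose
null permutes columns anyway) but does not reproduce any true haplotype
structure of the original sample.

## Forensic efficiency parameters

The formulas are listed in the README. Two variant choices matter:

- **PM uses observed genotype proportions**, not HWE-expected ones. The two
  differ little at these loci, but the observed-proportion convention
  reproduces the published PD column exactly at all 30 loci.
- **PE uses the Brenner/Fisher form** h²(1 − 2hH²), a function of observed
  heterozygosity only; it reproduces the published PE column exactly.
- Expected heterozygosity carries the 2n/(2n−1) small-sample factor.

`pm + pd = 1` and `cpd = 1 − cpm` hold exactly (they are computed as
complements, not independently). Missing calls are dropped per locus
(complete-case n per locus), the simplest policy consistent with
near-complete forensic genotyping.

## Hardy–Weinberg testing

Conditional on allele counts, the heterozygote count under HWE follows the
Levene/Haldane distribution; the exact p sums the probabilities of all
admissible heterozygote counts whose probability does not exceed the
observed one (two-sided, probability-mass ordering, Guo–Thompson style).
Monomorphic loci return p = 1 (single admissible outcome). The Monte-Carlo
test re-pairs the pooled 2n allele copies uniformly (vectorized shuffling),
applies the same ordering, and uses the add-one estimator
p = (1 + k)/(n_perm + 1), which never returns zero. Ties in log-probability
are compared with a 10⁻⁹ slack so log-space rounding cannot drop the
observed outcome's own mass. The default 10,000 permutations mirror the
study's setting.

The exact test is slightly conservative at α = 0.05 because the conditional
distribution is discrete; the calibration suite allows ±0.02 around nominal
at n = 631, p = 0.5.

## Linkage disequilibrium

Unphased two-locus data reduce to joint genotype-class counts. The EM
algorithm iterates expected haplotype counts over the double-heterozygote
phase ambiguity (Excoffier–Slatkin); the likelihood is non-decreasing by
construction and asserted at every iteration. Convergence is a
log-likelihood gain below 10⁻⁸ or 1,000 iterations. The product of observed
allele frequencies is always one starting point — this guarantees the EM
optimum dominates the gametic-equilibrium null, so the LR statistic
−2(logL₀ − logL₁) is non-negative — and two additional seeded Dirichlet
restarts guard against local optima in multiallelic (STR) pairs.

The null log-likelihood evaluates the same genotype likelihood at product
haplotype frequencies. Significance comes from permuting one locus'
genotype column across individuals, which preserves both single-locus
genotype distributions exactly; ties count toward the tail, making the test
conservative rather than liberal. For a biallelic pair the test suite
cross-checks EM against an independent one-dimensional profile-likelihood
maximization over the gametic disequilibrium D (allele frequencies are
fixed by the observed marginals regardless of phase, so D is the only free
parameter).

## FST estimation

"Sample-bias-corrected" FST is computed from allele frequencies and sample
sizes alone, assuming random mating within populations, with s populations
and harmonic-mean size ñ:

    Hs~  = 2ñ/(2ñ−1) · (1 − mean_k Σ_i x_ki²)
    Ht~  = 1 − Σ_i x̄_i² + Hs~/(2ñs)
    Dst' = s/(s−1) · (Ht~ − Hs~)
    fst  = Dst' / (Hs~ + Dst')

The s/(s−1) factor corrects for estimating the total diversity from the
sampled populations themselves; without it, a two-population Gst estimates
roughly F/2 rather than F under the Balding–Nichols model, while with it
the estimator is calibrated: the recovery suite demands ±0.03 at
F ∈ {0.02, 0.05, 0.10, 0.20} with 30 loci and 500 individuals per
population (averaged over a few replicates, since a single 30-locus draw at
F = 0.2 has a sampling spread of about ±0.04).

Multilocus FST is the ratio of sums (equivalently, of averages) of Dst' and
Hs~ + Dst' across loci, so loci monomorphic across all populations
contribute zero to both sums and drop out automatically; their per-locus
FST is reported as NaN. Negative estimates are kept in `FstResult` (they
carry information about sampling noise) and clamped to zero only when a
`DistanceMatrix` is built for trees or MDS.

## AMOVA

One-level AMOVA on the allele identity/non-identity distance over the 2n
allele copies: sums of squares decompose into among- and within-population
components with the usual degrees of freedom (s − 1 and 2N − s) and the
weighted coefficient n' for unequal group sizes; Phi_ST =
σ²_among/(σ²_among + σ²_within). The permutation null reassigns whole
individuals (both allele copies together) to groups. For unlinked biallelic
loci this is equivalent to FST-based AMOVA on allele-frequency data, and on
two-population Balding–Nichols data the multilocus Phi_ST (summed variance
components) agrees with the pairwise FST estimator within 0.02.

## Trees and ordination

Neighbor joining follows the canonical Q-criterion algorithm. Ties in Q are
broken by the lowest (i, j) pair in current label order, making the output
deterministic. Negative branch lengths — routine with FST distance
matrices — are clamped to zero with the deficit transferred to the sister
branch, preserving leaf-to-leaf path lengths. NJ therefore recovers any
additive matrix exactly (property-tested on random trees of 4–12 taxa).
Newick serialization orders children by smallest descendant leaf label and
writes six-decimal branch lengths; parsing goes through dendropy, with a
degree-2 root suppressed so round trips preserve the unrooted topology.
Trees are left unrooted: rooting and ladderization are presentation
choices, not data.

SMACOF minimizes stress by iterated Guttman transforms with uniform
weights. The initial configuration is classical scaling (Torgerson), which
is deterministic — no random restarts, so results are reproducible without
seeds. Iteration stops when the stress-1 decrease falls below 10⁻⁸ (default)
or at 10,000 iterations; monotone non-increase of stress is asserted at
every step. Reported stress is normalized stress-1,
sqrt(Σ(δ−d)²/Σδ²) over distinct pairs. An all-zero matrix maps to all
points at the origin with zero stress.

## Synthetic data

The generators emulate the statistical structure the analysis assumes, at
the study's stated conditions: the default panel is 30 biallelic loci at
the published Polish allele frequencies, 631 individuals, three regional
labels (the regional split is not published, so individuals are divided as
evenly as possible — 211/210/210). Three models are provided:

- **HWE**: two allele copies drawn independently per individual — exactly
  Hardy–Weinberg proportions, for any number of alleles.
- **Inbreeding**: the second copy duplicates the first with probability
  FIS, giving genotype probabilities p² + FIS·pq, 2pq(1 − FIS),
  q² + FIS·pq — the alternative used to verify HWE-test power.
- **Balding–Nichols**: per-population frequencies drawn from a Dirichlet
  with parameters pᵢ(1 − F)/F (the beta model when biallelic), genotypes
  then drawn under within-population HWE — ground truth for FST recovery.

A single master seed derives per-locus and per-population streams through
`numpy.random.SeedSequence.spawn`, so outputs are bit-reproducible and
independent of evaluation order.

What the generators do **not** emulate: genotyping error and allelic
dropout, missing-data patterns, relatedness between sampled individuals,
physical linkage (all loci are simulated independent), and real geographic
substructure. Passing calibration tests therefore demonstrates that the
estimators are correct under their stated assumptions, not that real
forensic datasets satisfy those assumptions.

## Problem sizes in the calibration suite

The stochastic acceptance checks run at the study's scale where that is
cheap (HWE type-I on 1,000 loci at n = 631; LD type-I on 200 pairs at
n = 631 with 199 permutations each; FST recovery at 30 loci × 500/pop,
eight replicates per target) and at reduced but statistically adequate
sizes elsewhere (AMOVA calibration uses 200 replicates of three groups of
60 with 99 permutations; permutation counts in examples and CLI defaults
remain 10,000). Tolerances are three-standard-error binomial bands around
the nominal rates, stated per test.

## Known limitations

- The HWE permutation p-values of the original tool chain are not
  reproducible bit-for-bit (its exact test flavour and seeds are unknown);
  they are treated as stochastic reference points, and this package's exact
  test is the anchor instead.
- Pairwise FST against the 19 external reference populations requires their
  published frequency tables, which are not bundled; the machinery
  (frequency-table reader → FST matrix → NJ/MDS) is fully in place.
- Kinship indexes beyond TPI, θ-corrected match probabilities, hierarchical
  (multi-level) AMOVA and Weir–Cockerham θ are out of scope.
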