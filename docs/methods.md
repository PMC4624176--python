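# Methods

## Study system and scope

The package models a two-pronged dissection of a quantitative behavioral
trait in *Drosophila*: (i) a reference-panel screen over ~200 inbred,
sequenced lines phenotyped for alcohol-induced elution time, analyzed by
variance partitioning and single-variant association on line means; and
(ii) extreme-QTL mapping in an advanced intercross population (AIP) bred
from six of those lines, phenotyped at scale, with pooled sequencing of the
phenotypic extremes. Downstream layers integrate the two mapping arms:
candidate genes recurring across analyses, interaction subnetworks, and
qPCR expression contrasts between the founder pools. The pipeline starts
from allele-count tables; read alignment, duplicate marking and base-quality
recalibration are upstream concerns outside its scope, as are
genomic-relatedness mixed models for the panel association (a generic
covariate matrix stands in for infection/inversion adjustment).

## Forward simulator

**Founders.** `make_founder_panel` draws biallelic SNPs with strictly
increasing positions on each chromosome arm (defaults: the five major
*D. melanogaster* arms with standard physical and map lengths). Lines are
fully homozygous; a configurable fraction of sites is private to a single
line — in a six-founder AIP such alleles segregate at frequency 1/6 ≈ 0.167,
which is the design's route to testing variants too rare for a MAF > 0.05
panel screen.

**Base population.** `diallel_base_population` performs a partial diallel:
every unordered pair of distinct founders contributes equally many F1s (15
pairs for six lines), so founder haplotype shares are exactly 1/n. Within-
line crosses and reciprocals are excluded; sizes not divisible by the pair
count are rejected rather than silently rounded.

**Random mating.** Each offspring draws two distinct parents uniformly
(selfing excluded; random union of gametes, not monogamous pairs). Gametes
recombine with a Poisson crossover count on the map length in Morgans,
uniform crossover positions, no interference. Recombination is restricted
to female meiosis by default because *Drosophila* males are achiasmatic;
the flag `female_recombination_only=False` turns this off. The effective
recombination rate is therefore half the map rate, which the test suite
checks via junction counts. Haplotypes are founder mosaics (segment lists
in cM); dosage queries binary-search segment boundaries. The census is 300
by default — the nominal population size is treated as census size, with
the census/effective distinction noted but not modeled — and the final
generation can be expanded to breed the cohort that will be phenotyped.

**Phenotypes.** Elution time = grand mean + Σ(dosage × additive effect) +
sex effect + tolerance shift (E2 only) + Gaussian residual, then
discretized to the **upper edge** of its 1-minute bin (flies are collected
at fixed intervals; a fly eluting at 5.4 min is recorded at minute 6) and
floored at one bin. `residual_sd = 0` is allowed so the noise-free limit is
exactly representable. For the panel screen, `simulate_dgrp_fly_data` draws
the balanced mixed model `Y = μ + L + F + L×F + Rep(L×F) + ε` directly with
Gaussian components — defaults match the screen design of 2 replicate runs
× 70 flies per sex per line.

**Pooled sequencing.** Per pool and site: true frequency from the selected
diploids' alleles, depth ~ Poisson(mean depth), alt reads ~ Binomial(depth,
frequency). Sites monomorphic among founders are excluded. The generator
does not emulate mapping error, indels, base-quality artifacts or reference
bias — passing tests show the statistics behave correctly under the
sampling model, not that upstream bioinformatics is error-free.

## Estimators and tests

**Variance components.** Balanced nested-factorial ANOVA with
method-of-moments solutions from the expected mean squares (f = flies/run,
r = runs/cell, s = factor levels): σ²_ε = MS_within; σ²_Rep = (MS_Rep −
MS_within)/f; σ²_L×F = (MS_L×F − MS_Rep)/(rf); σ²_L = (MS_L − MS_L×F)/(srf).
Negative estimates are truncated to zero only after all components are
solved, keeping H² ∈ [0, 1]. σ²_P excludes the replicate component by
default, matching the definition σ²_P = σ²_G + σ²_ε; `include_rep_in_P`
widens it. Unbalanced tables are rejected; a seeded subsampler
(`rebalance`) restores balance rather than approximating the EMS. REML and
Satterthwaite df are deliberately out of scope. F-tests use the mixed-model
denominators (L and F against L×F, L×F against Rep, Rep against within).
The estimator is cross-checked in tests against an independent hand-EMS
oracle and against `statsmodels` OLS sums of squares.

**Mutant ANOVA.** The fixed-effect factorial G × S × E with replicate
nested in cells uses `statsmodels` for sums of squares; whole-plot F-tests
are re-formed against the replicate mean square. Effects are reported per
sex/exposure as mutant − control with the pooled SEM √(SEm² + SEc²).

**Z test.** The null variance is `p₀(1 − p₀)(2/n + 1/d_S + 1/d_R)`: the
`2/n` term is the binomial variance of sampling individuals into the two
pools and each pool's sequencing depth contributes an independent
read-sampling variance. p-values are two-sided (sidedness is not
dictated by the design; two-sided is conservative) and floored at the
smallest positive double. Sites with p₀ ∈ {0, 1} are flagged degenerate and
reported with Z = 0, p = 1. `n` defaults to 2 × pool size; a per-chromosome
mapping accommodates hemizygous X in male pools (1 × pool size). Type-I
calibration, power monotonicity in effect/depth/pool size, and the
infinite-depth limit (two-proportion z-test) are part of the test suite.

**Extreme selection.** Lowest/highest `fraction` of elution times per pool.
Because times are binned, boundary ties are broken by a seeded uniform draw
so pool sizes are exact; with all flies tied the pools are seeded random
subsets.

**Association.** Covariates (plus intercept) are residualized out of line
means first; each site with MAF strictly > 0.05 and ≥ 3 lines per allele
class is then tested by regression on dosage, identical on homozygous lines
to the equal-variance two-class t-test (asserted as an internal
cross-check). df = n − 2; the covariate projection's df cost is ignored,
acceptable at panel sizes and documented here rather than hidden.

**Candidate overlap.** Variants map to every gene whose body ± window
(default 1 kb) contains them, via interval trees validated against a
brute-force all-pairs oracle. The permutation null redraws each analysis's
gene set uniformly without replacement, size-preserved, from the testable
universe — conditioning on set sizes is the minimal sufficient structure;
permuting at the variant level before gene mapping is a possible
alternative not taken as default since gene-level sets are what the
statistic consumes. The add-one estimator p = (1 + #{perm ≥ obs})/(B + 1)
never returns zero; with B = 1000 the floor is 1/1001 ≈ 0.001.

**Networks.** The one-linker rule admits a non-candidate only when adjacent
to ≥ 2 distinct candidates, and carries only its candidate edges; a linker
touching a single candidate bridges nothing and is excluded. A linker
shared by many candidate pairs is counted once (node-level inclusion).
Genetic and physical graphs are processed independently. Extraction is
idempotent and equals exhaustive length-≤2 path enumeration (property
tests).

**Expression.** Technical replicates are averaged before any statistic; the
biological replicate is the unit. Student's equal-variance t is the default
(Welch behind a flag). The altered-proportion comparison uses a one-sided
Fisher exact test, the claim being directional. Note: for the 2×2 table
[[15, 5], [3, 15]] the exact one-sided p is ≈ 4.7 × 10⁻⁴; the implementation
reports the exact hypergeometric value for whatever table it is given.

## Reproducibility and numerics

All randomness flows through `numpy.random.default_rng` from explicit
integer seeds; pipeline stages derive independent substreams from a master
seed by hashing the stage name, and the acceptance script spawns seeds via
`SeedSequence`. Identical configs produce byte-identical outputs (asserted
in tests, recorded as SHA-256 digests in the run manifest). Coordinates are
half-open 0-based internally with conversions exactly once at the BED/GFF3
and VCF boundaries.

## Problem sizes

Simulation-based checks run at reduced but statistically adequate scale,
chosen as the package's own test design: heritability calibration uses 200
replicates of the full 205 × 2 × 2 × 70 design (the array-based estimator
makes this cheap); drift and localization checks use one chromosome arm,
censuses of 120–400 and 7–9 end-to-end replicates; null calibrations use
40,000–60,000 sites. The acceptance script reports the problem size next to
every value it computes.

## Known limitations

Linear physical↔genetic map (no recombination-rate heterogeneity or
centromere suppression); no crossover interference; no migration, selection
during AIP maintenance, or unequal sex ratios; association layer omits
relatedness corrections; candidate-gene tallies tied to a specific genome
annotation release and genotype panel are not reproducible without those
exact inputs and are out of scope by design.
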