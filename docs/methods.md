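# Methods

This note records the models behind `riverrescue`, the defaults and why
they were chosen, the numerical decisions, and what the synthetic data
do and do not establish about real data.

## The riverscape generator

The simulator emulates a small, isolated riverine population monitored
along a 1-D river coordinate (km upstream of the most-downstream site)
and augmented by translocations from a larger, more diverse source
population.

**Breeding.** Spawning happens once a year, nominally on 15 November;
the cohort year is the calendar year of spawning, so larvae sampled in
December belong to that year's cohort and juveniles sampled in
February–March to the previous year's.  Breeders are drawn each year
from all alive mature fish (age ≥ α = 3 y, ≤ AL = 23 y), so individuals
can breed repeatedly across years (iteroparity, overlapping
generations).  The per-year breeder count is either given explicitly or
derived linearly from the yearly mean discharge (default 20 + 0.2 ×
ML/day, giving ~64 breeders in the wettest year and ~30 in the driest —
low-flow years recruit fewer breeders).  In the default *family* mating
mode, breeders form monogamous base pairs covering every selected
breeder plus ~30% extra re-pairings (polygamy, hence half-sib
structure), and each pairing produces a full-sib family whose size is
negative-binomial (dispersion 1.2) truncated to ≥ 2, mean ≈ 5.3 — the
range and mean observed in sibship reconstructions of such populations
(2–32 members).  A *random-union* mode instead draws every offspring's
parents independently from the selected breeders; this is the idealized
condition under which the effective number of breeders equals the census
breeder count, used for estimator-validation cohorts.

**Founder genetics.** SNP panels from reduced-representation sequencing
are ascertained polymorphic, so ancestral allele frequencies are drawn
from Beta(0.3, 7.6) truncated to [0.02, 0.98] (ancestral expected
heterozygosity ≈ 0.152).  The source population carries mild
Balding–Nichols drift from this ancestor (F_s = 0.05 — it is itself a
century-old impoundment population), giving source PHt ≈ 0.144; the
target's configured inbreeding F = 0.382 is applied *relative to the
source*, giving target PHt ≈ 0.089 and the study's observed deficit
1 − 0.089/0.144.  Because both populations are drifted from a common
ancestor, F1 crosses recover ancestral heterozygosity and exceed both
parental means — the hallmark of effective genetic rescue.  Note that
downstream QC (dropping loci monomorphic in the combined observed
sample) re-ascertains the panel and shifts both group means up a little
while approximately preserving their ratio; the stated means hold for
the raw generator output.

**Gene drop.** Founders are Hardy–Weinberg draws from their population's
frequencies (optionally with extra individual autozygosity for an
upstream inbreeding gradient); every offspring allele is an independent
fair draw of one of the corresponding parent's two alleles.  Missing
calls are injected uniformly (default 2%).

**Growth.** Length at age follows the Gompertz curve
L(t) = L∞·exp(−exp(−k(t−t₀))) with L∞ = 350 mm, k = 0.35 y⁻¹,
t₀ = 1.4 y and Gaussian noise of 8 mm — chosen so young-of-year are
~80 mm, 1–2 y juveniles ~120–170 mm and old adults ~330 mm, matching the
species' reported length ranges, with residual spread matching the
reported per-cohort residual SDs (~7–8 mm).  In stress years (default:
the lowest-flow year) each fish's expected length is shifted by
`inbreeding_growth_slope` × (PHt − cohort mean PHt).  The default slope,
340 mm per unit PHt, encodes a designed standardized effect of ≈ 0.27
residual SDs per SD of PHt — a moderate heterozygosity–fitness
correlation with planned power ≈ 0.95 at n ≈ 170 and α = 0.05.  (The
within-cohort PHt spread at a 2000-locus panel is ≈ 0.0066 and is
dominated by finite-panel measurement noise, which is why the slope
looks large in raw units.)

**Dispersal.** A fish's capture site is its natal site displaced by
Normal(−b·age, s·√age) km and snapped to the nearest survey site, with
downstream drift b = 0.8 km/year and kernel scale
s = 0.5 + 0.008 × (ML/day at birth) km — displacement accumulates with
time at large, and high-flow cohorts spread further.  This reproduces
the two qualitative field observations the model is meant to carry:
later-sampled siblings tend to lie downstream of earlier-sampled ones
(downstream-dominated direction calls), and family spread increases with
birth-year flow.

**Observations.** Cohort fish are sampled once (10% as December larvae,
the rest in February–March surveys with a 60/30/10% split across their
first three survey windows); ~1.5% are recaptured and re-genotyped in a
later year.  Translocated fish are measured and genotyped at release.
Daily discharge is lognormal (σ = 0.4) around the configured yearly
means.

**What the generator does not emulate.** No egg/larval survival model,
no barrier hydraulics, no temperature effects; flow acts only through
breeder counts, the stress-year flag and the dispersal kernel.  Sexes
are simulated but never exported (the field study had no sexing data).
True individual inbreeding varies only through pedigree and panel
sampling, not through a continuous autozygosity distribution, so
heterozygosity–fitness correlations in real data (where pedigree depth
and linked variation add variance) may be stronger or weaker than the
planted ones.  Passing recovery tests therefore demonstrates estimator
correctness under the stated generative model, not field performance.

## Estimators

**QC.** Filters run in a fixed order (individuals by missingness → locus
reproducibility → locus missingness → monomorphism → one SNP per tag) so
reports are reproducible; monomorphism is re-checked whenever a subset
is taken.  The excess-heterozygosity screen is a one-sided exact
binomial test of the heterozygote count against 0.5 per locus
(α = 0.05): a single biallelic locus cannot exceed expected
heterozygosity 0.5, so a significant excess marks incorrectly merged
loci.  A stricter profile (individuals > 20% missing, reproducibility
< 0.99, best-per-tag) is provided for parentage work.

**PCoA and ancestry.** Ordination is PCoA of standardized,
mean-imputed genotypes under squared-Euclidean distance (scikit-bio's
eigendecomposition).  Ancestry calls are PC1-interval based: reference
cluster centres and SDs come from known target/source fish, and an
unlabeled fish is *admixed* iff its PC1 lies between the centres and
more than 3 cluster SDs from both; the data-specific cutoffs of any one
study generalize this way.  Classification is refused when the reference
clusters overlap on PC1.

**AMOVA.** One-level variance decomposition on squared-Euclidean
genotype distances (σ²_among from the standard mean-square identity with
the unequal-group-size coefficient n₀), with a permutation p-value using
the (hits+1)/(n_perm+1) estimator.  Negative variance components are
clamped to zero before converting to percentages.

**Relatedness.** The estimator centres genotypes at 2p̂ and uses
ratio-of-sums weighting, r̂ = Σ(x−2p̂)(y−2p̂) / Σ2p̂q̂ over
pairwise-complete loci — an allele-frequency-weighted product-moment
(Queller–Goodnight family) estimator with expectation equal to the
relationship coefficient (0.5 full sibs, 0.25 half sibs, ~1 self).
Ratio-of-sums rather than per-locus standardization matters on
ascertained rare-skewed panels, where 1/(2pq) weights would let rare
loci dominate the variance.  Frequencies default to the sample estimate;
for small or family-dominated panels a reference frequency vector should
be supplied (the sample estimate is confounded by the very structure
being measured).

**Full-sib clustering.** Families are connected components of the
r̂ ≥ 0.35 graph (threshold midway between the half-sib and full-sib
expectations; the ≥ comparison is closed, so a pair exactly at the
threshold is an edge), refined by average-linkage re-clustering within
each component cut at the same threshold — one borderline half-sib edge
must not chain two families whose *average* cross-relatedness is
sub-threshold.  Five seeded replicate runs jitter the threshold by
±0.03 and assignments are kept when found in at least three replicates
(replicates perturb the threshold only; the operation receives a
relatedness matrix, not genotypes, so locus subsampling is not
available at this stage).  Components mixing cohorts more than one year
apart are flagged rather than split: they may be other relationships,
or the same pair breeding in multiple years.

**Parentage.** Exclusion-based: a candidate is accepted when its
opposing-homozygote count with the offspring does not exceed the
0.999-quantile of Binomial(n_comparable, dropout + other error), with
the default error model (dropout 0.01, other 0.001); among accepted
candidates the smallest count wins, and an unsampled parent is reported
when no candidate passes.  This replaces full-likelihood pedigree
reconstruction; its fidelity is demonstrated by truth recovery on
simulations rather than by replicating an external program's output.

**LD method.** The composite-LD r̂² between two loci is the squared
Pearson correlation of {0,1,2} genotype vectors over pairwise-complete
individuals, scaled by the Burrows small-sample factor (n/(n−1))² and
capped at 1.  This convention matters: without the factor the estimator's
null expectation is 1/(S−1) rather than the calibration value
1/S + 3.19/S², and breeder estimates run ~20% high (verified by
simulation; with the factor the simulated null mean matches the
calibration within 0.1%).  Pairs are weighted by their
pairwise-complete count, S is the harmonic mean of those counts, loci
with minor allele frequency below P_crit = 0.01 are excluded as whole
loci, and N̂b is the standard quadratic inversion of
r̂²′ = r̂² − E[r²|S] (the S ≥ 30 and S < 30 branches), with r̂²′ ≤ 0
mapping to an infinite estimate.  Confidence intervals come from a
delete-one-individual jackknife on r̂²′ (rank-one downdates of the pair
sufficient statistics; normal-theory interval mapped through the
monotone inversion).  Validation cohorts are produced by
`simulate_ld_reference_cohort`: five discrete random-union generations
at the target breeder count *before* the sampled cohort, because
unlinked-locus drift LD equilibrates at 4/3 of its per-generation input
— a cohort bred from fresh unrelated founders carries only ~3/4 of
equilibrium LD and reads ~35% too high.  Those cohorts use a uniform
common-allele spectrum (0.05–0.95), the domain the small-sample
calibrations were built on; on the riverscape's rare-skewed ascertained
spectrum with P_crit = 0.01 the method shows the upward bias that is
expected when rare alleles are admitted, and with family-structured
mating the estimate falls below the census breeder count because
overdispersed family sizes reduce the *effective* number of breeders —
both visible in `analysis/05_effective_breeders.py`.

**Sibship-frequency method.** Q̂ is the fraction of the C(n,2) offspring
dyads sharing at least one parent (full-sib dyads plus
shared-single-parent dyads).  Under equal sex ratio and random mating
P(share ≥ 1 parent) = 1 − (1 − 2/N_b)², which inverts to
N̂b = 2(1+√(1−Q̂))/Q̂; Q̂ = 0 gives infinity, Q̂ = 1 gives exactly 2.
This is a moment analogue of the likelihood-based sibship-assignment
method, validated against truth pedigrees.  The CI is a percentile
bootstrap over offspring; pairs formed by two resample copies of one
individual are artifacts and are excluded from numerator and
denominator alike.

**Life-history adjustment.** Cohort-based estimates from iteroparous,
age-structured populations are adjusted with
N_b(adj) = N̂b/(1.03 − 0.245·log₁₀(AL/α)) and
N_e(adj) = N_b(adj)/(0.485 + 0.758·log₁₀(AL/α)); both logs are base 10,
fixed by reproducing the published constants 0.8133 and 1.156 at
AL = 23 y, α = 3 y.  Infinite estimates propagate as infinite; CI
endpoints transform with the point estimate; rounding to integers
happens only in the presentation helper.

**Growth and inbreeding depression.** The Gompertz fit is nonlinear
least squares with multistart (L∞ from the sample maximum scaled by
1.05/1.2/1.5; k and t₀ from a log-linearized pass plus a coarse grid),
bounded positive, reporting the best SSE if no start converges.  Ages
are (capture date − 15 November of birth year)/365.25.  Cohort
assignment uses explicit length cuts per capture window, or an "auto"
mode that finds modes with ≥ 5% prominence on a kernel-smoothed length
density and cuts at the minima between consecutive modes; lengths within
a configurable band of a cut are labelled *uncertain*, never guessed,
and recaptured fish are checked for a consistent birth year (the rate is
reported).  The regression suite is a one-way cohort ANOVA with Tukey
HSD contrasts, pooled and per-cohort OLS of residuals on PHt (cohorts
with n < 10 excluded with a warning), and a random-intercept (birth
year) mixed model fitted by REML, with an ML likelihood-ratio comparison
against pooled OLS whose p-value uses the halved chi-square tail
appropriate to a variance component on the boundary.  A PHt × cohort
interaction model is available but not the default — per-cohort fits are
the reported route.

**Dispersal.** Distances are along the river centreline, never
Euclidean.  Direction requires ≥ 5 members (overridable): each
later-vs-earlier sibling pair votes by the sign of its river
displacement; unanimous votes give downstream/upstream, mixed or
undecidable cases are *unclear*, single-site families are *none*, and
larvae found away from their siblings vote downstream (downstream-only
movement is presumed for larvae).  The flow model is OLS of per-family
maximum sibling distance on mean daily discharge averaged over the birth
calendar year and on family size (larger families catch rare
long-distance moves); a constant flow covariate is refused.

**Rescue calculus.** F = 1 − PHt_target/PHt_source against an
assumed-outbred source (a nonzero source inbreeding rescales the
benchmark but is off by default); f = 1 − √(F_target/F) so that
F_target = F(1−f)²; N_m = f·N_b/(1−f); census migrants divide the
*rounded* effective number by N_e/N (default 0.17), matching the
convention that published chains apply the ratio to the reported
integer.  The default breeder base is the arithmetic mean of per-cohort
adjusted LD estimates, with the sibship-based mean as the alternative
profile.  The end-to-end check breeds the prescribed effective migrants
with the local breeder base for one generation
(`simulate_rescue_generation`) and recomputes F from the offspring/source
PHt ratio; with drifted-frequency founders the algebra closes:
E[F'] = (1−f)²F up to O(1/N) parent-pool sampling terms.

## Problem sizes

The test suite and acceptance script validate at sizes chosen to make
Monte-Carlo error small relative to the tolerances while keeping runs
desk-scale: 2000-locus panels, 50-breeder/60-offspring LD cohorts
(20 replicates in the tests, 10 in the acceptance script), 66-family
kin reconstructions, ~170 fish per cohort for the inbreeding-depression
power checks (20 planted replicates, 200 null-cohort tests), ~66-family
dispersal models (20 planted, 200 null replicates), and 20 replicates of
the one-generation rescue validation.

## Known limitations

* The LD and sibship estimators assume closed cohorts; admixed fish are
  excluded upstream rather than modelled.
* Exclusion parentage needs informative panels (hundreds of loci); at
  ~200 loci family clustering degrades and reports lower support rather
  than failing.
* The sibship N̂b inversion assumes equal sex ratios and random mating;
  strongly skewed mating systems bias it in the direction of the skew.
* The auto cohort-break detector is operator-reviewable output, not a
  validated ageing method; explicit breaks are the reproducible path.
* AMOVA is one-level only; hierarchical designs are out of scope.
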