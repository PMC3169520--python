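# Methods

`ailqtl` implements single-locus interval mapping for an advanced intercross
line (AIL) between two fully inbred strains, with explicit modeling of
parent-of-origin effects and genotype-by-context (sex, diet) interaction.
This note records the models, the numerical choices, and what the bundled
simulator does and does not emulate.

## The genotype model

Ordered genotypes carry the parent of origin: the paternal allele is written
first, so LS and SL are distinct heterozygotes. At an observed marker the
three genotypic scores are

| genotype | X_a | X_d | X_i |
|----------|-----|-----|-----|
| LL       | +1  | 0   | 0   |
| LS       | 0   | 1   | +1  |
| SL       | 0   | 1   | −1  |
| SS       | −1  | 0   | 0   |

so the regression coefficients on (X_a, X_d, X_i) are the additive effect
a = (G_LL − G_SS)/2, the dominance deviation
d = (G_LS + G_SL)/2 − (G_LL + G_SS)/2, and the imprinting effect
i = (G_LS − G_SL)/2, where G_g is the genotypic mean.

Between markers, expected scores are imputed on a pseudomarker grid
(default 1 cM) by flanking-marker regression. Because the paternal and
maternal transmissions are independent, it suffices to compute
p = P(paternal allele = L | paternal flanking alleles) and the analogous q
for the maternal haplotype, each by the two-point conditional

    P(L | h_left, h_right) = f·g / (f·g + (1−f)(1−g)),

with f = 1−r₁ or r₁ depending on the left flank allele (g likewise), and
r from the Haldane map function r = (1 − e^(−2d/100))/2. Then

    X_a = p + q − 1,  X_i = p − q,  X_d = p(1−q) + (1−p)q,

which satisfy X_d = (1 + X_i² − X_a²)/2 identically. Design choices:
conditioning is on the two flanking markers only (the classical
interval-mapping conditional; with maps this dense, multipoint conditioning
changes expectations negligibly), the Haldane function is used for
consistency with the simulator's no-interference crossover process, and
positions beyond a terminal marker condition on the single nearest flank.
Missing genotypes are not imputed; the simulator emits complete data, and
real-data missingness should be handled upstream.

## The scan model

At every grid position, for every trait, two Gaussian models are fitted by
maximum likelihood and compared:

* full: Y = µ + s + t + s·t + (X_a, X_d, X_i) × (1, s, t, s·t) + u + e —
  4 context terms plus 12 genetic terms;
* null: Y = µ + s + t + s·t + u + e,

where s and t are sex and diet in ±½ effect coding (M and HF positive), so
each genetic main effect is the average over the four cohorts and each
interaction coefficient is a cohort contrast; the (a, d, i) triplet of any
cohort is a four-term linear combination of coefficients, with standard
errors from the coefficient covariance. The random part u has four
mutually independent variance components — family, family×sex, family×diet,
family×sex×diet — plus residual; no cross-covariances (the simplest
structure consistent with family-clustered AIL data, where full-sib families
are the unit of relatedness). Variance components are re-estimated under
both models, and full ML (not REML) is used because the likelihood-ratio
test contrasts fixed effects.

The LRT statistic is referred to chi-square with 12 degrees of freedom and
reported as LOD = −log₁₀(Pr). Numerical choices:

* the covariance is block diagonal by family, so both β and the residual
  variance are profiled analytically and the likelihood is optimized
  (L-BFGS-B, non-negative bounds) over only the four variance ratios;
  families of equal size are batched, which is what makes scans with
  thousands of refits practical. The fitter is validated against
  statsmodels MixedLM (full ML) in the test suite;
* each position's full fit warm-starts at the trait's null-fit variance
  ratios, which structurally guarantees a non-negative LRT; residual tiny
  negatives are clamped to 0;
* the statistic carries a Bartlett-type small-sample rescaling
  (n − p_full)/n. Profiled-ML likelihood ratios over p fixed effects run
  hot by a multiplicative O(p/n) factor; at n ≈ 300 this measured ~3–5%,
  which compounds to ~1.6× the nominal tail probability at the extreme
  quantiles a genome scan thresholds on. The rescaling restores the 12-df
  calibration (verified by simulation: ~0.95 significant chromosomes per
  null trait over 19 autosomes) and changes the statistic by <2% at the
  ~1,000-animal scale the design targets. `small_sample_correction=False`
  recovers the raw LRT;
* p-values below floating-point underflow are computed from the chi-square
  log-survival function, with an asymptotic tail expansion when even that
  underflows, so LOD stays finite;
* degenerate positions (constant trait, rank-deficient design) raise or are
  logged and recorded as NaN rows; the scan continues.

Significance thresholds use the Li & Ji eigenvalue method: from the
eigenvalues λ of the marker additive-score correlation matrix,
M_eff = Σ[1(λᵢ ≥ 1) + (λᵢ − ⌊λᵢ⌋)], and the Bonferroni-type adjustment
α′ = 1 − (1−α)^(1/M_eff) gives the LOD threshold −log₁₀ α′, computed
genome-wide and per chromosome. Constant marker columns are dropped with a
warning.

## Pleiotropy test

Traits whose 1-LOD support intervals overlap on a chromosome are candidate
members of one pleiotropic locus (traits peaking at the identical cM
position are accepted as pleiotropic without a formal test). The combined
position is the grid point maximizing the summed LOD over member traits —
the operational reading of "most likely combined position weighted by LOD";
ties break toward the position closest to the unweighted mean of the
per-trait peaks and are logged. The statistic is
Σ_t [χ²_t(own peak) − χ²_t(combined)] on n_traits − 1 df (one position per
trait in the separate model versus one shared position); p ≤ 0.05 rejects
the single-locus explanation. Because all quantities are profile lookups on
a shared grid, refitting and lookup give identical values; off-grid
positions would be refitted.

The χ²(T−1) reference assumes well-localized peaks (a quadratic profile
near its maximum). The test's stated precondition — each member trait's
peak passes its significance threshold — is what makes this hold; in
simulations with clearly significant peaks (LOD ≈ 7) the null rejection
rate is ~0.05–0.07, while weak, wandering peaks inflate it. Regions should
therefore be formed from significant peaks only, as the pipeline does.

## Cohort effects, patterns, and GxE

Genotypic means per scope (full population, each sex, each diet, four
sex-by-diet cohorts) are least-squares adjusted means: the trait is
regressed on the four ordered-genotype indicators plus mean-centered
sex/diet covariates for factors that still vary inside the scope. Raw and
adjusted means coincide on balanced data; adjusted means are the default
because cohort composition is never exactly balanced.

Pattern classification per cohort uses per-term significance at α = 0.05
(no multiplicity adjustment across traits × cohorts × terms — the count of
per-cohort calls is therefore anticonservative, which is documented rather
than hidden): additivity alone → additive; a and d with |d/a| ≤ 1.1 →
L-/S-dominance by sign concordance; d beyond a (or without it) → over- or
underdominance by the sign of d; i alone → bipolar dominance imprinting;
i and d without a → polar dominance; i and a with |i/a| ∈ [0.5, 2] →
paternal expression (signs agree) or maternal expression (signs oppose).
The idealized expression patterns have |i| = |a|; the [0.5, 2] band is a
tolerance for noisy estimates. Conflicting combinations are labelled by
their dominance pattern and flagged rather than silently resolved. The
dominance ratio d/a is reported only when a is significantly non-zero.

Differential dominance at a locus is summarized geometrically: with
per-trait effects standardized by phenotypic SD, the dominance vector's
component orthogonal to the additive axis, d⊥ = d − (d·â)â, defines a
synthetic trait w = d⊥/|d⊥| whose additive effect is 0 and whose dominance
effect is |d⊥| — pure over/underdominance whenever the additive and
dominance vectors are not colinear. |d⊥| below 1e-8 reports "no
differential dominance". Opposite-signed additive effects across traits
are flagged as antagonistic pleiotropy.

Crossing versus spreading: when a locus shows a significant additive ×
sex/diet interaction, the trait is re-analyzed after per-cohort
standardization X′ = (X − mean_k)/SD_k × SD_pooled (SD_pooled = the average
cohort SD), which removes dispersion differences so only rank changes of
genotypic means can drive the interaction. The verdict is "crossing" only
if the interaction survives standardization and two cohorts with
significant additive effects order LL and SS oppositely; a significant
interaction without a rank flip is "spreading". Verdicts are invariant to
per-cohort affine rescaling by construction (tested).

## The simulator

The simulator emulates the breeding design of an LG/SM-style mouse AIL:
10 founder pairs (S-strain males × L-strain females, both strains fully
inbred, so founders are homozygous L or S genome-wide), expansion to 75
breeding families, pseudo-random non-sib mating with exactly one male and
one female breeder per family per generation (the rule that equalizes
family contributions and roughly doubles Ne), and a final experimental
generation — default F16 — whose litters are split by sex between high-fat
and low-fat diets at weaning. Defaults: 75 families × 7 offspring
(~525 animals; family size is a free parameter because real sibship sizes
varied), 19 autosomes × 10 markers at 8 cM.

Gene dropping is fully phased — every transmitted allele's parental origin
is recorded — with crossovers from the Haldane (no-interference) model, as
a Markov walk over markers with free recombination across chromosome
boundaries. Phenotypes follow the scan's own generating equation: context
means, cohort-specific (a, d, i) QTL effects (QTL positions snap to the
nearest marker), the four family-structured random effects, and Gaussian
residuals. Litter sizes are fixed per configuration rather than drawn from
an empirical distribution. A single master seed spawns named substreams
(pedigree / meiosis / cohorts / phenotypes / Ne), so each stage is
independently reproducible and identical seeds give bit-identical output.

What the simulator does *not* emulate — and what passing tests therefore do
not establish about real data: genotyping error and missingness, phasing
error (real ordered genotypes come from pedigree-based reconstruction),
segregation distortion, crossover interference, X-linked loci, maternal or
litter environmental effects beyond the family variance components,
non-Gaussian trait distributions, and selection during breeding.

The effective-size estimator gene-drops unlinked neutral loci (start
frequency 0.5) through the breeding design and pools the standardized
frequency change: Ne = 1/(2·mean[(Δp)²/p(1−p)]), excluding transitions that
start from fixation; the Monte-Carlo standard error comes from per-replicate
estimates. A Wright–Fisher variant (random parent draws at the same census)
provides the Ne ≈ census baseline; the AIL rule at 75 pairs measures
Ne ≈ 300 against a census of 150.

## Problem sizes used in the test and calibration suites

Simulation-based checks run at reduced but honest scales chosen so each
check's asymptotics hold: null-scan calibration uses 19 autosomes × 10
markers, 75 families × 4 animals (n = 300) and 20 null traits; effective
size uses 10 replicates × 10 loci × 10 generations; cohort-effect recovery
uses the full design scale (75 × 14 ≈ 1,050) over 20 replicates; pleiotropy
calibration uses 150 null + 50 power replicates of a one-chromosome design
at n = 300 with strongly localized peaks. Fixed-effect SEs are ML-based
(no REML or Kenward–Roger correction), so nominal 2-SE coverage is
marginally anticonservative; recovery tests ask for ≥ 90% where the nominal
is 95%.

## Known limitations

Single-locus model only (no multi-QTL conditioning, no epistasis); X
chromosome out of scope; pleiotropy test limited to profile-based
comparisons (no joint multivariate fit); per-cohort significance calls are
unadjusted for multiplicity; the mixed model assumes independent,
homoscedastic variance components and Gaussian residuals.
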