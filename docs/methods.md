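# Methods

## Scientific setting

`micropart` analyses the relationship between a gut microbial community
profiled by 16S amplicon sequencing (an OTU-by-sample count table) and a
continuous growth phenotype — average daily gain (ADG, g/day) in a fattening
cohort of ~105 animals housed in cages, with sex and cage as nuisance
covariates.  Three questions drive the design: which OTUs associate with
growth, how much phenotypic variance the community explains as a whole
("microbiability"), and which predicted functional features track the
phenotype.

## Preprocessing

Sequencing effort is equalized by rarefying every sample to a common depth
(default 40,000 tags) by subsampling without replacement
(`numpy`'s multivariate hypergeometric); samples below the depth are dropped
with a warning.  Counts are then converted to within-sample fractions, and
OTUs are removed when their mean relative abundance is below 0.1% or their
detection prevalence is below 3% of samples.  Both rules are strict
("less than"): an OTU at exactly 3% prevalence is kept.  The mean (rather
than the maximum) relative abundance is the filter statistic, the common
convention; `abundance_statistic="max"` switches it.  Retained fractions are
*not* renormalized after filtering — downstream stages use the original
within-sample fractions — with renormalization available as an option.
Filtering after rarefaction (rather than before) is a documented choice; the
two orders differ only for OTUs straddling the thresholds.

The phenotype is corrected once, on the full cohort, by ordinary least
squares of ADG on dummy-coded sex and cage; all association and
cross-validation stages consume the residuals.  A covariate with one level
per sample is rejected (it would absorb the phenotype), and single-sample
levels — which force their residual to zero — are logged.

## The two-part association model

OTU abundances are zero-inflated: a sample either lacks the OTU or carries
it at some abundance.  The model therefore tests each OTU twice:

* **Binary part.**  OLS of the residual phenotype on the 0/1 detection
  indicator; the coefficient β₁ is the phenotype difference associated with
  detection, and the test is equivalent to a pooled-variance two-sample
  t-test.  Skipped when either detection state has fewer than 2 samples.
* **Quantitative part.**  Restricted to the samples where the OTU is
  present: the abundance feature q is the natural log of the relative
  abundance, z-scored (ddof = 1) across the present samples; β₂ is the
  phenotype slope per SD of q.  Skipped below `min_present` (default 5 —
  the 3% prevalence floor on ~105 samples admits OTUs present in only 4
  samples, too few for a stable regression) or when q has no spread.
* **Meta part.**  Stouffer's weighted-Z of the two signed z-scores
  (normal quantiles of the two-sided t p-values, carrying the effect sign)
  with weights √n_total and √n_present.  When one part is unavailable the
  meta statistic equals the other part's z.

The per-OTU association statistic is **min-p**, the minimum of the available
part p-values.  Taking a minimum over correlated tests is anticonservative,
so the observed min-p is calibrated against its own permutation null: the
residual phenotype is permuted (one shared permutation per iteration across
all OTUs, preserving the between-OTU correlation structure), min-p is
recomputed, and the empirical p-value uses the add-one rule
p_perm = (1 + #{permuted ≤ observed}) / (n_perm + 1), so it is never zero
and its floor is 1/(n_perm + 1) (default n_perm = 1000).  Benjamini–Hochberg
FDR across OTUs is applied to the *calibrated* p-values; the default
significance threshold is q < 0.05.  The test suite verifies both halves of
the rationale: under the null the analytic min-p is stochastically smaller
than uniform while the permutation p is uniform at the deciles.

Numerical choices: p-values are clamped to [1e-300, 1] before normal
quantiles; an exact fit (zero residual with nonzero slope) maps to the
clamp, while zero phenotype variance (globally or within the present set,
detected at relative tolerance 1e-10) is reported as "no evidence" (p = 1),
not as an exact fit.  OTUs with no valid part are excluded from the result
with a logged reason.

## Microbiability by cross-validation

The cohort is split into an 80% discovery / 20% validation partition
(sklearn `ShuffleSplit`), repeated `n_repeats` times (default 100).  On the
discovery half the two-part scan estimates β₁ⱼ, β₂ⱼ and min-p per OTU; for
each p-value threshold in the sweep (defaults 1e-4, 1e-3, 1e-2, 0.05, 0.1)
the selected OTUs define an additive score on the held-out samples

    r_m(i) = Σⱼ β₁ⱼ·bⱼ(i) + β₂ⱼ·qⱼ(i),

with bⱼ(i) detection in validation sample i and qⱼ(i) the log relative
abundance standardized using the *discovery-set* mean and SD (0 when
absent — no information flows from validation to discovery).  The squared
Pearson correlation between r_m and the residual phenotype over the
validation samples estimates the variance explained; it is defined as 0
when nothing is selected or the score is constant.  The sweep reports the
mean and SD of R² and the mean number of selected OTUs per threshold.

Two design points were genuinely open and are resolved as follows.
First, the additive score weights the presence feature by β₁ (a literal
unweighted presence sum plus a constant Σβ₁ would make the estimated binary
effect sizes inert, and any constant is annihilated by the correlation);
the literal variant remains available via `literal_score` for sensitivity
analysis.  Second, discovery-stage selection uses the analytic min-p rather
than the 1000-fold permutation p — running the full permutation inside
every repeat multiplies cost by three orders of magnitude for a ranking
that is nearly unchanged; `use_permutation_in_discovery` enables it.

## Diversity and the functional screen

Alpha diversity is computed on the rarefied table only (equal depth is what
makes observed-species counts comparable): observed species (OTUs with
count > 0), Shannon entropy −Σ pᵢ ln pᵢ in nats (a base switch is provided;
log base is a convention, not a result), and Good's coverage 1 − F₁/N with
F₁ the singleton count.  Group comparisons use the Wilcoxon rank-sum test
(unpaired by default — the generic "Wilcoxon" convention — with a paired
signed-rank option since repeated measurements of the same animals may be
compared), BH-corrected across the metrics tested together.

The functional screen computes Spearman's correlation between each
KO/pathway-like feature's relative abundance and the residual phenotype
(rank transform + vectorized Pearson, t-approximation p), applies BH-FDR
across features, and selects features with q < 0.05 *and* |r| > 0.4 (both
conditions required).  Constant features are excluded and logged.

## Synthetic cohorts

The generator mirrors the two-part structure the model assumes, so
parameter recovery is well-posed:

* Each OTU j has a detection probability πⱼ ~ Beta(0.6, 1.8) (right-skewed:
  many rare, few common OTUs; floored at 0.01) and a log-normal abundance
  profile with per-OTU log-mean ~ N(0, 1.5²) and within-OTU log-SD 1.0.
* A sample draws presence per OTU, log-normal latent abundances for the
  present ones, renormalizes to the simplex, and is sequenced as a
  multinomial draw at a library size uniform on [40,000, 150,000] —
  zero-inflated, compositional counts with realistic depth.
* The phenotype is y = μ + sex·I(male) + cage effect + Σⱼ(β₁ⱼbⱼ + β₂ⱼqⱼ) + ε,
  where qⱼ is the same standardized log latent abundance the association
  module uses.  Causal OTUs are drawn among those with moderate detection
  probability (0.25–0.75 by default) so both feature types are
  identifiable.  Effect sizes are in phenotype units (g/day); when
  `target_h2m` is set, the noise variance is solved so the microbiome term
  contributes the target fraction of var(y), and the realized fraction —
  var(microbiome term)/var(y) on the drawn data — is reported in the truth
  object.  Requesting `target_h2m = 0` alongside planted effects is
  rejected as contradictory.
* Cage is simulated as a litter-like grouping (default 6 animals per cage)
  with a normal random intercept.  The finishing phase of such studies
  houses one animal per cage, in which case cage cannot be a finishing-house
  factor; the group size is therefore an explicit parameter rather than a
  hard-wired assumption.
* Defaults (105 samples, 1500 OTUs, μ = 32.7 g/day, sex effect 1.5, cage SD
  1.0, noise SD 3.0, 5 + 5 causal OTUs, target h²m = 0.15) sketch a
  plausible fattening cohort: ADG dispersion of a few g/day and a modest
  true microbiability.

What the generator does *not* emulate: phylogenetic correlation among OTUs,
over-dispersion beyond the log-normal/multinomial composition
(e.g. Dirichlet-multinomial), longitudinal weaning-to-finishing dynamics,
and library-size/phenotype confounding.  Tests passing on these cohorts
demonstrate correctness and calibration of the statistics, not robustness
to every failure mode of real amplicon data.

## Problem sizes used in the validation suite

The statistical checks run on deliberately compact configurations chosen to
keep the full suite fast while leaving each property clearly resolvable:
type-I error uses 100 null cohorts of n = 100 × 200 OTUs at 200
permutations; power uses 5 cohorts with 10 planted effects at 1000
permutations; the permutation oracle enumerates all 7! relabelings of a
7-sample phenotype; microbiability recovery uses one n = 500 cohort with 20
causal OTUs at 20 CV repeats.

## Known limitations

* Power analysis of the exact acceptance configuration shows two structural
  ceilings worth knowing about when planning a real study of this shape.
  With m OTUs tested and BH-FDR applied to permutation p-values floored at
  1/(n_perm + 1), no OTU can be declared significant until at least
  ⌈m/(α·(n_perm + 1))⌉ OTUs simultaneously sit at the floor (≈ 4 OTUs for
  m = 200, α = 0.05, n_perm = 1000) — discoveries arrive in blocks, never
  singly.  And when k OTUs share a fixed fraction of phenotypic variance,
  the per-OTU test statistic scales like √(n·h²m/k), so many weak causal
  OTUs are individually undetectable regardless of effect-size bookkeeping.
* The cross-validated R² is an attenuated estimate of the true microbiome
  variance fraction: selection misses weak causal OTUs and estimated
  effects carry sampling noise.  With the true causal set and discovery
  estimated effects the estimator approaches the realized h²m; with
  threshold-based selection under weak per-OTU signal it can undershoot
  severalfold.  This mirrors the behaviour of marginal-effect microbiome
  scores generally and is a property of the procedure, not a defect of the
  implementation.
* The two-part model assumes the phenotype residuals are exchangeable under
  the null; group structure not captured by the covariates (e.g. relatedness)
  would invalidate the permutation null.
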