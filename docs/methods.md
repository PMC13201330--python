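# Methods

This note records the generative models, estimators and numerical
choices behind `osrsim`, the defaults and why they were chosen, and what
the synthetic designs do and do not capture.

## Synthetic cousin-pair structure

The analysis unit throughout is the *cousin pair*: two offspring whose
fathers are full siblings (father relatedness 0.5).  A "family" is a
grandparental cluster — one sibling parent pair plus each parent's
offspring.  The registry data this emulates are not available, so the
generator reproduces their aggregate geometry rather than their links:

* `zietsch_like_config()` uses 539,731 sibling-father pairs with
  offspring counts drawn i.i.d. from a zero-truncated Poisson whose rate
  (λ ≈ 1.976, mean ≈ 2.294) is solved numerically so the expected
  cousin pairs per family, (E n)², matches 2,840,847 / 539,731 ≈ 5.26.
  Both published totals are then matched within 1% in expectation.
  Only the first two moments of the offspring-count distribution enter
  the power of the clustered test appreciably, which is why a
  one-parameter count family suffices; the true registry count
  distribution is unknown and this preset is an approximation.
* One-offspring-per-father designs (the conservative lower bound) force
  exactly one offspring per parent, giving one cousin pair per family.

Genotypes at a biallelic locus are assigned to the *parent* generation
by explicit Mendelian descent: two grandparental genotypes per family
from Hardy–Weinberg at the minor-allele frequency, one allele from each
grandparent to each sibling independently.  This yields Hardy–Weinberg
marginals and sibling genotype correlation exactly 0.5 (verified by
enumeration); grandparents are discarded.

What the generator does **not** emulate: real family-size/sex
correlations, shared environment, assortative mating, secular trends,
and the registry's exact count distribution.  Power statements made with
it are statements about this synthetic geometry; the test suite shows
the clustered estimator is calibrated under the null regardless.

## Sex models

Sexes are coded 1 = male.  Two mechanisms map genetics to
`P(offspring is male)`:

* **Single locus**: `p = clip(p0 + β·g, 0, 1)` with `g` the father's
  minor-allele count — additive per allele, heterozygote shift β.  The
  locus is expressed through males (a heritable X:Y gamete-ratio
  mechanism in spermatogenesis).  In the design variant with random
  parental sexes, a female parent's offspring sex is governed by her
  mate's genotype, drawn independently from Hardy–Weinberg; such pairs
  carry no cousin–cousin correlation, so only the ~¼ of pairs with two
  male parents are informative.  This male-limited expression is what
  places the corrected power for MAF = 0.10, β = 0.10 at ~90% in the
  14M-pair design (unrestricted expression in both parental sexes would
  drive it to ~100%).
* **Latent propensity**: father propensity `p = clip(μ + A + E, 0, 1)`,
  `A ~ N(0, h²σ²)` split as `√½·A_family + √½·A_individual` so sibling
  fathers correlate at exactly 0.5 on the additive part, and
  `E ~ N(0, (1−h²)σ²)` independent.  Defaults μ = 0.514 (the observed
  male fraction) and σ = 0.025 (coefficient of variation 0.05); the
  documented σ grid is exact multiples {0.8, 1, 1.2, 1.5, 2} of the
  baseline.  At these scales the [0,1] clip activates with probability
  < 1e-8; the draw function reports clip counts and the tests assert
  none occur at table parameters.

Offspring sexes are independent Bernoulli draws given the parent
probability — the "probabilistic sex determination" that attenuates any
latent heritability in the realized phenotype.

## Clustered association analysis

`build_cousin_pairs` emits, per family, every offspring of sibling 1
crossed with every offspring of sibling 2 in both orderings, clustered
on the family; the sandwich absorbs both the ordering duplication and
the sharing of parents across pairs.  (A single-offspring rule provides
the lower-bound design.)

With one binary covariate the logistic MLE is closed-form in the pooled
2×2 table (`ψ = ln(ad/bc)`), and score contributions depend only on the
cell, so per-cluster cell counts are a sufficient statistic for the
cluster sandwich: bread = total Fisher information, meat = Σ over
clusters of outer products of summed scores.  The row-level fit and the
aggregated per-family-cells fit are algebraically identical (asserted
exactly in tests), which is what makes 2.8M-pair clustered replicates
cheap.  For fully independent pairs the sandwich reduces to the classic
`√(1/a+1/b+1/c+1/d)` log-odds-ratio SE, and simulated 2×2 tables can be
drawn directly as multinomials over the four exact pair-cell
probabilities (computed by enumeration over sibling genotype pairs,
parental-sex patterns and mate genotypes) — the fast path used at the
14M-pair scale.  Separation (an empty cell) is flagged, not raised, and
replicates with it count as non-rejections.

Wald p-values are two-sided normal, the GEE convention.  Independence
working correlation is used so point estimates coincide with ordinary
logistic regression.  `statsmodels` GEE and HC0 logistic fits serve as
independent oracles in the test suite.

**Tetrachoric correlation** maximizes the multinomial likelihood of the
2×2 quadrant probabilities under a bivariate normal with thresholds
fixed at the margins' normal quantiles; bounded Brent search on
r ∈ (−1, 1) with tolerance 1e-10, asymptotic SE from the numeric
curvature of the profile log-likelihood.  Zero cells put r on the
boundary (flagged); zero margins are errors.  Liability heritability is
`r / relatedness` with the divisor exposed (default 0.5 for sibling
parents) because published family analyses differ in how relative
classes are pooled; out-of-[0,1] estimates are flagged, never clipped.

## Power engine

Per replicate the engine generates the design, realizes sexes, fits the
clustered test and records `p < α`; power is the rejection fraction with
an exact Clopper–Pearson 95% CI (valid at the 0 and 1 extremes where
several grid cells sit).  Replicate RNGs derive from
`SeedSequence(base_seed, spawn_key=(cell_index, replicate_index))`:
cells are order-invariant and replicate counts extend without
reshuffling.  A `crn` mode shares replicate keys across cells (common
random numbers) for monotonicity checks.  Headline runs use 200–1000
replicates; CI-based checks use ≥50.

Default baselines: `p0 = 0.5` with random parental sexes for the
original-design emulation, `p0 = 0.514` with fixed male–male parents
for the registry-style designs.

## Evolution simulator

Individual-based, one additive genetic value per individual
(infinitesimal-with-mutation, no explicit loci).  Per generation:
`pop_size/2` matings, each with a mother sampled uniformly from females
and a father uniformly from males (per-capita paternity ∝ 1/N_males —
the negative frequency dependence of Fisher's argument); each family
spends `family_budget` (default 4.0) on offspring costing `cost_son` /
`cost_daughter`; offspring genetic value = midparent + optional
segregation noise + (with probability `mutation_rate`) a ±
`mutation_size` mutation; population regulated to `pop_size` by uniform
subsampling.  Defaults: start 0.50 exactly, segregation SD 0 (mutation
is the variance source), 32,000 generations for 800,000 years at a
25-year generation time, desk presets 2,000–8,000 generations at
pop_size 10³–10⁴.

Two structural choices determine whether the simulated equilibrium is
the equal-allocation optimum, and both were validated against the
closed form `cost_daughter/(cost_son+cost_daughter)`:

* **Parental sex control** (default `sex_determination="father"`,
  matching a gamete-ratio mechanism).  Letting the offspring's own
  genetic value set its sex creates an individual-control model — a
  son-biasing mutation always finds itself in the currently devalued
  sex — whose equilibrium sits measurably below the parental-control
  optimum.  That variant is retained as a config option, not a default.
* **Exact marginal costs.**  A child whose cost exceeds the remaining
  family budget is realized with probability remaining/cost.
  Deterministic stopping rules bias the effective cost ratio (overshoot
  discounts the last daughter; stop-on-unaffordable wastes budget on
  daughter-biased lineages) and shift the equilibrium by several
  percentage points.

Under the ample-mutation conditions used in the tests (rate 0.05, size
0.05, pop 10⁴) the realized OSR reaches the 2/3 optimum (costs 1:2) to
within 0.02 after roughly 5,000–6,000 generations; the convergence test
runs 8,000 generations and averages the final 1,000.

**Realized OSR heritability** is estimated as twice the single-parent →
offspring regression slope of the OSR phenotype (fraction of sons among
an individual's offspring), pooled over father and mother links,
averaged over the final 10% of generations, with a Monte-Carlo SE from
the spread of per-generation estimates (autocorrelation across
generations makes this SE approximate).  Negative estimates are
reported as such.  Two behaviours worth knowing: (i) attenuation — even
a fully heritable propensity yields realized h² ≈ Var(g)/(Var(g)+p̄q̄/n̄)
at family size n̄, verified against a closed-form oracle; (ii) under
directional selection with unequal costs the estimate sits a percent or
two *below* zero, because a daughter's phenotype reflects her mates'
propensities, and mates are drawn from the male pool, which is enriched
for son-biasing lineages — an estimator-level effect absent in the
neutral model, where estimates are slightly positive as expected.

**Classification** of a condition: progress = (window-mean OSR − 0.5) /
(optimum − 0.5); red below the halfway point, green above, white within
a ±0.05 progress band of halfway (the halfway "colour" is a band, not a
measure-zero event); `within_ci` iff the window-mean realized h² lies in
the empirical interval [−0.00147, 0.00038] (bounds configurable — an
alternative published pair is [−0.00076, 0.00196] / 2 on the liability
scale); asterisk = at-least-halfway progress *and* within the CI.
Extinct runs classify red with a reason code.  The default grid is 8
mutation rates × 5 sizes = 40 conditions with order-invariant per-cell
seeds.  The h²-CI flag is only as good as the estimator's sampling
noise (SE a few 10⁻³ at desk scale against a CI ~2×10⁻³ wide), so
grid-level CI flags at small population sizes are indicative, not
inferential — the classification logic itself is exercised on exact
constructed trajectories in the tests.

## Determinism and I/O

All randomness flows from explicit integer seeds through
`numpy.random.SeedSequence` hierarchies; no global state.  Identical
config + seed reproduces every TSV byte-for-byte, and each pipeline run
writes a JSON manifest (resolved config, base seed, derivation rule,
package version, output SHA-256 checksums) sufficient to re-run.
Pedigrees, pair tables, trajectories and grids are plain TSV with frozen
column vocabularies and `NA` for missing values.

## Known limitations

* The cousin-pair structure is a two-moment approximation of the
  registry design; mid-grid latent-model powers are sensitive to the
  family-size distribution and should be read as ordering, not point
  predictions.
* The single-locus emulation at a genome-wide threshold retains ~1–2%
  power (mean Wald z ≈ 3.4 puts a non-trivial mass beyond |z| = 5.45);
  "effectively zero" at that threshold would require a design with
  roughly 2/3 of the information, which is incompatible with ~90% power
  at α = 0.05 under the same design.
* The evolution model is one member of the described model class
  (budgeted families, midparent inheritance, ± mutation); absolute
  per-condition heritabilities and the count of asterisked cells depend
  on these structural choices, population size and window length.
* No dominance, shared environment, multi-locus architecture,
  X/Y-linked transmission, or demographic structure anywhere.
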