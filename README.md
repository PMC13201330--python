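# osrsim

Simulation toolkit for the genetics of human **offspring sex ratio (OSR)** —
the fraction of sons among an individual's children.  Large family studies
estimate OSR heritability at essentially zero, which is hard to reconcile
with Fisher's principle of sex-ratio evolution.  One proposed escape is a
*latent, heritable propensity* expressed through probabilistic sex
determination: each parent carries a probability of producing sons, but with
only a few Bernoulli draws per family the observable OSR phenotype could
look non-heritable.  `osrsim` provides the machinery to examine that
argument quantitatively:

* **Synthetic cousin-pair designs** — pedigrees of full-sibling parent
  pairs and their offspring emulating the statistical geometry of the
  Swedish-registry analysis (539,731 male–male sibling pairs; ≈2.84M cousin
  pairs; 14,015,421 pairs in the full design), with Mendelian transmission
  of a biallelic locus through latent grandparents.
* **Familial-aggregation inference** — logistic regression of one cousin's
  sex on the other's with cluster-robust (GEE-type) sandwich errors,
  closed-form at any scale; maximum-likelihood tetrachoric correlation and
  liability-scale heritability with confidence intervals.
* **Monte-Carlo power engines** — replicated power for a single locus
  (probability shift β per minor allele at frequency MAF) and for a latent
  normal propensity (mean 0.514, SD σ, heritability h²) on the full
  clustered structure, with exact sufficient-statistic fast paths that make
  14M-pair replicates take milliseconds.
* **A Fisherian evolution simulator** — individual-based directional model
  in which a son propensity starting at 0.50 evolves toward the
  equal-allocation optimum `cost_daughter/(cost_son+cost_daughter)` under
  negative frequency-dependent selection, with per-condition classification
  (progress colour, realized-heritability CI flag, asterisk).

The intended audience is researchers in behaviour genetics and evolutionary
biology who want to stress-test claims about undetectable heritability of
binary-outcome traits under explicit generative models.

## The statistics in brief

For cousins *i, j* with full-sibling fathers, the association test fits
`logit P(y_i = 1) = α + ψ y_j` by ordinary logistic ML (independence
working correlation) and uses the cluster sandwich
`V = B⁻¹ (Σ_c S_c S_cᵀ) B⁻¹` over extended families *c* for the Wald test
of ψ.  A latent propensity `p = μ + A + E`, `A ~ N(0, h²σ²)` with sibling
correlation ½, `E ~ N(0, (1−h²)σ²)`, induces a cousin-sex covariance
`½ h² σ²`, so the detectable signal scales with both the heritability and
the variance of the propensity.  Liability heritability is read off a 2×2
cousin table as `h² = r_tetrachoric / 0.5`.

## Worked example

`examples/single_locus_power.py` reproduces the headline power
calculation — the same condition evaluated at the correct
familial-aggregation threshold and at a genome-wide threshold:

```
MAF = 0.10, per-allele shift in P(male offspring) = 0.10, 14,015,421 cousin pairs
  power at alpha = 0.05 : 0.945 (95% CI 0.904-0.972)
  power at alpha = 5e-8 : 0.010 (95% CI 0.001-0.036)
```

A registry-scale family design detects a MAF-10%, β=0.10 locus with ~90%
power at α = 0.05; misapplying the genome-wide 5×10⁻⁸ threshold to this
single test collapses the power to ~0.  The other example scripts print,
with one narrative line each: the latent-propensity power surface
(`latent_propensity_power.py`), a tetrachoric heritability estimate under
the null with its few-thousandths-wide interval
(`tetrachoric_heritability.py`), and a full directional evolution run with
its classification (`fisher_evolution.py`), e.g.

```
Fisher optimum (male fraction): 0.6667
  gen     0: realized OSR = 0.5250
  gen  4000: realized OSR = 0.6374
  gen  7999: realized OSR = 0.6660
final-window mean OSR : 0.6698
realized OSR h2       : -0.01565 (MC SE 0.00083)
classification        : colour=green, progress=1.02, within empirical h2 CI=False, asterisk=False
```

## Command line

A thin CLI wraps the library for batch runs; every run writes tidy TSV
plus a JSON manifest (resolved config, base seed, version, output
checksums) that reproduces the outputs byte-for-byte:

```bash
osr power locus --maf 0.10 --beta 0.10 --n-pairs 14015421 --reps 200 --seed 1 --out run1
osr power latent --h2 1.0 --sigma-mult 2.0 --reps 50 --seed 1 --out run2
osr evolve --mutation-rate 0.05 --mutation-size 0.05 --cost-daughter 2 --seed 1 --out run3
osr evolve-grid --rates 0.01 --rates 0.05 --sizes 0.05 --reps 3 --seed 1 --out run4
osr export --results run4/evolve-grid.tsv --figure fig2_style --out fig2.tsv
```

## Layout

```
src/osrsim/        family.py (pedigrees), sex_models.py, association.py,
                   power.py, evolution.py, reporting.py, cli.py
examples/          one narrative script per capability
tests/             unit + property suite, incl. end-to-end acceptance checks
docs/methods.md    modelling assumptions, parameter choices, limitations
```
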