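"""Power to detect a heritable latent offspring-sex propensity.

Each father carries a latent probability of producing sons, normally
distributed around 0.514; full-sibling fathers share half of the
additive variance.  Offspring sexes are Bernoulli draws, and the
analysis is the clustered cousin-pair logistic regression on the
synthetic male-male sibling structure (~2.84M cousin pairs, as in the
Swedish registry design).
"""

from osrsim import LatentPropensityConfig, estimate_power_latent, zietsch_like_config

family = zietsch_like_config()  # 539,731 sibling-father pairs
print("h2    sigma   power   (95% CI)")
for sigma, label in [(0.025, "baseline"), (0.050, "+100%")]:
    for h2 in (0.6, 1.0):
        est = estimate_power_latent(
            LatentPropensityConfig(h2=h2, mu=0.514, sigma=sigma),
            family, alpha=0.05, n_replicates=20, seed=2,
        )
        print(f"{h2:.1f}   {sigma:.3f}  {est.power:5.2f}   "
              f"({est.ci_low:.2f}-{est.ci_high:.2f})  {label}")
print("Power rises steeply with both the heritability and the spread of the "
      "latent propensity: a wide or strongly heritable propensity would not "
      "have gone unnoticed in the registry analysis.")
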