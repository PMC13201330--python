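"""Directional evolution of the sex-ratio propensity under Fisher's
principle with sons half as costly as daughters.

The propensity starts at 0.50 and, with mutational input, climbs toward
the equal-allocation optimum cost_daughter/(cost_son+cost_daughter) =
2/3.  Along the way the realized offspring-sex-ratio heritability —
what a family study could measure — stays tiny, because each family's
OSR is a handful of Bernoulli draws.
"""

import numpy as np

from osrsim import (
    ClassificationConfig,
    EvolutionConfig,
    classify_condition,
    evolve,
    fisher_optimum,
    realized_osr_heritability,
)

config = EvolutionConfig(
    pop_size=10_000, n_generations=8_000,
    mutation_rate=0.05, mutation_size=0.05,
    cost_son=1.0, cost_daughter=2.0, family_budget=4.0,
    seed=6,
)
trajectory = evolve(config)
optimum = fisher_optimum(config.cost_son, config.cost_daughter)
h2, h2_se = realized_osr_heritability(trajectory)
cls = classify_condition(trajectory, ClassificationConfig(optimum=optimum))

print(f"Fisher optimum (male fraction): {optimum:.4f}")
for gen in (0, 2_000, 4_000, 6_000, 7_999):
    print(f"  gen {gen:>5}: realized OSR = {trajectory.realized_osr[gen]:.4f}")
window = np.nanmean(trajectory.realized_osr[-1_000:])
print(f"final-window mean OSR : {window:.4f}")
print(f"realized OSR h2       : {h2:+.5f} (MC SE {h2_se:.5f})")
print(f"classification        : colour={cls.colour}, progress={cls.progress:.2f}, "
      f"within empirical h2 CI={cls.within_ci}, asterisk={cls.asterisk}")
print("The sex ratio evolves essentially all the way to the cost-determined "
      "optimum (colour green) while the measurable OSR heritability stays "
      "within a couple of hundredths of zero — minuscule next to the fully "
      "heritable latent propensity, yet at this ample-mutation corner still "
      "outside the narrow empirical interval, so the condition earns no "
      "asterisk.")
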