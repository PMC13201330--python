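"""Liability-scale heritability of offspring sex from a cousin 2x2 table.

Simulates the null world (no heritable propensity), cross-tabulates
cousin sexes, and converts the tetrachoric correlation of the 2x2 table
into a liability-scale heritability using the 0.5 relatedness of
full-sibling fathers — the estimator family studies use to report
near-zero offspring-sex-ratio heritability with tight intervals.
"""

import numpy as np

from osrsim import (
    LatentPropensityConfig,
    build_cousin_pairs,
    draw_latent_propensities,
    generate_family_structure,
    heritability_from_tetrachoric,
    realize_offspring_sexes,
    tetrachoric_correlation,
    zietsch_like_config,
)

family = zietsch_like_config(n_sibling_pairs=200_000, seed=3)
pedigree = generate_family_structure(family)
props = draw_latent_propensities(
    pedigree, LatentPropensityConfig(h2=0.0, mu=0.514, sigma=0.025), seed=4
)
pedigree = realize_offspring_sexes(pedigree, props, seed=5)
pairs = build_cousin_pairs(pedigree, "one_per_family")

counts = np.zeros((2, 2), dtype=int)
for (y, x), k in pairs.groupby(["outcome_sex", "covariate_sex"]).size().items():
    counts[1 - y, 1 - x] = k

tet = tetrachoric_correlation(counts)
ci = (tet.r - 1.96 * tet.se, tet.r + 1.96 * tet.se)
est = heritability_from_tetrachoric(tet.r, parent_relatedness=0.5, ci=ci)

print(f"cousin pairs analysed : {len(pairs):,}")
print(f"tetrachoric r         : {tet.r:+.5f} (SE {tet.se:.5f})")
print(f"liability h2          : {est.h2:+.5f} "
      f"(95% CI {est.ci_low:+.5f} to {est.ci_high:+.5f})")
print("Under the null the heritability estimate is ~0 with an interval a "
      "few thousandths wide — the scale on which empirical registry "
      "estimates exclude any appreciable OSR heritability.")
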