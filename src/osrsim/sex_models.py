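"""Generative models mapping genetic state to offspring-sex probability.

Two mechanisms are supported:

* a single biallelic locus shifting the probability of a male offspring
  additively per minor allele, and
* a latent normally distributed OSR propensity with a specified
  heritability, shared between full-sibling parents with additive
  genetic correlation 0.5.

Offspring sexes are coded 1 = male, 0 = female throughout, and are
realized as independent Bernoulli draws from the parent's probability
(probabilistic sex determination — the source of the attenuation that
makes realized OSR heritability far smaller than the latent one).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "LocusEffectConfig",
    "LatentPropensityConfig",
    "SIGMA_MULTIPLIERS",
    "sigma_variants",
    "genotype_to_sex_probability",
    "draw_latent_propensities",
    "realize_offspring_sexes",
]

#: Row labels of the latent-model power table: multipliers applied to
#: the baseline propensity standard deviation 0.025.
SIGMA_MULTIPLIERS = {
    "-20%": 0.8,
    "original": 1.0,
    "+20%": 1.2,
    "+50%": 1.5,
    "+100%": 2.0,
}


def sigma_variants(base_sigma: float = 0.025) -> dict[str, float]:
    """The documented standard-deviation grid: exact multiples of base."""
    return {label: base_sigma * m for label, m in SIGMA_MULTIPLIERS.items()}


@dataclass(frozen=True)
class LocusEffectConfig:
    """Additive single-locus effect on P(male offspring).

    ``beta`` is the shift in probability per minor allele; the
    heterozygote shift is beta and the homozygote shift 2*beta, clipped
    to [0, 1].
    """

    beta: float
    p0: float = 0.514

    def validate(self) -> None:
        if not 0 < self.p0 < 1:
            raise ValueError("p0 must lie in (0, 1)")
        if not abs(self.beta) < 1:
            raise ValueError("|beta| must be < 1")


@dataclass(frozen=True)
class LatentPropensityConfig:
    """Latent normal OSR propensity with heritability ``h2``.

    The propensity of parent j is mu + A_j + E_j with
    A ~ N(0, h2 * sigma^2) and E ~ N(0, (1 - h2) * sigma^2); within a
    full-sibling pair Corr(A_1, A_2) = 0.5 and E is independent.
    Draws are clipped to [0, 1]; at the default scale (mu = 0.514,
    sigma <= 0.05) clipping has probability < 1e-8.
    """

    h2: float
    mu: float = 0.514
    sigma: float = 0.025

    def validate(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if not 0 <= self.h2 <= 1:
            raise ValueError("h2 must lie in [0, 1]")
        if not 0 < self.mu < 1:
            raise ValueError("mu must lie in (0, 1)")


def genotype_to_sex_probability(genotype, config: LocusEffectConfig):
    """clip(p0 + genotype * beta, 0, 1) for genotype in {0, 1, 2}.

    Accepts scalars or arrays; raises on genotypes outside {0, 1, 2}.
    """
    config.validate()
    g = np.asarray(genotype)
    if not np.isin(g, (0, 1, 2)).all():
        raise ValueError("genotype must be a minor-allele count in {0, 1, 2}")
    p = np.clip(config.p0 + g * config.beta, 0.0, 1.0)
    if np.isscalar(genotype) or np.ndim(genotype) == 0:
        return float(p)
    return p


def sibling_propensity_components(
    rng: np.random.Generator, n_families: int, config: LatentPropensityConfig
) -> np.ndarray:
    """Draw (n_families, 2) propensities for the two sibling parents.

    The additive value splits into a family-shared and an individual
    segregation part, A = sqrt(0.5)*A_family + sqrt(0.5)*A_individual,
    which yields sibling correlation 0.5 on A with the correct marginal
    variance h2 * sigma^2.
    """
    sd_a = config.sigma * np.sqrt(config.h2)
    sd_e = config.sigma * np.sqrt(1.0 - config.h2)
    a_fam = rng.standard_normal(n_families)[:, None]
    a_ind = rng.standard_normal((n_families, 2))
    a = sd_a * (np.sqrt(0.5) * a_fam + np.sqrt(0.5) * a_ind)
    e = sd_e * rng.standard_normal((n_families, 2))
    return config.mu + a + e


def draw_latent_propensities(
    pedigree: pd.DataFrame, config: LatentPropensityConfig, seed: int
) -> pd.DataFrame:
    """Per-parent latent propensities for a pedigree.

    Returns a frame with columns ``parent_id``, ``propensity`` and
    ``clipped`` (whether the [0, 1] clip was active for that parent —
    all False for every parameter setting used in the power tables).
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    parents = (
        pedigree[["family_id", "parent_id", "sibling_index"]]
        .drop_duplicates()
        .sort_values(["family_id", "sibling_index"])
    )
    fam_codes, fam_index = pd.factorize(parents["family_id"], sort=True)
    n_fam = len(fam_index)
    raw = sibling_propensity_components(rng, n_fam, config)
    # parents are sorted family-major, sibling-minor: raw rows align
    values = raw[fam_codes, parents["sibling_index"].to_numpy() - 1]
    clipped = (values < 0.0) | (values > 1.0)
    return pd.DataFrame(
        {
            "parent_id": parents["parent_id"].to_numpy(),
            "propensity": np.clip(values, 0.0, 1.0),
            "clipped": clipped,
        }
    )


def realize_offspring_sexes(
    pedigree: pd.DataFrame,
    parent_probabilities: pd.Series | pd.DataFrame,
    seed: int,
) -> pd.DataFrame:
    """Fill ``offspring_sex`` with independent Bernoulli draws.

    ``parent_probabilities`` is a Series indexed by parent_id (or a
    frame with ``parent_id`` / ``propensity`` columns, as returned by
    :func:`draw_latent_propensities`).  Every parent with offspring must
    have a probability in [0, 1].
    """
    if isinstance(parent_probabilities, pd.DataFrame):
        parent_probabilities = parent_probabilities.set_index("parent_id")[
            "propensity"
        ]
    probs = parent_probabilities.reindex(pedigree["parent_id"]).to_numpy(dtype=float)
    if np.isnan(probs).any():
        missing = pedigree["parent_id"][np.isnan(probs)].unique()[:5]
        raise ValueError(f"missing sex probability for parents {list(missing)}")
    if ((probs < 0) | (probs > 1)).any():
        raise ValueError("sex probabilities must lie in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    out = pedigree.copy()
    out["offspring_sex"] = pd.array(
        (rng.random(len(out)) < probs).astype(np.int64), dtype="Int64"
    )
    return out
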