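"""Synthetic pedigrees for cousin-pair offspring-sex-ratio designs.

A "family" here is a grandparental cluster: two full-sibling parents,
each with one or more offspring.  Two offspring whose parents are full
siblings are first cousins; the cousin pair is the analysis unit of the
Swedish-registry familial-aggregation design this generator emulates.
The registry links themselves are not available, so the generator
reproduces their aggregate geometry: number of sibling parent pairs and
the offspring-count distribution (hence the total cousin-pair count).

Pedigrees are plain :class:`pandas.DataFrame` objects with one row per
offspring and the frozen column vocabulary in :data:`PEDIGREE_COLUMNS`.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import exp, sqrt

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "PEDIGREE_COLUMNS",
    "ZIETSCH_N_FAMILIES",
    "ZIETSCH_ALL_OFFSPRING_PAIRS",
    "FamilyStructureConfig",
    "zietsch_like_config",
    "ztp_mean",
    "ztp_lambda_for_mean",
    "generate_family_structure",
    "count_cousin_pairs",
    "transmit_locus",
    "sibling_genotype_joint",
    "hardy_weinberg",
    "write_pedigree_tsv",
    "read_pedigree_tsv",
]

#: TSV column vocabulary (frozen).
PEDIGREE_COLUMNS = [
    "family_id",
    "parent_id",
    "sibling_index",
    "parent_genotype",
    "offspring_id",
    "offspring_sex",
]

#: Male-male full-sibling parent pairs in the Swedish cousin design
#: when restricted to one offspring per father (= number of families).
ZIETSCH_N_FAMILIES = 539_731
#: Cousin pairs from male-male full-sibling parents and all offspring.
ZIETSCH_ALL_OFFSPRING_PAIRS = 2_840_847


class ConfigurationError(ValueError):
    """Raised for invalid generator configurations."""


@dataclass(frozen=True)
class FamilyStructureConfig:
    """Configuration of the synthetic family structure.

    Parameters
    ----------
    n_sibling_pairs:
        Number of full-sibling parent pairs (= grandparental clusters).
    offspring_count_model:
        ``"fixed"`` (every parent has exactly ``k`` offspring),
        ``"ztp"`` (zero-truncated Poisson with rate ``lam``), or
        ``"empirical"`` (``count_table`` maps count -> probability).
    one_offspring_per_father:
        Force exactly one offspring per parent (the lower-bound design).
    parent_sex_mode:
        ``"fixed_male_male"`` — both sibling parents are male;
        ``"random"`` — independent fair coin per parent (the original
        emulation with "unnecessary randomness in parental sexes").
    seed:
        RNG seed; mandatory at generation time (here or as an argument).
    """

    n_sibling_pairs: int
    offspring_count_model: str = "fixed"
    k: int = 1
    lam: float | None = None
    count_table: dict[int, float] | None = None
    one_offspring_per_father: bool = False
    parent_sex_mode: str = "fixed_male_male"
    seed: int | None = None

    def validate(self) -> None:
        if self.n_sibling_pairs < 0:
            raise ConfigurationError("n_sibling_pairs must be >= 0")
        if self.parent_sex_mode not in ("fixed_male_male", "random"):
            raise ConfigurationError(
                f"unknown parent_sex_mode {self.parent_sex_mode!r}"
            )
        if self.one_offspring_per_father:
            return
        if self.offspring_count_model == "fixed":
            if self.k < 1:
                raise ConfigurationError("fixed offspring count k must be >= 1")
        elif self.offspring_count_model == "ztp":
            if self.lam is None or self.lam <= 0:
                raise ConfigurationError("ztp model requires lam > 0")
        elif self.offspring_count_model == "empirical":
            if not self.count_table:
                raise ConfigurationError("empirical model requires count_table")
            counts = np.array(sorted(self.count_table), dtype=int)
            probs = np.array([self.count_table[c] for c in counts], dtype=float)
            if (counts < 1).any():
                raise ConfigurationError("offspring counts must be >= 1")
            if (probs < 0).any() or not np.isclose(probs.sum(), 1.0, atol=1e-9):
                raise ConfigurationError("count_table probabilities must sum to 1")
        else:
            raise ConfigurationError(
                f"unknown offspring_count_model {self.offspring_count_model!r}"
            )


def ztp_mean(lam: float) -> float:
    """Mean of a zero-truncated Poisson with rate ``lam``."""
    return lam / (1.0 - exp(-lam))


def ztp_lambda_for_mean(mean: float) -> float:
    """Invert :func:`ztp_mean`; requires ``mean > 1``."""
    if mean <= 1:
        raise ConfigurationError("zero-truncated Poisson mean must exceed 1")
    return float(brentq(lambda lam: ztp_mean(lam) - mean, 1e-9, 100.0, xtol=1e-12))


def zietsch_like_config(
    n_sibling_pairs: int = ZIETSCH_N_FAMILIES,
    one_offspring_per_father: bool = False,
    seed: int | None = None,
) -> FamilyStructureConfig:
    """Preset calibrated to the Swedish male-male sibling design.

    Offspring counts are zero-truncated Poisson with the rate chosen so
    that the expected number of cousin pairs per family, E[n1]*E[n2],
    matches 2,840,847 / 539,731 ~= 5.26 — reproducing both printed
    totals within 1% at the default family count.
    """
    mean = sqrt(ZIETSCH_ALL_OFFSPRING_PAIRS / ZIETSCH_N_FAMILIES)
    return FamilyStructureConfig(
        n_sibling_pairs=n_sibling_pairs,
        offspring_count_model="ztp",
        lam=ztp_lambda_for_mean(mean),
        one_offspring_per_father=one_offspring_per_father,
        parent_sex_mode="fixed_male_male",
        seed=seed,
    )


def _sample_ztp(rng: np.random.Generator, lam: float, size: int) -> np.ndarray:
    """Zero-truncated Poisson via redraw of zeros (vectorized rejection)."""
    x = rng.poisson(lam, size)
    zero = x == 0
    while zero.any():
        x[zero] = rng.poisson(lam, int(zero.sum()))
        zero = x == 0
    return x


def sample_offspring_counts(
    config: FamilyStructureConfig, rng: np.random.Generator, n_parents: int
) -> np.ndarray:
    """Draw i.i.d. offspring counts for ``n_parents`` parents."""
    if config.one_offspring_per_father:
        return np.ones(n_parents, dtype=np.int64)
    if config.offspring_count_model == "fixed":
        return np.full(n_parents, config.k, dtype=np.int64)
    if config.offspring_count_model == "ztp":
        return _sample_ztp(rng, float(config.lam), n_parents).astype(np.int64)
    counts = np.array(sorted(config.count_table), dtype=np.int64)
    probs = np.array([config.count_table[c] for c in counts], dtype=float)
    probs = probs / probs.sum()
    return rng.choice(counts, size=n_parents, p=probs)


def _resolve_rng(config_seed: int | None, seed: int | None) -> np.random.Generator:
    if seed is None:
        seed = config_seed
    if seed is None:
        raise ConfigurationError("a seed is required (config.seed or seed argument)")
    return np.random.default_rng(np.random.SeedSequence(seed))


def generate_family_structure(
    config: FamilyStructureConfig, seed: int | None = None
) -> pd.DataFrame:
    """Generate a pedigree table: one row per offspring.

    Columns are :data:`PEDIGREE_COLUMNS` plus ``parent_is_male`` (a
    generator-side convenience used by the single-locus power designs;
    it is not part of the TSV contract).  ``parent_genotype`` and
    ``offspring_sex`` start missing (pandas ``NA``) and are filled by
    :func:`transmit_locus` / the sex models.
    """
    config.validate()
    rng = _resolve_rng(config.seed, seed)
    n_fam = int(config.n_sibling_pairs)

    n_parents = 2 * n_fam
    counts = sample_offspring_counts(config, rng, n_parents)
    if config.parent_sex_mode == "random":
        parent_is_male = rng.random(n_parents) < 0.5
    else:
        parent_is_male = np.ones(n_parents, dtype=bool)

    parent_id = np.arange(n_parents, dtype=np.int64)
    family_id = parent_id // 2
    sibling_index = (parent_id % 2 + 1).astype(np.int64)

    rows_parent = np.repeat(parent_id, counts)
    frame = pd.DataFrame(
        {
            "family_id": family_id[rows_parent],
            "parent_id": rows_parent,
            "sibling_index": sibling_index[rows_parent],
            "parent_genotype": pd.array([pd.NA] * len(rows_parent), dtype="Int64"),
            "offspring_id": np.arange(len(rows_parent), dtype=np.int64),
            "offspring_sex": pd.array([pd.NA] * len(rows_parent), dtype="Int64"),
            "parent_is_male": parent_is_male[rows_parent],
        }
    )
    return frame


def count_cousin_pairs(pedigree: pd.DataFrame) -> int:
    """Number of cousin pairs: sum over families of n1 * n2.

    n1, n2 are the offspring counts of the two sibling parents.  A pair
    is counted once (unordered).  Raises on families without exactly two
    distinct parents.
    """
    if len(pedigree) == 0:
        return 0
    per_parent = pedigree.groupby(["family_id", "parent_id"]).size()
    per_family = per_parent.groupby(level=0).size()
    if (per_family != 2).any():
        bad = per_family.index[per_family != 2][0]
        raise ValueError(f"family {bad} does not have exactly 2 parents")
    counts = per_parent.to_numpy().reshape(-1, 2)
    return int((counts[:, 0] * counts[:, 1]).sum())


def hardy_weinberg(maf: float) -> np.ndarray:
    """Genotype distribution (minor-allele count 0/1/2) at frequency ``maf``."""
    q = maf
    p = 1.0 - q
    return np.array([p * p, 2 * p * q, q * q])


def _transmission_matrix() -> np.ndarray:
    """P(transmitted allele = minor | parent genotype g) for g = 0,1,2."""
    return np.array([0.0, 0.5, 1.0])


def sibling_genotype_joint(maf: float) -> np.ndarray:
    """Exact 3x3 joint genotype distribution of two full siblings.

    Enumerates the two grandparental genotypes under Hardy-Weinberg and
    independent Mendelian transmission to each sibling.  Marginals are
    Hardy-Weinberg at ``maf``; the implied allele-count correlation is
    exactly 0.5.
    """
    if not 0 < maf <= 0.5:
        raise ConfigurationError("maf must lie in (0, 0.5]")
    hw = hardy_weinberg(maf)
    tmit = _transmission_matrix()
    joint = np.zeros((3, 3))
    for g_a, p_a in enumerate(hw):
        for g_b, p_b in enumerate(hw):
            # P(child genotype | grandparents) = conv of two Bernoulli alleles
            pa, pb = tmit[g_a], tmit[g_b]
            child = np.array(
                [
                    (1 - pa) * (1 - pb),
                    pa * (1 - pb) + (1 - pa) * pb,
                    pa * pb,
                ]
            )
            joint += p_a * p_b * np.outer(child, child)
    return joint


def transmit_locus(
    pedigree: pd.DataFrame, maf: float, seed: int | None = None
) -> pd.DataFrame:
    """Fill ``parent_genotype`` by Mendelian descent from latent grandparents.

    Per family, two grandparental genotypes are drawn from Hardy-Weinberg
    at ``maf``; each sibling parent independently receives one allele
    from each grandparent.  Grandparents are discarded (only the
    transmitting generation carries the locus in the sex models).
    """
    if not 0 < maf <= 0.5:
        raise ConfigurationError("maf must lie in (0, 0.5]")
    if seed is None:
        raise ConfigurationError("transmit_locus requires a seed")
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    out = pedigree.copy()
    if len(out) == 0:
        return out
    parents = out[["family_id", "parent_id"]].drop_duplicates().sort_values(
        "parent_id"
    )
    fam_codes, fam_index = pd.factorize(parents["family_id"], sort=True)
    n_fam = len(fam_index)
    gp1 = rng.binomial(2, maf, n_fam)
    gp2 = rng.binomial(2, maf, n_fam)
    n_parents = len(parents)
    a1 = rng.random(n_parents) < gp1[fam_codes] / 2.0
    a2 = rng.random(n_parents) < gp2[fam_codes] / 2.0
    genotype = (a1.astype(np.int64) + a2.astype(np.int64))
    geno_by_parent = pd.Series(genotype, index=parents["parent_id"].to_numpy())
    out["parent_genotype"] = pd.array(
        geno_by_parent.reindex(out["parent_id"]).to_numpy(), dtype="Int64"
    )
    return out


def write_pedigree_tsv(pedigree: pd.DataFrame, path) -> None:
    """Write the six-column pedigree TSV (missing values as ``NA``)."""
    pedigree[PEDIGREE_COLUMNS].to_csv(path, sep="\t", index=False, na_rep="NA")


def read_pedigree_tsv(path) -> pd.DataFrame:
    """Read a pedigree TSV written by :func:`write_pedigree_tsv`."""
    frame = pd.read_csv(
        path,
        sep="\t",
        na_values=["NA"],
        dtype={
            "family_id": np.int64,
            "parent_id": np.int64,
            "sibling_index": np.int64,
            "parent_genotype": "Int64",
            "offspring_id": np.int64,
            "offspring_sex": "Int64",
        },
    )
    return frame[PEDIGREE_COLUMNS]
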