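"""Monte-Carlo power estimation for family-based OSR association tests.

Two designs are simulated:

* **single locus** — independent cousin pairs, one offspring per parent,
  each pair descending from a full-sibling parental pair whose genotypes
  share Mendelian grandparents (Hardy-Weinberg founders).  The locus is
  expressed through male parents only (a heritable X:Y gamete-ratio
  mechanism); a female parent's offspring sex is driven by her mate's
  genotype, drawn independently from Hardy-Weinberg, which contributes
  no cousin-cousin correlation.  Under the "random" parental-sex mode
  only about a quarter of pairs are therefore informative.
* **latent propensity** — a full synthetic family structure (many
  offspring per parent), sibling-correlated latent propensities, and the
  clustered all-cross-pairs regression.

Both designs admit exact sufficient-statistic fast paths: the
independent-pair design through the pooled 2x2 table (multinomial over
the four sex-pattern cells), the clustered design through per-family
cell counts.  The fast paths are algebraically identical to the
row-level fits and are what make paper-scale replication (14 million
pairs per replicate) cheap.

Replicate seeds derive from ``SeedSequence(base_seed,
spawn_key=(cell_index, replicate_index))``, so grid cells are
order-invariant and replicate counts can be extended without
reshuffling earlier replicates.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats

from .association import (
    AssociationResult,
    build_cousin_pairs,
    fit_2x2_independent,
    fit_clustered_logistic,
    fit_from_family_cells,
)
from .family import (
    FamilyStructureConfig,
    generate_family_structure,
    hardy_weinberg,
    sample_offspring_counts,
    sibling_genotype_joint,
    transmit_locus,
)
from .sex_models import (
    LatentPropensityConfig,
    LocusEffectConfig,
    draw_latent_propensities,
    genotype_to_sex_probability,
    realize_offspring_sexes,
    sibling_propensity_components,
)

__all__ = [
    "PowerEstimate",
    "PowerGridSpec",
    "replicate_rng",
    "pair_cell_probabilities",
    "estimate_power_single_locus",
    "estimate_power_latent",
    "run_power_grid",
]


@dataclass(frozen=True)
class PowerEstimate:
    """Rejection proportion over replicates with an exact binomial CI."""

    power: float
    ci_low: float
    ci_high: float
    n_replicates: int
    n_rejections: int
    n_degenerate: int = 0
    p_values: tuple[float, ...] | None = None


@dataclass(frozen=True)
class PowerGridSpec:
    """A grid of power conditions (one model, rectangular axes)."""

    model: str  # "single_locus" | "latent_propensity"
    alpha: float
    n_replicates: int
    base_seed: int
    # single_locus axes
    mafs: tuple[float, ...] = ()
    betas: tuple[float, ...] = ()
    n_pairs: int = 0
    parent_sex_mode: str = "random"
    p0: float = 0.5
    # latent axes
    h2s: tuple[float, ...] = ()
    sigmas: tuple[float, ...] = ()
    family: FamilyStructureConfig | None = None
    mu: float = 0.514
    crn: bool = False

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.model == "single_locus":
            if not (self.mafs and self.betas and self.n_pairs >= 1):
                raise ValueError("single_locus grid needs mafs, betas, n_pairs")
        elif self.model == "latent_propensity":
            if not (self.h2s and self.sigmas and self.family is not None):
                raise ValueError("latent grid needs h2s, sigmas and a family config")
        else:
            raise ValueError(f"unknown model {self.model!r}")


def clopper_pearson(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact binomial confidence interval for a proportion."""
    alpha = 1.0 - conf
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def replicate_rng(
    base_seed: int, cell_index: int, replicate_index: int
) -> np.random.Generator:
    """Deterministic per-(cell, replicate) generator (stable spawn-key hash)."""
    ss = np.random.SeedSequence(base_seed, spawn_key=(cell_index, replicate_index))
    return np.random.default_rng(ss)


# ---------------------------------------------------------------------------
# single-locus design
# ---------------------------------------------------------------------------

def _locus_offspring_prob_dists(maf: float, cfg: LocusEffectConfig):
    """Hardy-Weinberg weights and per-genotype offspring male probability.

    A male parent of genotype g passes probability clip(p0 + beta*g); a
    female parent's offspring probability is driven by her mate's
    genotype, Hardy-Weinberg and independent of the family.
    """
    hw = hardy_weinberg(maf)
    p_by_g = np.array([genotype_to_sex_probability(g, cfg) for g in (0, 1, 2)])
    return hw, p_by_g


def pair_cell_probabilities(
    maf: float,
    beta: float,
    p0: float = 0.5,
    parent_sex_mode: str = "random",
) -> np.ndarray:
    """Exact joint distribution of a cousin pair's sexes (4 cells).

    Cells are ordered [P11, P10, P01, P00] for (outcome, covariate).
    Computed by enumeration over the sibling parents' joint genotypes
    (exact Mendelian joint, correlation 0.5), parental sexes, and —
    for female parents — the mate genotype marginalized over
    Hardy-Weinberg.
    """
    cfg = LocusEffectConfig(beta=beta, p0=p0)
    cfg.validate()
    joint_g = sibling_genotype_joint(maf)
    hw, p_by_g = _locus_offspring_prob_dists(maf, cfg)
    # moments of the offspring male probability per parent role
    p_father = p_by_g  # indexed by own genotype
    p_mother_mean = float(hw @ p_by_g)  # mate marginalized, independent

    if parent_sex_mode == "fixed_male_male":
        sex_patterns = [(True, True, 1.0)]
    elif parent_sex_mode == "random":
        sex_patterns = [
            (True, True, 0.25),
            (True, False, 0.25),
            (False, True, 0.25),
            (False, False, 0.25),
        ]
    else:
        raise ValueError(f"unknown parent_sex_mode {parent_sex_mode!r}")

    cells = np.zeros(4)
    for male1, male2, w in sex_patterns:
        if male1 and male2:
            p11 = float(np.einsum("ij,i,j->", joint_g, p_father, p_father))
            m1 = float(hw @ p_father)
            m2 = m1
        elif male1:
            m1 = float(hw @ p_father)
            m2 = p_mother_mean
            p11 = m1 * m2
        elif male2:
            m1 = p_mother_mean
            m2 = float(hw @ p_father)
            p11 = m1 * m2
        else:
            m1 = m2 = p_mother_mean
            p11 = m1 * m2
        cells += w * np.array(
            [p11, m1 - p11, m2 - p11, 1.0 - m1 - m2 + p11]
        )
    return cells


def _locus_replicate_pedigree(
    rng: np.random.Generator,
    maf: float,
    cfg: LocusEffectConfig,
    n_pairs: int,
    parent_sex_mode: str,
) -> AssociationResult:
    """Row-level single-locus replicate through the pedigree machinery."""
    seeds = rng.integers(0, 2**31 - 1, size=3)
    fam_cfg = FamilyStructureConfig(
        n_sibling_pairs=n_pairs,
        one_offspring_per_father=True,
        parent_sex_mode=parent_sex_mode,
        seed=int(seeds[0]),
    )
    ped = generate_family_structure(fam_cfg)
    ped = transmit_locus(ped, maf, seed=int(seeds[1]))
    rng2 = np.random.default_rng(np.random.SeedSequence(int(seeds[2])))
    g = ped["parent_genotype"].to_numpy(dtype=np.int64)
    is_male = ped["parent_is_male"].to_numpy()
    mate_g = rng2.binomial(2, maf, size=len(ped))
    eff_g = np.where(is_male, g, mate_g)
    probs = np.clip(cfg.p0 + cfg.beta * eff_g, 0.0, 1.0)
    prob_series = pd.Series(probs, index=ped["parent_id"].to_numpy())
    ped = realize_offspring_sexes(ped, prob_series, seed=int(seeds[2]) + 1)
    table = build_cousin_pairs(ped, pairing_rule="one_per_family")
    return fit_clustered_logistic(table)


def estimate_power_single_locus(
    maf: float,
    beta: float,
    n_pairs: int,
    alpha: float = 0.05,
    n_replicates: int = 200,
    seed: int = 0,
    parent_sex_mode: str = "random",
    p0: float = 0.5,
    method: str = "multinomial",
    cell_index: int = 0,
    keep_p_values: bool = False,
) -> PowerEstimate:
    """Power of the cousin-pair logistic test for one locus condition.

    ``method="multinomial"`` draws the pooled 2x2 sex-pattern table
    directly (the sufficient statistic of the independent-pairs design)
    and fits the closed-form logistic + sandwich; ``method="pedigree"``
    runs the full row-level pipeline (founder genotypes, Mendelian
    transmission, Bernoulli sexes, clustered fit) — identical in
    distribution, used for cross-validation at small n.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    cells = pair_cell_probabilities(maf, beta, p0=p0, parent_sex_mode=parent_sex_mode)
    cfg = LocusEffectConfig(beta=beta, p0=p0)
    rejections = 0
    degenerate = 0
    p_values: list[float] = []
    for rep in range(n_replicates):
        rng = replicate_rng(seed, cell_index, rep)
        if method == "multinomial":
            counts = rng.multinomial(n_pairs, cells)
            result = fit_2x2_independent(*counts.astype(float))
        elif method == "pedigree":
            result = _locus_replicate_pedigree(rng, maf, cfg, n_pairs, parent_sex_mode)
        else:
            raise ValueError(f"unknown method {method!r}")
        if result.separated or not np.isfinite(result.p):
            degenerate += 1  # counted as a non-rejection
            p_values.append(np.nan)
            continue
        p_values.append(result.p)
        if result.p < alpha:
            rejections += 1
    lo, hi = clopper_pearson(rejections, n_replicates)
    return PowerEstimate(
        power=rejections / n_replicates,
        ci_low=lo,
        ci_high=hi,
        n_replicates=n_replicates,
        n_rejections=rejections,
        n_degenerate=degenerate,
        p_values=tuple(p_values) if keep_p_values else None,
    )


# ---------------------------------------------------------------------------
# latent-propensity design
# ---------------------------------------------------------------------------

def latent_replicate_fit(
    rng: np.random.Generator,
    latent: LatentPropensityConfig,
    family: FamilyStructureConfig,
) -> AssociationResult:
    """One latent-model replicate via per-family sufficient statistics.

    Draws per-parent offspring counts and male counts directly
    (Binomial given the parent's propensity) and fits the clustered
    logistic from per-family cell counts of the both-orderings
    all-cross-pairs table:

        a_f = 2*m1*m2, b_f = c_f = m1*(n2-m2) + m2*(n1-m1),
        d_f = 2*(n1-m1)*(n2-m2).

    Exactly equal to building the row table and calling
    :func:`fit_clustered_logistic` (asserted in the test suite).
    """
    latent.validate()
    family.validate()
    n_fam = family.n_sibling_pairs
    props = np.clip(sibling_propensity_components(rng, n_fam, latent), 0.0, 1.0)
    counts = sample_offspring_counts(family, rng, 2 * n_fam).reshape(n_fam, 2)
    males = rng.binomial(counts, props)
    n1, n2 = counts[:, 0], counts[:, 1]
    m1, m2 = males[:, 0], males[:, 1]
    f1, f2 = n1 - m1, n2 - m2
    a_f = (2 * m1 * m2).astype(float)
    b_f = (m1 * f2 + m2 * f1).astype(float)
    d_f = (2 * f1 * f2).astype(float)
    return fit_from_family_cells(a_f, b_f, b_f.copy(), d_f)


def _latent_replicate_rows(
    rng: np.random.Generator,
    latent: LatentPropensityConfig,
    family: FamilyStructureConfig,
) -> AssociationResult:
    """Row-level latent replicate (reference path, small scale)."""
    seeds = rng.integers(0, 2**31 - 1, size=3)
    ped = generate_family_structure(
        FamilyStructureConfig(
            n_sibling_pairs=family.n_sibling_pairs,
            offspring_count_model=family.offspring_count_model,
            k=family.k,
            lam=family.lam,
            count_table=family.count_table,
            one_offspring_per_father=family.one_offspring_per_father,
            parent_sex_mode=family.parent_sex_mode,
            seed=int(seeds[0]),
        )
    )
    props = draw_latent_propensities(ped, latent, seed=int(seeds[1]))
    ped = realize_offspring_sexes(ped, props, seed=int(seeds[2]))
    table = build_cousin_pairs(ped, pairing_rule="all_cross_pairs")
    return fit_clustered_logistic(table)


def estimate_power_latent(
    latent: LatentPropensityConfig,
    family: FamilyStructureConfig,
    alpha: float = 0.05,
    n_replicates: int = 50,
    seed: int = 0,
    method: str = "aggregated",
    cell_index: int = 0,
    keep_p_values: bool = False,
) -> PowerEstimate:
    """Power of the clustered cousin-pair test under the latent model."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    rejections = 0
    degenerate = 0
    p_values: list[float] = []
    for rep in range(n_replicates):
        rng = replicate_rng(seed, cell_index, rep)
        if method == "aggregated":
            result = latent_replicate_fit(rng, latent, family)
        elif method == "rows":
            result = _latent_replicate_rows(rng, latent, family)
        else:
            raise ValueError(f"unknown method {method!r}")
        if result.separated or not np.isfinite(result.p):
            degenerate += 1
            p_values.append(np.nan)
            continue
        p_values.append(result.p)
        if result.p < alpha:
            rejections += 1
    lo, hi = clopper_pearson(rejections, n_replicates)
    return PowerEstimate(
        power=rejections / n_replicates,
        ci_low=lo,
        ci_high=hi,
        n_replicates=n_replicates,
        n_rejections=rejections,
        n_degenerate=degenerate,
        p_values=tuple(p_values) if keep_p_values else None,
    )


# ---------------------------------------------------------------------------
# grids
# ---------------------------------------------------------------------------

def run_power_grid(spec: PowerGridSpec) -> pd.DataFrame:
    """One :class:`PowerEstimate` per grid cell, order-invariant seeds.

    With ``crn=True`` the replicate seed ignores the cell index, giving
    common random numbers across cells (used for monotonicity checks).
    """
    spec.validate()
    rows = []
    if spec.model == "single_locus":
        axes = list(product(spec.mafs, spec.betas))
        for cell_index, (maf, beta) in enumerate(axes):
            est = estimate_power_single_locus(
                maf,
                beta,
                spec.n_pairs,
                alpha=spec.alpha,
                n_replicates=spec.n_replicates,
                seed=spec.base_seed,
                parent_sex_mode=spec.parent_sex_mode,
                p0=spec.p0,
                cell_index=0 if spec.crn else cell_index,
            )
            rows.append(
                {
                    "model": "single_locus",
                    "maf": maf,
                    "beta": beta,
                    "n_pairs": spec.n_pairs,
                    "alpha": spec.alpha,
                    "power": est.power,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                    "n_replicates": est.n_replicates,
                    "n_degenerate": est.n_degenerate,
                }
            )
    else:
        axes = list(product(spec.sigmas, spec.h2s))
        for cell_index, (sigma, h2) in enumerate(axes):
            latent = LatentPropensityConfig(h2=h2, mu=spec.mu, sigma=sigma)
            est = estimate_power_latent(
                latent,
                spec.family,
                alpha=spec.alpha,
                n_replicates=spec.n_replicates,
                seed=spec.base_seed,
                cell_index=0 if spec.crn else cell_index,
            )
            rows.append(
                {
                    "model": "latent_propensity",
                    "sigma": sigma,
                    "h2": h2,
                    "n_families": spec.family.n_sibling_pairs,
                    "alpha": spec.alpha,
                    "power": est.power,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                    "n_replicates": est.n_replicates,
                    "n_degenerate": est.n_degenerate,
                }
            )
    return pd.DataFrame(rows)
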