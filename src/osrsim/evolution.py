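"""Individual-based evolution of a sex-ratio propensity under Fisher's
principle with unequal parental costs.

Each individual carries a single additive genetic value: its propensity
to produce sons (infinitesimal-with-mutation; no explicit loci).  Every
generation, mating pairs are formed by sampling a mother uniformly from
females and a father uniformly from males — per-capita paternity scales
as 1/N_males, which is exactly the negative frequency dependence of
Fisher's argument.  Each family spends a fixed budget on offspring, sons
and daughters having different per-offspring costs, so producing the
cheaper sex yields more offspring per family.  Offspring inherit the
midparent genetic value plus segregation noise and, with some
probability, a mutation of fixed magnitude and random sign.

Two modelling choices matter for where the sex ratio equilibrates and
are easy to get subtly wrong:

* **Sex determination is parental.**  By default an offspring's sex is
  Bernoulli in the *father's* propensity (a heritable X:Y gamete-ratio
  mechanism; ``sex_determination="midparent"`` and ``"offspring"`` are
  provided as variants).  If the offspring's own genetic value set its
  sex, a son-biasing mutation would always find itself in the currently
  devalued sex — an individual-control model whose equilibrium sits
  below the parental-control optimum.
* **The family budget is spent at exact marginal costs.**  A child
  whose cost exceeds the family's remaining budget is realized with
  probability remaining/cost.  Deterministic stopping rules either let
  the last daughter overshoot (discounting her effective cost) or waste
  leftover budget on daughter-biased lineages; both distort the
  effective cost ratio and shift the equilibrium away from the
  equal-allocation point.

With these choices and ample mutational input the mean realized
offspring sex ratio (OSR) converges to the Fisher equilibrium
``cost_daughter / (cost_son + cost_daughter)``.  The population is
regulated back to a constant size by uniform subsampling of offspring.

The realized-OSR heritability tracked along the trajectory is the
quantity empirical family studies estimate: twice the single-parent ->
offspring regression slope of the OSR phenotype (fraction of sons among
an individual's offspring), heavily attenuated relative to the latent
propensity by Bernoulli sampling noise at small family sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import product

import numpy as np
import pandas as pd

__all__ = [
    "EvolutionConfig",
    "EvolutionTrajectory",
    "ClassificationConfig",
    "Classification",
    "fisher_optimum",
    "evolve",
    "parent_offspring_h2",
    "realized_osr_heritability",
    "classify_condition",
    "classify_values",
    "run_condition_grid",
]

#: Empirical 95% CI for realized OSR heritability (UK GWAS-based bounds)
#: used by the default classification.
DEFAULT_H2_CI = (-0.00147, 0.00038)


def fisher_optimum(cost_son: float, cost_daughter: float) -> float:
    """Equilibrium male fraction equalizing expenditure on the sexes.

    Solving N_m * cost_son = N_f * cost_daughter gives the male fraction
    cost_daughter / (cost_son + cost_daughter).
    """
    if cost_son <= 0 or cost_daughter <= 0:
        raise ValueError("offspring costs must be > 0")
    return cost_daughter / (cost_son + cost_daughter)


@dataclass(frozen=True)
class EvolutionConfig:
    """Parameters of the directional evolution simulation.

    ``n_generations`` defaults to 800,000 years at a 25-year generation
    time (32,000 generations); desk-scale runs use far fewer.  The
    family budget must afford at least two offspring of the costlier
    sex so the population can replace itself.
    """

    pop_size: int = 10_000
    n_generations: int = 32_000
    mutation_rate: float = 0.0
    mutation_size: float = 0.0
    cost_son: float = 1.0
    cost_daughter: float = 1.0
    family_budget: float = 4.0
    segregation_sd: float = 0.0
    initial_propensity: float = 0.50
    initial_propensity_sd: float = 0.0
    sex_determination: str = "father"  # father | midparent | offspring
    seed: int = 0

    def validate(self) -> None:
        if self.sex_determination not in ("father", "midparent", "offspring"):
            raise ValueError(
                f"unknown sex_determination {self.sex_determination!r}"
            )
        if self.pop_size < 2:
            raise ValueError("pop_size must be >= 2")
        if self.cost_son <= 0 or self.cost_daughter <= 0:
            raise ValueError("offspring costs must be > 0")
        if not 0 <= self.mutation_rate <= 1:
            raise ValueError("mutation_rate must lie in [0, 1]")
        if self.family_budget < 2 * max(self.cost_son, self.cost_daughter):
            raise ValueError(
                "family_budget must afford at least two offspring of the "
                "costlier sex"
            )
        if self.n_generations < 1:
            raise ValueError("n_generations must be >= 1")


@dataclass
class EvolutionTrajectory:
    """Per-generation summaries plus parent-offspring regression stats.

    ``h2_estimate[t]`` is twice the pooled single-parent regression
    slope linking generation t individuals' OSR phenotypes to their
    parents' (defined from the second recorded generation on; NaN where
    undefined).  The raw per-generation regression sufficient statistics
    are retained so windowed estimators can be recomputed.
    """

    config: EvolutionConfig
    mean_propensity: np.ndarray
    male_fraction: np.ndarray
    realized_osr: np.ndarray
    h2_estimate: np.ndarray
    regression_stats: np.ndarray  # columns: n, sx, sy, sxx, sxy
    children_produced: np.ndarray | None = None
    paternal_offspring_sum: np.ndarray | None = None
    maternal_offspring_sum: np.ndarray | None = None
    extinct: bool = False
    extinct_generation: int | None = None

    @property
    def n_recorded(self) -> int:
        return len(self.mean_propensity)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "generation": np.arange(self.n_recorded),
                "mean_propensity": self.mean_propensity,
                "realized_osr": self.realized_osr,
                "male_fraction": self.male_fraction,
                "h2_estimate": self.h2_estimate,
            }
        )


def _slope_from_stats(stats_row: np.ndarray) -> float:
    n, sx, sy, sxx, sxy = stats_row
    if n < 2:
        return np.nan
    varx = sxx - sx * sx / n
    if varx <= 0:
        return np.nan
    return (sxy - sx * sy / n) / varx


def parent_offspring_h2(parent_osr: np.ndarray, offspring_osr: np.ndarray) -> float:
    """h2 = 2 * slope of offspring OSR on a single parent's OSR.

    Negative values are legitimate estimates and are not clipped.
    Undefined (NaN) when the parent phenotype has zero variance.
    """
    x = np.asarray(parent_osr, dtype=float)
    y = np.asarray(offspring_osr, dtype=float)
    if len(x) != len(y):
        raise ValueError("parent and offspring arrays must align")
    stats_row = np.array(
        [len(x), x.sum(), y.sum(), (x * x).sum(), (x * y).sum()]
    )
    return 2.0 * _slope_from_stats(stats_row)


def evolve(config: EvolutionConfig) -> EvolutionTrajectory:
    """Run the directional simulation; deterministic given the seed.

    Extinction of either sex flags and truncates the trajectory rather
    than raising.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    pop_size = config.pop_size
    n_fam = max(pop_size // 2, 1)

    g = np.full(pop_size, config.initial_propensity, dtype=float)
    if config.initial_propensity_sd > 0:
        g = g + rng.normal(0.0, config.initial_propensity_sd, pop_size)
        g = np.clip(g, 0.0, 1.0)
    sex = rng.random(pop_size) < np.clip(g, 0.0, 1.0)
    # force both sexes at initialization
    if not sex.any():
        sex[0] = True
    if sex.all():
        sex[0] = False

    n_gen = config.n_generations
    mean_propensity = np.full(n_gen, np.nan)
    male_fraction = np.full(n_gen, np.nan)
    realized_osr = np.full(n_gen, np.nan)
    h2_estimate = np.full(n_gen, np.nan)
    reg_stats = np.zeros((n_gen, 5))
    children_produced = np.zeros(n_gen, dtype=np.int64)
    paternal_sum = np.zeros(n_gen, dtype=np.int64)
    maternal_sum = np.zeros(n_gen, dtype=np.int64)
    extinct = False
    extinct_at: int | None = None

    prev_osr: np.ndarray | None = None  # parent-generation OSR phenotypes
    father_of: np.ndarray | None = None  # current individuals -> prev index
    mother_of: np.ndarray | None = None

    for t in range(n_gen):
        males = np.flatnonzero(sex)
        females = np.flatnonzero(~sex)
        mean_propensity[t] = g.mean()
        male_fraction[t] = sex.mean()
        if len(males) == 0 or len(females) == 0:
            extinct = True
            extinct_at = t
            break

        mothers = rng.choice(females, size=n_fam, replace=True)
        fathers = rng.choice(males, size=n_fam, replace=True)
        midparent = 0.5 * (g[mothers] + g[fathers])
        if config.sex_determination == "father":
            family_sex_prob = np.clip(g[fathers], 0.0, 1.0)
        else:  # midparent; "offspring" resolved per child below
            family_sex_prob = np.clip(midparent, 0.0, 1.0)

        child_g: list[np.ndarray] = []
        child_sex: list[np.ndarray] = []
        child_fam: list[np.ndarray] = []
        remaining = np.full(n_fam, config.family_budget)
        active = np.arange(n_fam)
        while len(active):
            k = len(active)
            cg = midparent[active]
            if config.segregation_sd > 0:
                cg = cg + rng.normal(0.0, config.segregation_sd, k)
            if config.mutation_rate > 0 and config.mutation_size > 0:
                mut = rng.random(k) < config.mutation_rate
                sign = rng.integers(0, 2, k) * 2 - 1
                cg = cg + mut * sign * config.mutation_size
            cg = np.clip(cg, 0.0, 1.0)
            if config.sex_determination == "offspring":
                cs = rng.random(k) < cg
            else:
                cs = rng.random(k) < family_sex_prob[active]
            cost = np.where(cs, config.cost_son, config.cost_daughter)
            # fractional boundary: a child costing more than the budget
            # left is realized with probability remaining/cost, keeping
            # the expected marginal cost of each sex exact
            pay = np.minimum(cost, remaining[active])
            partial = pay < cost
            produce = ~partial | (rng.random(k) < pay / cost)
            child_g.append(cg[produce])
            child_sex.append(cs[produce])
            child_fam.append(active[produce])
            remaining[active] -= np.where(partial, remaining[active], cost)
            active = active[remaining[active] > 1e-12]

        cg = np.concatenate(child_g)
        cs = np.concatenate(child_sex)
        cf = np.concatenate(child_fam)
        n_children = len(cg)
        realized_osr[t] = cs.mean()

        # per-parent OSR phenotypes of the current generation; paternal
        # and maternal ledgers kept separate so the one-father-one-mother
        # bookkeeping (the frequency-dependence accounting) is checkable
        paternal_off = np.zeros(pop_size, dtype=np.int64)
        maternal_off = np.zeros(pop_size, dtype=np.int64)
        n_sons = np.zeros(pop_size, dtype=np.int64)
        fam_children = np.bincount(cf, minlength=n_fam)
        fam_sons = np.bincount(cf, weights=cs, minlength=n_fam).astype(np.int64)
        np.add.at(maternal_off, mothers, fam_children)
        np.add.at(n_sons, mothers, fam_sons)
        np.add.at(paternal_off, fathers, fam_children)
        np.add.at(n_sons, fathers, fam_sons)
        n_off = paternal_off + maternal_off
        children_produced[t] = n_children
        paternal_sum[t] = paternal_off[sex].sum()
        maternal_sum[t] = maternal_off[~sex].sum()
        with np.errstate(invalid="ignore", divide="ignore"):
            cur_osr = np.where(n_off > 0, n_sons / np.maximum(n_off, 1), np.nan)

        # parent-offspring regression: this generation's phenotypes on
        # the previous generation's (both parent links pooled)
        if prev_osr is not None:
            has_pheno = n_off > 0
            xs, ys = [], []
            for parent_idx in (father_of, mother_of):
                px = prev_osr[parent_idx]
                ok = has_pheno & np.isfinite(px)
                xs.append(px[ok])
                ys.append(cur_osr[ok])
            x = np.concatenate(xs)
            y = np.concatenate(ys)
            reg_stats[t] = [len(x), x.sum(), y.sum(), (x * x).sum(), (x * y).sum()]
            h2_estimate[t] = 2.0 * _slope_from_stats(reg_stats[t])

        # regulate to pop_size
        if n_children > pop_size:
            keep = rng.choice(n_children, size=pop_size, replace=False)
        else:
            keep = np.arange(n_children)
        prev_osr = cur_osr
        father_of = fathers[cf[keep]]
        mother_of = mothers[cf[keep]]
        g = cg[keep]
        sex = cs[keep]
        pop_size_next = len(g)
        if pop_size_next < 2:
            extinct = True
            extinct_at = t
            break
        pop_size = pop_size_next

    if extinct:
        end = extinct_at + 1 if extinct_at is not None else n_gen
        return EvolutionTrajectory(
            config=config,
            mean_propensity=mean_propensity[:end],
            male_fraction=male_fraction[:end],
            realized_osr=realized_osr[:end],
            h2_estimate=h2_estimate[:end],
            regression_stats=reg_stats[:end],
            children_produced=children_produced[:end],
            paternal_offspring_sum=paternal_sum[:end],
            maternal_offspring_sum=maternal_sum[:end],
            extinct=True,
            extinct_generation=extinct_at,
        )
    return EvolutionTrajectory(
        config=config,
        mean_propensity=mean_propensity,
        male_fraction=male_fraction,
        realized_osr=realized_osr,
        h2_estimate=h2_estimate,
        regression_stats=reg_stats,
        children_produced=children_produced,
        paternal_offspring_sum=paternal_sum,
        maternal_offspring_sum=maternal_sum,
    )


def realized_osr_heritability(
    trajectory: EvolutionTrajectory, window_frac: float = 0.1
) -> tuple[float, float]:
    """Mean realized-OSR heritability over the final window.

    Averages the per-generation parent-offspring estimates over the last
    ``window_frac`` of recorded generations; the second return value is
    the Monte-Carlo standard error (SD of per-generation estimates over
    the window / sqrt(window length)).  NaN if no generation in the
    window has a defined estimate.
    """
    n = trajectory.n_recorded
    start = max(int(np.floor(n * (1 - window_frac))), 1)
    vals = trajectory.h2_estimate[start:]
    vals = vals[np.isfinite(vals)]
    if len(vals) == 0:
        return np.nan, np.nan
    se = float(np.std(vals, ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else np.nan
    return float(np.mean(vals)), se


@dataclass(frozen=True)
class ClassificationConfig:
    """Fig-2-style classification of an evolution condition."""

    h2_ci_low: float = DEFAULT_H2_CI[0]
    h2_ci_high: float = DEFAULT_H2_CI[1]
    optimum: float = 2.0 / 3.0
    white_band: float = 0.05
    window_frac: float = 0.1

    def validate(self) -> None:
        if self.h2_ci_low > self.h2_ci_high:
            raise ValueError("h2 CI bounds out of order")
        if self.optimum == 0.5:
            raise ValueError("optimum must differ from the 0.5 start")


@dataclass(frozen=True)
class Classification:
    progress: float
    mean_h2: float
    colour: str  # red | white | green
    within_ci: bool
    asterisk: bool
    reason: str = ""


def classify_values(
    progress: float, mean_h2: float, cfg: ClassificationConfig, reason: str = ""
) -> Classification:
    """Apply the colour / CI / asterisk rules to summary values.

    Colour: red below halfway to the optimum, white within the halfway
    band, green beyond it.  ``within_ci`` holds when the mean realized
    heritability falls inside the empirical CI.  The asterisk marks
    conditions with at-least-halfway evolution AND heritability within
    the CI.
    """
    cfg.validate()
    if not np.isfinite(progress):
        return Classification(np.nan, mean_h2, "red", False, False, reason or "undefined")
    if abs(progress - 0.5) <= cfg.white_band:
        colour = "white"
    elif progress < 0.5:
        colour = "red"
    else:
        colour = "green"
    within = bool(
        np.isfinite(mean_h2) and cfg.h2_ci_low <= mean_h2 <= cfg.h2_ci_high
    )
    asterisk = within and progress >= 0.5 - cfg.white_band
    return Classification(progress, mean_h2, colour, within, asterisk, reason)


def trajectory_progress(
    trajectory: EvolutionTrajectory, cfg: ClassificationConfig
) -> float:
    """Progress toward the optimum: (final OSR - 0.5) / (optimum - 0.5).

    The final OSR is the mean realized OSR over the classification
    window (a colour-scale midpoint, not a single-generation snapshot).
    """
    n = trajectory.n_recorded
    start = max(int(np.floor(n * (1 - cfg.window_frac))), 0)
    window = trajectory.realized_osr[start:]
    window = window[np.isfinite(window)]
    if len(window) == 0:
        return np.nan
    return (float(np.mean(window)) - 0.5) / (cfg.optimum - 0.5)


def classify_condition(
    trajectory: EvolutionTrajectory, cfg: ClassificationConfig
) -> Classification:
    """Classify one trajectory; extinct runs are red with a reason code."""
    cfg.validate()
    mean_h2, _ = realized_osr_heritability(trajectory, cfg.window_frac)
    if trajectory.extinct:
        within = bool(
            np.isfinite(mean_h2) and cfg.h2_ci_low <= mean_h2 <= cfg.h2_ci_high
        )
        return Classification(
            progress=np.nan,
            mean_h2=mean_h2,
            colour="red",
            within_ci=within,
            asterisk=False,
            reason="extinct",
        )
    progress = trajectory_progress(trajectory, cfg)
    return classify_values(progress, mean_h2, cfg)


def run_condition_grid(
    mutation_rates,
    mutation_sizes,
    reps: int,
    template: EvolutionConfig,
    cfg: ClassificationConfig | None = None,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Classify every (mutation rate, mutation size) condition.

    Per cell, ``reps`` independent trajectories are run with seeds
    derived from ``SeedSequence(base_seed, spawn_key=(cell, rep))``
    (order-invariant); progress and window heritability are averaged
    over replicates before classification.
    """
    if len(mutation_rates) == 0 or len(mutation_sizes) == 0:
        raise ValueError("grid axes must be non-empty")
    if cfg is None:
        cfg = ClassificationConfig(
            optimum=fisher_optimum(template.cost_son, template.cost_daughter)
        )
    rows = []
    for cell, (rate, size) in enumerate(product(mutation_rates, mutation_sizes)):
        progresses, h2s = [], []
        any_extinct = False
        for rep in range(reps):
            ss = np.random.SeedSequence(base_seed, spawn_key=(cell, rep))
            seed = int(ss.generate_state(1)[0] % (2**31 - 1))
            traj = evolve(
                replace(template, mutation_rate=rate, mutation_size=size, seed=seed)
            )
            if traj.extinct:
                any_extinct = True
            progresses.append(trajectory_progress(traj, cfg))
            h2s.append(realized_osr_heritability(traj, cfg.window_frac)[0])
        mean_progress = float(np.nanmean(progresses)) if progresses else np.nan
        mean_h2 = float(np.nanmean(h2s)) if h2s else np.nan
        cls = classify_values(
            mean_progress, mean_h2, cfg, reason="extinct" if any_extinct else ""
        )
        rows.append(
            {
                "mutation_rate": rate,
                "mutation_size": size,
                "mean_progress": mean_progress,
                "mean_h2": mean_h2,
                "colour": cls.colour,
                "within_ci": cls.within_ci,
                "asterisk": cls.asterisk,
                "n_replicates": reps,
                "any_extinct": any_extinct,
            }
        )
    return pd.DataFrame(rows)
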