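"""Familial-aggregation inference for binary offspring sex.

The analysis regresses one cousin's sex on the other cousin's sex by
logistic regression with an independence working correlation, so the
point estimate is the ordinary logistic MLE; standard errors come from
the cluster-robust sandwich (bread = total Fisher information, meat =
sum over extended-family clusters of outer products of cluster-summed
scores).  With a single binary covariate the MLE is available in closed
form from the 2x2 table, which is what lets the paper-scale designs
(millions of rows) be fitted exactly in vectorized form.

Also provided: maximum-likelihood tetrachoric correlation for 2x2
tables (bivariate-normal threshold model, thresholds fixed at the
margins' normal quantiles) and the liability-scale heritability read
off from a relative-pair tetrachoric correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "COUSIN_PAIR_COLUMNS",
    "AssociationResult",
    "TetrachoricResult",
    "HeritabilityEstimate",
    "build_cousin_pairs",
    "fit_clustered_logistic",
    "fit_2x2_independent",
    "tetrachoric_correlation",
    "heritability_from_tetrachoric",
]

COUSIN_PAIR_COLUMNS = ["outcome_sex", "covariate_sex", "cluster_id"]


@dataclass(frozen=True)
class AssociationResult:
    """One clustered logistic fit of outcome sex on cousin's sex."""

    log_odds: float
    robust_se: float
    z: float
    p: float
    n_rows: int
    n_clusters: int
    separated: bool = False


@dataclass(frozen=True)
class TetrachoricResult:
    r: float
    threshold_1: float
    threshold_2: float
    se: float
    boundary: bool = False


@dataclass(frozen=True)
class HeritabilityEstimate:
    h2: float
    ci_low: float | None
    ci_high: float | None
    out_of_range: bool


# ---------------------------------------------------------------------------
# cousin-pair construction
# ---------------------------------------------------------------------------

def _offspring_by_sibling(pedigree: pd.DataFrame):
    """Per family, offspring sex arrays for sibling 1 and sibling 2."""
    if pedigree["offspring_sex"].isna().any():
        raise ValueError("all offspring sexes must be realized before pairing")
    frame = pedigree.sort_values(["family_id", "sibling_index", "offspring_id"])
    fam = frame["family_id"].to_numpy()
    sib = frame["sibling_index"].to_numpy()
    sex = frame["offspring_sex"].to_numpy(dtype=np.int64)
    return fam, sib, sex


def build_cousin_pairs(
    pedigree: pd.DataFrame, pairing_rule: str = "all_cross_pairs"
) -> pd.DataFrame:
    """Emit the cousin-pair analysis table.

    ``all_cross_pairs``: for each family, every offspring of sibling 1
    crossed with every offspring of sibling 2, in both orderings
    (outcome/covariate swapped), clustered on the family so the sandwich
    absorbs the induced dependence.  ``one_per_family``: a single row per
    family using the first offspring of each parent (the one-offspring-
    per-father lower-bound design).  Families where a parent has no
    offspring contribute no rows.
    """
    if pairing_rule not in ("all_cross_pairs", "one_per_family"):
        raise ValueError(f"unknown pairing_rule {pairing_rule!r}")
    fam, sib, sex = _offspring_by_sibling(pedigree)

    # first/last index of each (family, sibling) run
    fam_ids, fam_start = np.unique(fam, return_index=True)
    n_off_1 = np.zeros(len(fam_ids), dtype=np.int64)
    n_off_2 = np.zeros(len(fam_ids), dtype=np.int64)
    fam_code = np.searchsorted(fam_ids, fam)
    np.add.at(n_off_1, fam_code[sib == 1], 1)
    np.add.at(n_off_2, fam_code[sib == 2], 1)

    # offspring sexes grouped per family and sibling (ragged via offsets)
    sex1 = sex[sib == 1]
    sex2 = sex[sib == 2]
    off1 = np.concatenate([[0], np.cumsum(n_off_1)])
    off2 = np.concatenate([[0], np.cumsum(n_off_2)])

    if pairing_rule == "one_per_family":
        keep = (n_off_1 > 0) & (n_off_2 > 0)
        outcome = sex1[off1[:-1][keep]]
        covariate = sex2[off2[:-1][keep]]
        cluster = fam_ids[keep]
        return pd.DataFrame(
            {
                "outcome_sex": outcome,
                "covariate_sex": covariate,
                "cluster_id": cluster,
            }
        )

    n_pairs = n_off_1 * n_off_2
    total = int(n_pairs.sum())
    if total == 0:
        return pd.DataFrame(
            {
                "outcome_sex": np.array([], dtype=np.int64),
                "covariate_sex": np.array([], dtype=np.int64),
                "cluster_id": np.array([], dtype=fam_ids.dtype),
            }
        )
    pair_fam = np.repeat(np.arange(len(fam_ids)), n_pairs)
    pair_offset = np.concatenate([[0], np.cumsum(n_pairs)])
    rank = np.arange(total) - pair_offset[pair_fam]
    idx1 = off1[pair_fam] + rank // np.maximum(n_off_2[pair_fam], 1)
    idx2 = off2[pair_fam] + rank % np.maximum(n_off_2[pair_fam], 1)
    y1 = sex1[idx1]
    y2 = sex2[idx2]
    cluster = fam_ids[pair_fam]
    return pd.DataFrame(
        {
            "outcome_sex": np.concatenate([y1, y2]),
            "covariate_sex": np.concatenate([y2, y1]),
            "cluster_id": np.concatenate([cluster, cluster]),
        }
    )


# ---------------------------------------------------------------------------
# clustered logistic regression (closed-form MLE + sandwich)
# ---------------------------------------------------------------------------

def _sandwich_from_cells_and_scores(
    a: float, b: float, c: float, d: float, s1: np.ndarray, s2: np.ndarray
):
    """Assemble log-odds, robust SE from 2x2 cells and cluster score sums.

    a, b, c, d are total counts of (y=1,x=1), (y=1,x=0), (y=0,x=1),
    (y=0,x=0); s1/s2 are per-cluster sums of the intercept and slope
    score contributions evaluated at the MLE.
    """
    p1 = a / (a + c)
    p0 = b / (b + d)
    log_odds = np.log(p1 / (1 - p1)) - np.log(p0 / (1 - p0))
    w1 = (a + c) * p1 * (1 - p1)
    w0 = (b + d) * p0 * (1 - p0)
    bread = np.array([[w1 + w0, w1], [w1, w1]])
    meat = np.array(
        [
            [np.dot(s1, s1), np.dot(s1, s2)],
            [np.dot(s1, s2), np.dot(s2, s2)],
        ]
    )
    bread_inv = np.linalg.inv(bread)
    cov = bread_inv @ meat @ bread_inv
    robust_se = float(np.sqrt(cov[1, 1]))
    return float(log_odds), robust_se, float(p1), float(p0)


def fit_from_family_cells(
    a_f: np.ndarray, b_f: np.ndarray, c_f: np.ndarray, d_f: np.ndarray
) -> AssociationResult:
    """Clustered fit from per-cluster 2x2 cell counts.

    Algebraically identical to :func:`fit_clustered_logistic` on the
    expanded row table with one cluster per input position — scores of
    rows in the same (y, x) cell coincide, so per-cluster cell counts
    are sufficient for the sandwich.  This is the vectorized path used
    for paper-scale designs.
    """
    a, b = float(a_f.sum()), float(b_f.sum())
    c, d = float(c_f.sum()), float(d_f.sum())
    n_rows = int(a + b + c + d)
    n_clusters = int(len(a_f))
    if n_clusters < 2:
        raise ValueError("cluster-robust sandwich requires >= 2 clusters")
    if min(a, b, c, d) == 0:
        sign = 1.0 if (a * d) > (b * c) or (b == 0 or c == 0) else -1.0
        return AssociationResult(
            log_odds=sign * np.inf,
            robust_se=np.nan,
            z=np.nan,
            p=np.nan,
            n_rows=n_rows,
            n_clusters=n_clusters,
            separated=True,
        )
    p1 = a / (a + c)
    p0 = b / (b + d)
    s1 = (
        a_f * (1 - p1) + b_f * (1 - p0) - c_f * p1 - d_f * p0
    )
    s2 = a_f * (1 - p1) - c_f * p1
    log_odds, robust_se, _, _ = _sandwich_from_cells_and_scores(a, b, c, d, s1, s2)
    z = log_odds / robust_se
    p = float(2 * stats.norm.sf(abs(z)))
    return AssociationResult(
        log_odds=log_odds,
        robust_se=robust_se,
        z=float(z),
        p=max(p, np.finfo(float).tiny),
        n_rows=n_rows,
        n_clusters=n_clusters,
    )


def fit_clustered_logistic(table: pd.DataFrame) -> AssociationResult:
    """Logistic regression of outcome on intercept + cousin's sex.

    Point estimate is the ordinary logistic MLE (independence working
    correlation); ``robust_se`` is the cluster sandwich.  Separation (a
    zero cell in the implied 2x2) yields a flagged result with infinite
    estimate rather than an exception.
    """
    y = table["outcome_sex"].to_numpy(dtype=np.int64)
    x = table["covariate_sex"].to_numpy(dtype=np.int64)
    if not (np.isin(y, (0, 1)).all() and np.isin(x, (0, 1)).all()):
        raise ValueError("outcome_sex and covariate_sex must be binary")
    if len(np.unique(x)) < 2 or len(np.unique(y)) < 2:
        raise ValueError("both outcome and covariate values must be present")
    cluster, cluster_code = np.unique(table["cluster_id"].to_numpy(), return_inverse=True)
    n_clusters = len(cluster)

    cell = 2 * y + x  # 3:(1,1)=a 2:(1,0)=b 1:(0,1)=c 0:(0,0)=d
    counts = np.zeros((n_clusters, 4), dtype=np.int64)
    np.add.at(counts, (cluster_code, cell), 1)
    return fit_from_family_cells(
        counts[:, 3].astype(float),
        counts[:, 2].astype(float),
        counts[:, 1].astype(float),
        counts[:, 0].astype(float),
    )


def fit_2x2_independent(a: float, b: float, c: float, d: float) -> AssociationResult:
    """Fit for independent pairs (every row its own cluster).

    For singleton clusters the sandwich reduces exactly to the
    heteroskedasticity-robust form, which for the saturated one-binary-
    covariate model equals the classic log-odds-ratio standard error
    sqrt(1/a + 1/b + 1/c + 1/d).
    """
    n_rows = int(a + b + c + d)
    if min(a, b, c, d) == 0:
        return AssociationResult(
            log_odds=np.inf if (b == 0 or c == 0) else -np.inf,
            robust_se=np.nan,
            z=np.nan,
            p=np.nan,
            n_rows=n_rows,
            n_clusters=n_rows,
            separated=True,
        )
    log_odds = float(np.log(a * d / (b * c)))
    robust_se = float(np.sqrt(1 / a + 1 / b + 1 / c + 1 / d))
    z = log_odds / robust_se
    p = float(2 * stats.norm.sf(abs(z)))
    return AssociationResult(
        log_odds=log_odds,
        robust_se=robust_se,
        z=float(z),
        p=max(p, np.finfo(float).tiny),
        n_rows=n_rows,
        n_clusters=n_rows,
    )


# ---------------------------------------------------------------------------
# tetrachoric correlation and liability heritability
# ---------------------------------------------------------------------------

def _bvn_upper(tau1: float, tau2: float, r: float) -> float:
    """P(Z1 > tau1, Z2 > tau2) for standard bivariate normal, corr r."""
    cov = np.array([[1.0, r], [r, 1.0]])
    return float(
        stats.multivariate_normal(mean=[0.0, 0.0], cov=cov, allow_singular=True).cdf(
            [-tau1, -tau2]
        )
    )


def tetrachoric_correlation(counts) -> TetrachoricResult:
    """ML tetrachoric correlation of a 2x2 table.

    ``counts`` is [[n11, n10], [n01, n00]] with index order (first
    variable, second variable), 1 meaning the latent normal exceeded its
    threshold.  Thresholds are fixed at the margins' normal quantiles;
    r maximizes the multinomial likelihood of the quadrant
    probabilities.  A zero margin is an error; a zero cell puts r on the
    boundary and is flagged.
    """
    table = np.asarray(counts, dtype=float)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("counts must be a non-negative 2x2 table")
    n = table.sum()
    p1 = (table[0, 0] + table[0, 1]) / n
    p2 = (table[0, 0] + table[1, 0]) / n
    if p1 in (0.0, 1.0) or p2 in (0.0, 1.0):
        raise ValueError("a zero margin leaves a threshold undefined")
    tau1 = float(stats.norm.ppf(1 - p1))
    tau2 = float(stats.norm.ppf(1 - p2))

    if (table == 0).any():
        concordant = table[0, 1] == 0 or table[1, 0] == 0
        r = 1.0 if concordant else -1.0
        return TetrachoricResult(r, tau1, tau2, np.nan, boundary=True)

    def neg_loglik(r: float) -> float:
        p11 = _bvn_upper(tau1, tau2, r)
        p10 = p1 - p11
        p01 = p2 - p11
        p00 = 1.0 - p1 - p01
        probs = np.array([p11, p10, p01, p00])
        if (probs <= 0).any():
            return np.inf
        return -float(np.sum(table.ravel() * np.log(probs)))

    res = optimize.minimize_scalar(
        neg_loglik, bounds=(-0.999999, 0.999999), method="bounded",
        options={"xatol": 1e-10},
    )
    r_hat = float(res.x)
    # asymptotic SE from the observed information (numeric curvature)
    h = 1e-4
    if abs(r_hat) > 0.999:
        se = np.nan
    else:
        curv = (
            neg_loglik(r_hat + h) - 2 * neg_loglik(r_hat) + neg_loglik(r_hat - h)
        ) / h**2
        se = float(1.0 / np.sqrt(curv)) if curv > 0 else np.nan
    return TetrachoricResult(r_hat, tau1, tau2, se)


def heritability_from_tetrachoric(
    r: float,
    parent_relatedness: float = 0.5,
    ci: tuple[float, float] | None = None,
) -> HeritabilityEstimate:
    """Liability-scale heritability: h2 = r / relatedness.

    The confidence interval, if given on the tetrachoric scale, is
    transformed by the same linear scaling.  Estimates outside [0, 1]
    are reported as-is and flagged (family designs legitimately produce
    slightly negative interval bounds around a zero heritability).
    """
    if not 0 < parent_relatedness <= 1:
        raise ValueError("parent_relatedness must lie in (0, 1]")
    h2 = r / parent_relatedness
    lo = hi = None
    if ci is not None:
        lo, hi = (ci[0] / parent_relatedness, ci[1] / parent_relatedness)
    return HeritabilityEstimate(
        h2=h2, ci_low=lo, ci_high=hi, out_of_range=not 0 <= h2 <= 1
    )
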