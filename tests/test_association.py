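"""Cousin-pair tables, clustered logistic sandwich, tetrachoric."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from osrsim.association import (
    build_cousin_pairs,
    fit_2x2_independent,
    fit_clustered_logistic,
    fit_from_family_cells,
    heritability_from_tetrachoric,
    tetrachoric_correlation,
)


def _random_table(rng, n_rows=500, n_clusters=100):
    return pd.DataFrame(
        {
            "outcome_sex": rng.integers(0, 2, n_rows),
            "covariate_sex": rng.integers(0, 2, n_rows),
            "cluster_id": rng.integers(0, n_clusters, n_rows),
        }
    )


def brute_force_sandwich(table: pd.DataFrame):
    """Textbook logistic MLE + cluster sandwich, assembled per observation.

    Independent of the closed-form implementation: Newton iterations on
    the full likelihood, scores accumulated row by row in Python.
    """
    y = table["outcome_sex"].to_numpy(float)
    x = np.column_stack(
        [np.ones(len(table)), table["covariate_sex"].to_numpy(float)]
    )
    beta = np.zeros(2)
    for _ in range(60):
        eta = x @ beta
        mu = 1 / (1 + np.exp(-eta))
        w = mu * (1 - mu)
        grad = x.T @ (y - mu)
        hess = x.T @ (x * w[:, None])
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.abs(step).max() < 1e-13:
            break
    eta = x @ beta
    mu = 1 / (1 + np.exp(-eta))
    bread = x.T @ (x * (mu * (1 - mu))[:, None])
    scores = x * (y - mu)[:, None]
    meat = np.zeros((2, 2))
    for _, idx in table.groupby("cluster_id").indices.items():
        s = scores[idx].sum(axis=0)
        meat += np.outer(s, s)
    cov = np.linalg.inv(bread) @ meat @ np.linalg.inv(bread)
    return beta[1], np.sqrt(cov[1, 1])


class TestBuildCousinPairs:
    def test_cross_pair_counts(self, small_pedigree):
        table = build_cousin_pairs(small_pedigree, "all_cross_pairs")
        # (2*3 + 1*1) unordered pairs, both orderings
        assert len(table) == 14
        one = build_cousin_pairs(small_pedigree, "one_per_family")
        assert len(one) == 2

    def test_both_orderings_present(self, small_pedigree):
        table = build_cousin_pairs(small_pedigree, "all_cross_pairs")
        fam0 = table[table.cluster_id == 0]
        # symmetric: swapping outcome/covariate leaves the multiset intact
        fwd = sorted(zip(fam0.outcome_sex, fam0.covariate_sex))
        rev = sorted(zip(fam0.covariate_sex, fam0.outcome_sex))
        assert fwd == rev

    def test_zero_offspring_parent_skipped(self, small_pedigree):
        no_side2 = small_pedigree[
            ~((small_pedigree.family_id == 1) & (small_pedigree.sibling_index == 2))
        ]
        table = build_cousin_pairs(no_side2, "all_cross_pairs")
        assert set(table.cluster_id) == {0}

    def test_unrealized_sexes_rejected(self, small_pedigree):
        ped = small_pedigree.copy()
        ped.loc[0, "offspring_sex"] = pd.NA
        with pytest.raises(ValueError, match="realized"):
            build_cousin_pairs(ped)

    def test_unknown_rule(self, small_pedigree):
        with pytest.raises(ValueError):
            build_cousin_pairs(small_pedigree, "every_other")


class TestClusteredLogistic:
    def test_closed_form_2x2(self):
        """a=30 b=20 c=20 d=30 singleton clusters -> log odds ln(2.25)."""
        rows = (
            [(1, 1)] * 30 + [(1, 0)] * 20 + [(0, 1)] * 20 + [(0, 0)] * 30
        )
        table = pd.DataFrame(rows, columns=["outcome_sex", "covariate_sex"])
        table["cluster_id"] = np.arange(len(table))
        res = fit_clustered_logistic(table)
        assert res.log_odds == pytest.approx(np.log(2.25), abs=1e-12)
        assert res.robust_se == pytest.approx(
            np.sqrt(1 / 30 + 1 / 20 + 1 / 20 + 1 / 30), abs=1e-12
        )

    def test_row_duplication_invariance(self, rng):
        table = _random_table(rng)
        doubled = pd.concat([table, table], ignore_index=True)
        a = fit_clustered_logistic(table)
        b = fit_clustered_logistic(doubled)
        assert b.log_odds == pytest.approx(a.log_odds, abs=1e-12)
        assert b.robust_se == pytest.approx(a.robust_se, abs=1e-12)

    def test_matches_brute_force_sandwich(self, rng):
        """100 random tables agree with the per-observation oracle."""
        for _ in range(100):
            table = _random_table(
                rng,
                n_rows=int(rng.integers(60, 400)),
                n_clusters=int(rng.integers(10, 80)),
            )
            mine = fit_clustered_logistic(table)
            slope, se = brute_force_sandwich(table)
            assert mine.log_odds == pytest.approx(slope, rel=1e-10)
            assert mine.robust_se == pytest.approx(se, rel=1e-10)

    def test_matches_statsmodels_gee(self, rng):
        import statsmodels.api as sm

        table = _random_table(rng, 800, 150)
        mine = fit_clustered_logistic(table)
        gee = sm.GEE(
            table["outcome_sex"],
            sm.add_constant(table["covariate_sex"].to_numpy()),
            groups=table["cluster_id"],
            family=sm.families.Binomial(),
        ).fit()
        assert mine.log_odds == pytest.approx(float(gee.params.iloc[1]), rel=1e-8)
        assert mine.robust_se == pytest.approx(float(gee.bse.iloc[1]), rel=1e-8)

    def test_singleton_clusters_equal_hc0(self, rng):
        import statsmodels.api as sm

        table = _random_table(rng, 300, n_clusters=300)
        table["cluster_id"] = np.arange(len(table))
        mine = fit_clustered_logistic(table)
        logit = sm.Logit(
            table["outcome_sex"], sm.add_constant(table["covariate_sex"].to_numpy())
        ).fit(disp=0, cov_type="HC0")
        assert mine.robust_se == pytest.approx(float(logit.bse.iloc[1]), rel=1e-8)

    def test_separation_flagged_not_raised(self):
        table = pd.DataFrame(
            {
                "outcome_sex": [1, 1, 0, 0],
                "covariate_sex": [1, 1, 0, 1],
                "cluster_id": [0, 1, 2, 3],
            }
        )  # no (y=1, x=0) cell
        res = fit_clustered_logistic(table)
        assert res.separated
        assert np.isinf(res.log_odds)

    def test_single_cluster_errors(self):
        table = pd.DataFrame(
            {
                "outcome_sex": [1, 0, 1, 0],
                "covariate_sex": [1, 0, 0, 1],
                "cluster_id": [7, 7, 7, 7],
            }
        )
        with pytest.raises(ValueError, match="clusters"):
            fit_clustered_logistic(table)

    def test_aggregated_cells_equal_row_fit(self, rng):
        table = _random_table(rng, 600, 80)
        cell = 2 * table["outcome_sex"].to_numpy() + table["covariate_sex"].to_numpy()
        counts = np.zeros((80, 4))
        code = table["cluster_id"].to_numpy()
        np.add.at(counts, (code, cell), 1)
        agg = fit_from_family_cells(
            counts[:, 3], counts[:, 2], counts[:, 1], counts[:, 0]
        )
        row = fit_clustered_logistic(table)
        assert agg.log_odds == pytest.approx(row.log_odds, abs=0)
        assert agg.robust_se == pytest.approx(row.robust_se, abs=0)

    def test_2x2_fast_path_equals_singleton_cluster_fit(self):
        a, b, c, d = 37.0, 21.0, 14.0, 52.0
        fast = fit_2x2_independent(a, b, c, d)
        rows = (
            [(1, 1)] * int(a) + [(1, 0)] * int(b) + [(0, 1)] * int(c) + [(0, 0)] * int(d)
        )
        table = pd.DataFrame(rows, columns=["outcome_sex", "covariate_sex"])
        table["cluster_id"] = np.arange(len(table))
        slow = fit_clustered_logistic(table)
        assert fast.log_odds == pytest.approx(slow.log_odds, abs=1e-12)
        assert fast.robust_se == pytest.approx(slow.robust_se, abs=1e-12)


class TestTetrachoric:
    def test_independence_gives_zero(self):
        res = tetrachoric_correlation([[25, 25], [25, 25]])
        assert res.r == pytest.approx(0.0, abs=1e-6)
        assert res.threshold_1 == pytest.approx(0.0, abs=1e-12)

    @given(
        n11=st.integers(26, 49),
        total=st.just(100),
    )
    def test_symmetric_margin_arcsine_identity(self, n11, total):
        """Zero-threshold tables satisfy r = sin(2*pi*(P11 - 1/4))."""
        off = (total - 2 * n11) // 2
        res = tetrachoric_correlation([[n11, off], [off, n11]])
        expected = np.sin(2 * np.pi * (n11 / total - 0.25))
        assert res.r == pytest.approx(expected, abs=1e-6)

    def test_perfect_concordance_boundary(self):
        res = tetrachoric_correlation([[50, 0], [0, 50]])
        assert res.boundary and res.r == 1.0

    def test_zero_margin_raises(self):
        with pytest.raises(ValueError, match="margin"):
            tetrachoric_correlation([[0, 0], [10, 90]])

    def test_parameter_recovery_within_3_se(self):
        """Dichotomized bivariate-normal samples recover r at n=1e5."""
        rng = np.random.default_rng(42)
        true_r, tau1, tau2 = 0.35, 0.2, -0.4
        n = 100_000
        z = rng.multivariate_normal(
            [0, 0], [[1, true_r], [true_r, 1]], size=n
        )
        x = z[:, 0] > tau1
        y = z[:, 1] > tau2
        counts = [
            [int((x & y).sum()), int((x & ~y).sum())],
            [int((~x & y).sum()), int((~x & ~y).sum())],
        ]
        res = tetrachoric_correlation(counts)
        assert abs(res.r - true_r) < 3 * res.se
        assert res.se < 0.02


class TestHeritabilityFromTetrachoric:
    @pytest.mark.parametrize(
        "r,relatedness,expected",
        [(0.0, 0.5, 0.0), (0.25, 0.5, 0.5), (0.1, 0.25, 0.4)],
    )
    def test_linear_scaling(self, r, relatedness, expected):
        est = heritability_from_tetrachoric(r, relatedness)
        assert est.h2 == pytest.approx(expected)
        assert not est.out_of_range or expected > 1

    def test_negative_flagged_not_clipped(self):
        est = heritability_from_tetrachoric(
            -0.00038, 0.5, ci=(-0.00038, 0.00098)
        )
        assert est.h2 == pytest.approx(-0.00076)
        assert est.out_of_range
        assert est.ci_low == pytest.approx(-0.00076)
        assert est.ci_high == pytest.approx(0.00196)

    def test_invalid_relatedness(self):
        with pytest.raises(ValueError):
            heritability_from_tetrachoric(0.1, 0.0)
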