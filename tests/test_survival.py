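"""Cox screening, permutation p, cross-tabulation, Fisher exact test."""

from itertools import count
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from dosepath import synthetic
from dosepath.survival import (
    cox_univariate,
    cross_tabulate,
    fisher_exact_2x2,
    load_pattern_survival_table,
    permutation_p,
    screen_genes,
    select_survival_genes,
)


def brute_force_fisher(table):
    """Two-sided p by direct enumeration of all same-margin tables."""
    (a, b), (c, d) = table
    n, row1, col1 = a + b + c + d, a + b, a + c

    def prob(k):
        # hypergeometric probability of the table with cell (0,0) = k
        return (
            comb(row1, k) * comb(n - row1, col1 - k) / comb(n, col1)
        )

    lo = max(0, col1 - (n - row1))
    hi = min(row1, col1)
    p_obs = prob(a)
    return sum(prob(k) for k in range(lo, hi + 1) if prob(k) <= p_obs * (1 + 1e-7))


class TestCox:
    def test_constant_covariate_gives_unit_hazard_ratio(self):
        cohort = synthetic.generate_survival(
            None, {}, 0.5, 0.0, 50, seed=1, extra_genes=["X"]
        )
        with pytest.warns(UserWarning):
            beta, hr, p = cox_univariate(
                np.ones(50), cohort["time"], cohort["event"]
            )
        assert (beta, hr, p) == (0.0, 1.0, 1.0)

    def test_parameter_recovery_at_large_n(self):
        cohort = synthetic.generate_survival(
            None, {"G1": np.log(2)}, 0.1, 0.0, 1000, seed=3
        )
        _, hr, _ = cox_univariate(
            cohort["G1"], cohort["time"], cohort["event"], p_method="wald"
        )
        assert 1.8 <= hr <= 2.2

    def test_negating_covariate_negates_beta(self):
        cohort = synthetic.generate_survival(
            None, {"G1": 0.7}, 0.2, 0.1, 200, seed=4
        )
        b1, _, _ = cox_univariate(
            cohort["G1"], cohort["time"], cohort["event"], p_method="wald"
        )
        b2, _, _ = cox_univariate(
            -cohort["G1"], cohort["time"], cohort["event"], p_method="wald"
        )
        assert b2 == pytest.approx(-b1, abs=1e-9)

    def test_matches_lifelines_without_ties(self):
        lifelines = pytest.importorskip("lifelines")
        cohort = synthetic.generate_survival(
            None, {"G1": 0.5}, 0.3, 0.2, 150, seed=5
        )
        x = cohort["G1"].to_numpy()
        x = (x - x.mean()) / x.std()
        beta, _, _ = cox_univariate(
            x, cohort["time"], cohort["event"], p_method="wald",
            standardize=False,
        )
        df = pd.DataFrame({"T": cohort["time"], "E": cohort["event"], "x": x})
        cph = lifelines.CoxPHFitter().fit(df, "T", "E")
        assert beta == pytest.approx(float(cph.params_.iloc[0]), abs=1e-5)

    def test_breslow_likelihood_maximised_with_tied_times(self):
        """Newton solution maximises an independently written Breslow
        partial log-likelihood on data with tied event times."""
        from scipy.optimize import minimize_scalar

        cohort = synthetic.generate_survival(
            None, {"G1": 0.6}, 0.3, 0.2, 120, seed=12
        )
        time = np.round(cohort["time"].to_numpy(), 1) + 0.05
        event = cohort["event"].to_numpy().astype(bool)
        x = cohort["G1"].to_numpy()
        x = (x - x.mean()) / x.std()

        def breslow_negloglik(beta):
            ll = 0.0
            for t in np.unique(time[event]):
                at_t = event & (time == t)
                risk = time >= t
                ll += beta * x[at_t].sum()
                ll -= at_t.sum() * np.log(np.exp(beta * x[risk]).sum())
            return -ll

        oracle = minimize_scalar(
            breslow_negloglik, bounds=(-5, 5), method="bounded",
            options={"xatol": 1e-10},
        ).x
        beta, _, _ = cox_univariate(
            x, time, event, p_method="wald", standardize=False
        )
        assert beta == pytest.approx(oracle, abs=1e-6)

    def test_coefficient_within_three_se_most_of_the_time(self):
        """Planted coefficient recovered within 3 SE in >=95% of datasets."""
        hits = 0
        n_rep = 40
        for seed in range(n_rep):
            cohort = synthetic.generate_survival(
                None, {"G1": 0.5}, 0.2, 0.2, 500, seed=1000 + seed
            )
            x = cohort["G1"].to_numpy()
            x = (x - x.mean()) / x.std()
            from dosepath.survival import _newton_cox, _wald_se

            beta = float(
                _newton_cox(cohort["time"], cohort["event"], x[:, None])[0]
            )
            se = _wald_se(cohort["time"], cohort["event"], x, beta)
            # true coefficient on the standardized scale ~ 0.5 (x ~ N(0,1))
            if abs(beta - 0.5) <= 3 * se:
                hits += 1
        assert hits / n_rep >= 0.95

    def test_too_few_events_rejected(self):
        with pytest.raises(ValueError):
            cox_univariate([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [1, 0, 0])


class TestPermutationP:
    def test_strong_association_is_significant(self):
        cohort = synthetic.generate_survival(
            None, {"G1": 2.0}, 0.1, 0.0, 200, seed=6
        )
        p = permutation_p(
            cohort["G1"], cohort["time"], cohort["event"],
            n_permutations=1000, seed=7,
        )
        assert p <= 0.001

    def test_floor_prevents_zero(self):
        cohort = synthetic.generate_survival(
            None, {"G1": 3.0}, 0.1, 0.0, 300, seed=8
        )
        p = permutation_p(
            cohort["G1"], cohort["time"], cohort["event"],
            n_permutations=200, seed=9,
        )
        assert p >= 1 / 200

    def test_null_p_uniform_across_genes(self):
        cohort = synthetic.generate_survival(
            None, {}, 0.1, 0.2, 130, seed=10,
            extra_genes=[f"G{i}" for i in range(150)],
        )
        table = screen_genes(
            cohort, [f"G{i}" for i in range(150)],
            n_permutations=500, seed=11,
        )
        assert kstest(table["p"], "uniform").pvalue > 0.01


class TestFisher2x2:
    CASES = [
        [[32, 16], [24, 26]],
        [[5, 5], [5, 5]],
        [[10, 0], [0, 10]],
        [[3, 9], [14, 2]],
        [[1, 0], [0, 1]],
        [[0, 7], [8, 0]],
        [[6, 2], [11, 9]],
    ]

    @pytest.mark.parametrize("table", CASES, ids=count())
    def test_matches_exhaustive_enumeration(self, table):
        _, p = fisher_exact_2x2(table)
        assert p == pytest.approx(brute_force_fisher(table), rel=1e-9)

    @pytest.mark.parametrize("table", CASES, ids=count())
    def test_matches_scipy_two_sided(self, table):
        from scipy.stats import fisher_exact

        _, p = fisher_exact_2x2(table)
        assert p == pytest.approx(fisher_exact(table)[1], rel=1e-7)

    def test_balanced_table_p_one(self):
        _, p = fisher_exact_2x2([[5, 5], [5, 5]])
        assert p == pytest.approx(1.0)

    def test_perfect_separation_closed_form(self):
        odds, p = fisher_exact_2x2([[10, 0], [0, 10]])
        assert odds == np.inf
        assert p == pytest.approx(2 / comb(20, 10))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1, -1], [2, 3]])


class TestCrossTabulation:
    def test_packaged_table_counts(self):
        table = load_pattern_survival_table()
        assert len(table) == 98
        selected = select_survival_genes(table, alpha=0.05)
        assert len(selected) == 98
        res = cross_tabulate(table)
        np.testing.assert_array_equal(res.counts, [[32, 16], [24, 26]])
        assert res.odds_ratio == pytest.approx((32 * 26) / (16 * 24))

    def test_alpha_bounds(self):
        table = load_pattern_survival_table()
        assert select_survival_genes(table, alpha=0.0) == set()
        assert len(select_survival_genes(table, alpha=1.0)) == 98

    def test_degenerate_column_gives_infinite_odds(self):
        table = pd.DataFrame(
            {
                "pattern": ["down", "down", "up", "up"],
                "p": [0.01] * 4,
                "hazard_ratio": [1.5, 1.2, 2.0, 3.0],
            },
            index=list("abcd"),
        )
        res = cross_tabulate(table)
        assert res.odds_ratio in (np.inf,) or np.isnan(res.odds_ratio)

    def test_label_swap_transposes_rows(self):
        table = load_pattern_survival_table()
        swapped = table.copy()
        swapped["pattern"] = swapped["pattern"].map({"down": "up", "up": "down"})
        res = cross_tabulate(table)
        res_sw = cross_tabulate(swapped)
        np.testing.assert_array_equal(res_sw.counts, res.counts[::-1])

    def test_unit_hazard_ratio_excluded_with_warning(self):
        table = pd.DataFrame(
            {
                "pattern": ["down", "down", "up", "up", "up"],
                "p": [0.01] * 5,
                "hazard_ratio": [1.5, 0.5, 1.0, 2.0, 0.4],
            },
            index=list("abcde"),
        )
        with pytest.warns(UserWarning):
            res = cross_tabulate(table)
        assert res.counts.sum() == 4
        assert res.excluded_unit_hr == 1


def test_planted_reciprocal_chain_gives_positive_association():
    """Down-risk / up-protective planting yields odds ratio > 1."""
    rng = np.random.default_rng(42)
    down = [f"D{i}" for i in range(25)]
    up = [f"U{i}" for i in range(25)]
    risk = {g: 0.8 for g in down} | {g: -0.8 for g in up}
    cohort = synthetic.generate_survival(None, risk, 0.1, 0.2, 300, seed=43)
    labels = {g: "down" for g in down} | {g: "up" for g in up}
    table = screen_genes(
        cohort, down + up, pattern_labels=labels,
        p_method="wald", seed=44,
    )
    res = cross_tabulate(table, alpha=0.05)
    assert res.odds_ratio > 1
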