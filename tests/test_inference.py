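"""Group-comparison suite: rank-sum, permutation null, NB regression,
Fisher exact, power simulation."""

import math
from itertools import combinations

import numpy as np
import pytest
from scipy import stats
from scipy.special import comb

from reportcheck.inference import (
    PowerSimSpec,
    compare_groups,
    fisher_exact_2x2,
    nb_regression,
    permutation_null_W,
    wilcoxon_power_sim,
    wilcoxon_rank_sum,
)


def _brute_force_rank_sum_p(x, y, alternative="less"):
    """Exact permutation distribution of the rank-sum W by enumeration."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1, n = len(x), len(pooled)
    observed = ranks[:n1].sum()
    mean_W = n1 * (n + 1) / 2
    ws = np.array([ranks[list(idx)].sum() for idx in combinations(range(n), n1)])
    if alternative == "less":
        return (ws <= observed + 1e-9).mean()
    if alternative == "greater":
        return (ws >= observed - 1e-9).mean()
    return (np.abs(ws - mean_W) >= abs(observed - mean_W) - 1e-9).mean()


class TestWilcoxonRankSum:
    def test_minimal_w_exact_p(self):
        # x occupies the two smallest ranks; 1 of the C(4,2)=6 assignments
        # is as small, so the exact one-sided p is 1/6 (enumeration oracle)
        res = wilcoxon_rank_sum([1, 2], [3, 4], alternative="less")
        assert res.W == 3.0
        assert res.p_value == pytest.approx(_brute_force_rank_sum_p([1, 2], [3, 4], "less"))
        assert res.p_value == pytest.approx(1 / 6)

    def test_identical_constant_groups(self):
        res = wilcoxon_rank_sum([5, 5, 5], [5, 5], alternative="two-sided")
        assert res.p_value == 1.0

    @pytest.mark.parametrize("alternative", ["two-sided", "greater", "less"])
    def test_matches_enumeration_small_samples(self, rng, alternative):
        for _ in range(20):
            x = rng.normal(size=int(rng.integers(2, 6)))
            y = rng.normal(size=int(rng.integers(2, 6)))
            res = wilcoxon_rank_sum(x, y, alternative=alternative)
            assert res.p_value == pytest.approx(
                _brute_force_rank_sum_p(x, y, alternative), abs=1e-9
            )

    def test_w_range_invariant(self, rng):
        for _ in range(20):
            n1, n2 = int(rng.integers(1, 10)), int(rng.integers(1, 10))
            res = wilcoxon_rank_sum(rng.normal(size=n1), rng.normal(size=n2))
            assert n1 * (n1 + 1) / 2 <= res.W <= n1 * n2 + n1 * (n1 + 1) / 2

    def test_null_p_values_roughly_uniform(self, rng):
        """Under the null the asymptotic p values are uniform (KS check)."""
        ps = []
        for _ in range(2000):
            ps.append(wilcoxon_rank_sum(rng.normal(size=30), rng.normal(size=30)).p_value)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestPermutationNull:
    def test_matches_exhaustive_enumeration(self, rng):
        x, y = rng.normal(size=3), rng.normal(size=3) + 1.0
        exact = permutation_null_W(x, y, exhaustive=True)
        assert exact.reps == comb(6, 3, exact=True)
        assert exact.p_empirical == pytest.approx(
            _brute_force_rank_sum_p(x, y, "two-sided"), abs=1e-12
        )

    def test_monte_carlo_converges_to_exact(self, rng):
        x, y = rng.normal(size=4), rng.normal(size=4) + 0.8
        exact = permutation_null_W(x, y, exhaustive=True).p_empirical
        mc = permutation_null_W(x, y, reps=20000, seed=1).p_empirical
        assert mc == pytest.approx(exact, abs=0.02)

    def test_reproducible_given_seed(self, rng):
        x, y = rng.normal(size=10), rng.normal(size=10)
        a = permutation_null_W(x, y, reps=2000, seed=7)
        b = permutation_null_W(x, y, reps=2000, seed=7)
        assert a.p_empirical == b.p_empirical

    def test_add_one_convention_bounds(self, rng):
        x, y = rng.normal(size=5) + 10, rng.normal(size=5)  # maximally separated
        res = permutation_null_W(x, y, reps=999, seed=0)
        assert 1 / (res.reps + 1) <= res.p_empirical <= 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            permutation_null_W([], [1.0, 2.0])

    def test_rejection_rate_tracks_power_sim(self, rng):
        """Permutation test rejection under a d=0.5 shift approximates the
        rank-sum power at the same design (small-scale cross-check)."""
        n, runs = 40, 60
        power_ref = wilcoxon_power_sim(PowerSimSpec(d=0.5, n_per_group=n, reps=2000, seed=3))
        rej = 0
        for i in range(runs):
            x = rng.normal(0, 1, n)
            y = rng.normal(0.5, 1, n)
            if permutation_null_W(x, y, reps=400, seed=i).p_empirical < 0.05:
                rej += 1
        assert rej / runs == pytest.approx(power_ref, abs=0.2)


class TestNBRegression:
    @staticmethod
    def _simulate(rng, n_per_group, b0, b1, b2, alpha):
        g = np.repeat([0, 1], n_per_group)
        n_stats = rng.integers(3, 40, g.size)
        mu = np.exp(b0 + b1 * g + b2 * np.log(n_stats))
        lam = rng.gamma(1 / alpha, alpha * mu)
        return rng.poisson(lam), g, n_stats

    def test_recovers_coefficients(self, rng):
        counts, g, n_stats = self._simulate(rng, 400, -2.3, 0.5, 1.0, 0.8)
        fit = nb_regression(counts, g, n_stats)
        assert fit.model == "negative_binomial"
        # single replicate: allow 3 SE (the multi-replicate coverage check
        # lives in the acceptance suite)
        assert fit.params[1] == pytest.approx(0.5, abs=3 * fit.bse[1])
        assert fit.params[2] == pytest.approx(1.0, abs=3 * fit.bse[2])
        assert fit.dispersion > 0

    def test_no_signal_flat_counts(self, rng):
        counts = np.full(60, 3.0)
        g = np.repeat([0, 1], 30)
        n_stats = np.full(60, 10.0)
        with pytest.warns(UserWarning):
            fit = nb_regression(counts, g, n_stats)  # no dispersion: Poisson route
        assert abs(fit.params[1]) < 1e-3
        assert abs(fit.params[2]) < 1e-3

    def test_all_zero_counts_raise_for_fisher_fallback(self):
        with pytest.raises(ValueError, match="fisher"):
            nb_regression(np.zeros(20), np.repeat([0, 1], 10), np.full(20, 5.0))

    def test_too_few_articles(self):
        with pytest.raises(ValueError):
            nb_regression([1, 2], [0, 1], [5, 5])


class TestFisherExact:
    def test_matches_brute_force_enumeration(self, rng):
        def brute(t):
            a, b = t[0]
            c, d = t[1]
            r1, r2, c1 = a + b, c + d, a + c
            n = r1 + r2
            p_obs = stats.hypergeom.pmf(a, n, c1, r1)
            total = 0.0
            for x in range(max(0, c1 - r2), min(c1, r1) + 1):
                px = stats.hypergeom.pmf(x, n, c1, r1)
                if px <= p_obs * (1 + 1e-9):
                    total += px
            return min(total, 1.0)

        for _ in range(25):
            t = rng.integers(0, 30, (2, 2))
            if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
                continue
            assert fisher_exact_2x2(t) == pytest.approx(brute(t), abs=1e-9)

    def test_extreme_diagonal_table(self):
        # all successes in one group: p = 2 / C(20, 10)
        assert fisher_exact_2x2([[10, 0], [0, 10]]) == pytest.approx(
            2 / comb(20, 10, exact=True)
        )

    def test_zero_margin_gives_one(self):
        assert fisher_exact_2x2([[0, 5], [0, 7]]) == 1.0

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1, 2, 3], [4, 5, 6]])


class TestPowerSim:
    def test_type_one_error_calibrated(self):
        power = wilcoxon_power_sim(PowerSimSpec(d=0.0, n_per_group=40, reps=4000, seed=2))
        assert power == pytest.approx(0.05, abs=0.015)

    def test_saturates_at_huge_effect(self):
        power = wilcoxon_power_sim(PowerSimSpec(d=3.0, n_per_group=90, reps=1000, seed=2))
        assert power == 1.0

    def test_reproducible(self):
        spec = PowerSimSpec(d=0.5, n_per_group=30, reps=1000, seed=9)
        assert wilcoxon_power_sim(spec) == wilcoxon_power_sim(spec)

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            PowerSimSpec(alpha=1.5)
        with pytest.raises(ValueError):
            PowerSimSpec(reps=10)


class TestCompareGroups:
    def test_report_structure_and_null_behavior(self, rng):
        import pandas as pd

        n = 40
        df = pd.DataFrame(
            {
                "article_id": [f"a{i}" for i in range(2 * n)],
                "group": ["outliers_removed"] * n + ["no_removal"] * n,
                "journal": ["JESP", "CP"] * n,
                "n_significant": rng.integers(5, 25, 2 * n),
                "median_recomputed_p": rng.uniform(0.001, 0.04, 2 * n),
                "n_error": rng.poisson(1.0, 2 * n),
                "n_large": rng.poisson(0.2, 2 * n),
                "n_gross": rng.poisson(0.2, 2 * n),
                "median_sample_size": rng.integers(30, 200, 2 * n).astype(float),
            }
        )
        df["n_error"] = df[["n_error", "n_large", "n_gross"]].max(axis=1)
        report = compare_groups(df, reps=2000, seed=0)
        assert set(report["fisher_exact"]) == {"all", "large", "gross"}
        assert "Total" in report["wilcoxon_median_p"]
        # no group effect was simulated: total p should not be tiny
        assert report["wilcoxon_median_p"]["Total"]["p"] > 0.001
        # permutation p agrees with the asymptotic Wilcoxon p
        assert report["permutation_median_p"]["p_empirical"] == pytest.approx(
            report["wilcoxon_median_p"]["Total"]["p"], abs=0.05
        )
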