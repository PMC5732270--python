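"""Population statistics: Friedman + LSD, linear models, FDR, power,
rank tests."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from oddball.stats import (
    bh_fdr,
    correlate,
    fit_hierarchy_model,
    fit_spl_model,
    friedman_conditions,
    min_sample_size,
    rank_sum_test,
    signed_rank_test,
)

HIER_COEF = {
    "const": 0.012, "NL": 0.020, "MGB": -0.136, "AC": 0.092,
    "NL:MGB": 0.185, "NL:AC": 0.158,
}


def simulate_hierarchy(rng, n, noise_sd=0.3):
    rows = []
    for _ in range(n):
        h = rng.choice(["L", "NL"])
        nuc = rng.choice(["IC", "MGB", "AC"])
        mu = HIER_COEF["const"]
        if h == "NL":
            mu += HIER_COEF["NL"]
        mu += HIER_COEF.get(nuc, 0.0)
        if h == "NL" and nuc in ("MGB", "AC"):
            mu += HIER_COEF[f"NL:{nuc}"]
        rows.append(dict(ipe=mu + rng.normal(0, noise_sd), hierarchy=h, nucleus=nuc))
    return pd.DataFrame(rows)


class TestFriedman:
    def test_identical_conditions_not_significant(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        jitter = rng.normal(scale=1e-9, size=(3, 30))  # break exact ties
        res = friedman_conditions(x + jitter[0], x + jitter[1], x + jitter[2])
        assert res.p_value > 0.2
        assert all(p > 0.2 for p in res.pairwise_p.values())

    def test_consistent_shift_detected_in_right_pair(self):
        rng = np.random.default_rng(1)
        std = rng.normal(10, 1, size=60)
        res = friedman_conditions(std + 1.0, std, std + rng.normal(0, 1e-6, 60))
        assert res.pairwise_p[("DEV", "STD")] < 1e-6
        assert res.median_diff[("DEV", "STD")] == pytest.approx(1.0)

    def test_statistic_matches_hand_ranks(self):
        """Tiny table against a brute-force Friedman chi-square."""
        dev = np.array([3.0, 2.0, 5.0, 4.0])
        std = np.array([1.0, 1.0, 2.0, 2.0])
        ctr = np.array([2.0, 3.0, 4.0, 3.0])
        res = friedman_conditions(dev, std, ctr)
        ranks = np.array([sps.rankdata(row) for row in np.c_[dev, std, ctr]])
        n, k = ranks.shape
        rj = ranks.sum(axis=0)
        chi = 12.0 / (n * k * (k + 1)) * np.sum(rj**2) - 3 * n * (k + 1)
        # scipy applies a tie correction; the uncorrected value bounds it
        assert res.statistic == pytest.approx(chi, rel=0.2)
        assert res.n == 4

    def test_unmatched_rows_rejected(self):
        with pytest.raises(ValueError):
            friedman_conditions(np.ones(5), np.ones(4), np.ones(5))


class TestHierarchyModel:
    def test_coefficients_recovered(self):
        rng = np.random.default_rng(2)
        fit = fit_hierarchy_model(simulate_hierarchy(rng, 3000, noise_sd=0.05))
        for name, true in HIER_COEF.items():
            assert fit.params[name] == pytest.approx(true, abs=3 * fit.bse[name])

    def test_fitted_cell_is_sum_of_terms(self):
        rng = np.random.default_rng(3)
        fit = fit_hierarchy_model(simulate_hierarchy(rng, 4000, noise_sd=0.01))
        cell = fit.predict_sum(["const", "NL", "AC", "NL:AC"])
        assert cell == pytest.approx(0.012 + 0.020 + 0.092 + 0.158, abs=0.01)

    def test_anova_terms_present(self):
        rng = np.random.default_rng(4)
        fit = fit_hierarchy_model(simulate_hierarchy(rng, 600))
        assert {"hierarchy", "nucleus", "hierarchy:nucleus"} <= set(fit.anova.index)

    def test_null_anova_p_roughly_uniform(self):
        rng = np.random.default_rng(5)
        ps = []
        for _ in range(120):
            df = simulate_hierarchy(rng, 120)
            df["ipe"] = rng.normal(size=len(df))  # no structure
            ps.append(fit_hierarchy_model(df).anova.loc["hierarchy", "PR(>F)"])
        # Kolmogorov-Smirnov against U(0,1)
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_robust_option_returns_params(self):
        rng = np.random.default_rng(6)
        fit = fit_hierarchy_model(simulate_hierarchy(rng, 500), robust=True)
        assert fit.robust and fit.anova is None
        assert "NL" in fit.params


class TestSPLModel:
    def test_printed_coefficient_evaluation(self):
        """The fitted surface at (ascending, 4 Bels) from exactly-generated
        data matches the closed-form sum 0.064+0.194+0.003*4-0.037*4."""
        rng = np.random.default_rng(7)
        rows = []
        for _ in range(4000):
            d = rng.choice(["ascending", "descending"])
            spl = rng.choice([2.0, 3.0, 4.0, 6.0])
            mu = 0.064 + 0.003 * spl
            if d == "ascending":
                mu += 0.194 - 0.037 * spl
            rows.append(dict(ipe=mu + rng.normal(0, 0.01), direction=d, spl_bels=spl))
        fit = fit_spl_model(pd.DataFrame(rows))
        at = (
            fit.params["const"] + fit.params["ascending"]
            + 4.0 * (fit.params["SPL"] + fit.params["ascending:SPL"])
        )
        assert at == pytest.approx(0.122, abs=0.005)
        assert fit.params["const"] == pytest.approx(0.064, abs=0.005)

    def test_single_spl_level_warns(self):
        df = pd.DataFrame(
            dict(ipe=np.random.default_rng(0).normal(size=20),
                 direction=["ascending", "descending"] * 10,
                 spl_bels=[4.0] * 20)
        )
        with pytest.warns(UserWarning):
            fit_spl_model(df)


class TestFDR:
    def test_step_up_example(self):
        reject, _ = bh_fdr([0.001, 0.02, 0.03, 0.5], q=0.1)
        assert reject.tolist() == [True, True, True, False]

    def test_all_ones_none_rejected(self):
        reject, _ = bh_fdr([1.0, 1.0, 1.0], q=0.1)
        assert not reject.any()

    def test_single_p_threshold_is_q(self):
        assert bh_fdr([0.04], q=0.1)[0][0]
        assert not bh_fdr([0.2], q=0.1)[0][0]

    def test_null_false_discovery_proportion_controlled(self):
        rng = np.random.default_rng(8)
        any_rej = 0
        for _ in range(1000):
            p = rng.uniform(size=20)
            rej, _ = bh_fdr(p, q=0.1)
            any_rej += rej.any()
        # under the global null, FDR = P(any rejection) <= q
        assert any_rej / 1000 <= 0.12


class TestMinSampleSize:
    def test_medium_effect_matches_noncentral_t_scan(self):
        """d = 0.4 needs n = 52; verified against a direct power scan."""
        rng = np.random.default_rng(9)
        vals = rng.normal(0.2, 0.5, size=200_000)
        res = min_sample_size(vals)
        # brute-force power scan via the noncentral t distribution
        d = res.effect_size
        def power(n):
            crit = sps.t.ppf(0.975, n - 1)
            nc = d * math.sqrt(n)
            return sps.nct.sf(crit, n - 1, nc) + sps.nct.cdf(-crit, n - 1, nc)
        n_scan = next(n for n in range(2, 500) if power(n) >= 0.8)
        assert abs(res.n - n_scan) <= 2
        assert res.n == pytest.approx(52, abs=2)

    def test_huge_effect_floors_at_two(self):
        assert min_sample_size([5.0, 5.1, 4.9, 5.05]).n <= 3

    def test_zero_mean_uses_effect_floor(self):
        rng = np.random.default_rng(10)
        vals = rng.normal(0.0, 0.5, size=100_000)
        res = min_sample_size(vals)
        assert res.effect_size == pytest.approx(0.05 / 0.5, rel=0.05)

    def test_zero_variance_degenerate(self):
        assert min_sample_size([0.3, 0.3, 0.3]).degenerate


class TestRankTests:
    def test_identical_pairs_no_evidence(self):
        assert signed_rank_test(np.ones(10), np.ones(10))[1] == 1.0

    def test_unit_shift_detected(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=30)
        assert signed_rank_test(x + 1.0, x)[1] < 0.001

    def test_rank_sum_matches_exact_enumeration(self):
        """4-vs-4 rank-sum p equals brute force over all label
        permutations."""
        x = np.array([1.2, 3.4, 2.2, 5.0])
        y = np.array([0.1, 0.5, 1.0, 0.7])
        _, p = rank_sum_test(x, y)
        pooled = np.concatenate([x, y])
        ranks = sps.rankdata(pooled)
        obs = ranks[:4].sum()
        stats = []
        for comb in itertools.combinations(range(8), 4):
            stats.append(ranks[list(comb)].sum())
        stats = np.array(stats)
        mean = stats.mean()
        p_exact = np.mean(np.abs(stats - mean) >= abs(obs - mean) - 1e-12)
        assert p == pytest.approx(p_exact, abs=1e-9)

    def test_too_small_samples_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([1.0], [2.0, 3.0])


class TestCorrelate:
    def test_perfect_monotone(self):
        x = np.arange(10.0)
        assert correlate(x, x**3)[0] == pytest.approx(1.0)
        assert correlate(x, -x)[0] == pytest.approx(-1.0)

    def test_independent_near_zero(self):
        rng = np.random.default_rng(12)
        rho, p = correlate(rng.normal(size=2000), rng.normal(size=2000))
        assert abs(rho) < 0.06

    def test_minimum_n(self):
        with pytest.raises(ValueError):
            correlate([1.0, 2.0], [2.0, 1.0])
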