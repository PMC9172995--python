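"""Tukey range test, Mann-Whitney U, bootstrap SE, and the 4PL curve."""

import itertools

import numpy as np
import pytest

from incubehave.assay_stats import (
    anova_tukey,
    blank_subtract,
    bootstrap_se,
    fit_4pl,
    invert_4pl,
    mannwhitney_one_tailed,
)
from incubehave.synthetic_data import DEFAULT_4PL_PARAMS, FourPLParams, gen_elisa_plate


class TestAnovaTukey:
    def test_identical_groups_p_one(self):
        g = np.array([1.0, 2.0, 3.0])
        res = anova_tukey({"a": g, "b": g.copy()})
        assert res.q_statistics[0] == 0.0
        assert res.p_adjusted[0] == pytest.approx(1.0)

    def test_three_identical_groups(self):
        g = np.array([1.0, 2.0, 3.0])
        res = anova_tukey({"a": g, "b": g.copy(), "c": g.copy()})
        np.testing.assert_allclose(res.p_adjusted, 1.0)

    def test_q_statistics_match_hand_formula(self):
        rng = np.random.default_rng(0)
        groups = {
            "g1": rng.normal(0.0, 1.0, 5),
            "g2": rng.normal(1.0, 1.0, 5),
            "g3": rng.normal(2.5, 1.0, 5),
        }
        res = anova_tukey(groups)
        # independent oracle: q = |mean_i - mean_j| / sqrt(MSE / n), equal n
        labels = list(groups)
        means = {g: groups[g].mean() for g in labels}
        mse = sum(((groups[g] - means[g]) ** 2).sum() for g in labels) / (15 - 3)
        for (gi, gj), q in zip(res.pairs, res.q_statistics):
            oracle = abs(means[gi] - means[gj]) / np.sqrt(mse / 5)
            assert q == pytest.approx(oracle, abs=1e-10)

    def test_p_values_match_statsmodels(self):
        statsmodels = pytest.importorskip("statsmodels.stats.multicomp")
        rng = np.random.default_rng(1)
        groups = {
            "g1": rng.normal(0.0, 1.0, 6),
            "g2": rng.normal(0.8, 1.0, 8),  # unequal n exercises Kramer
            "g3": rng.normal(2.0, 1.0, 5),
        }
        res = anova_tukey(groups)
        data = np.concatenate(list(groups.values()))
        labels = np.repeat(list(groups), [len(v) for v in groups.values()])
        sm = statsmodels.pairwise_tukeyhsd(data, labels)
        np.testing.assert_allclose(res.p_adjusted, sm.pvalues, atol=1e-6)

    def test_shift_invariance(self):
        rng = np.random.default_rng(2)
        groups = {g: rng.normal(i, 1.0, 5) for i, g in enumerate("abc")}
        res1 = anova_tukey(groups)
        res2 = anova_tukey({g: v + 100.0 for g, v in groups.items()})
        np.testing.assert_allclose(res1.p_adjusted, res2.p_adjusted, rtol=1e-9)
        np.testing.assert_allclose(res1.q_statistics, res2.q_statistics, rtol=1e-9)

    def test_too_few_groups_rejected(self):
        with pytest.raises(ValueError):
            anova_tukey({"only": np.array([1.0, 2.0])})


class TestMannWhitney:
    def test_singleton_samples_half(self):
        _u, p = mannwhitney_one_tailed([1.0], [2.0], "A<B")
        assert p == pytest.approx(0.5)

    def test_fully_separated_triples_exact(self):
        u, p = mannwhitney_one_tailed([1, 2, 3], [4, 5, 6], "A<B")
        assert u == 0.0
        assert p == pytest.approx(0.05)  # 1 of C(6,3)=20 assignments

    def test_exact_matches_enumeration_oracle(self):
        a = np.array([1.0, 3.0, 5.0])
        b = np.array([2.0, 4.0, 6.0])
        _u, p = mannwhitney_one_tailed(a, b, "A<B")
        # enumerate all label assignments of the pooled sample
        pooled = np.concatenate([a, b])
        u_obs = sum((x < y) for x in a for y in b)  # pairs favoring A<B
        count = 0
        total = 0
        for idx in itertools.combinations(range(6), 3):
            aa = pooled[list(idx)]
            bb = pooled[[i for i in range(6) if i not in idx]]
            u = sum((x < y) for x in aa for y in bb)
            count += u >= u_obs  # as-or-more extreme toward A<B
            total += 1
        assert p == pytest.approx(count / total, abs=1e-12)

    def test_identical_multisets_p_at_least_half(self):
        a = [1.0, 2.0, 7.0]
        with pytest.warns(UserWarning):
            _u, p_lt = mannwhitney_one_tailed(a, list(a), "A<B")
        with pytest.warns(UserWarning):
            _u, p_gt = mannwhitney_one_tailed(a, list(a), "A>B")
        assert p_lt >= 0.5 and p_gt >= 0.5

    def test_exact_close_to_normal_approximation_at_n12(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, 6)
        b = rng.normal(0.5, 1, 6)
        _u, p_exact = mannwhitney_one_tailed(a, b, "A<B", exact_max_n=12)
        _u, p_approx = mannwhitney_one_tailed(a, b, "A<B", exact_max_n=0)
        assert abs(p_exact - p_approx) < 0.02

    def test_bad_direction_rejected(self):
        with pytest.raises(ValueError):
            mannwhitney_one_tailed([1.0], [2.0], "sideways")


class TestBootstrap:
    def test_identical_observations_zero_se(self):
        assert bootstrap_se(np.ones(20), n_boot=500, seed=0) == 0.0

    def test_binary_percentage_matches_binomial_se(self):
        obs = np.r_[np.ones(39), np.zeros(8)]  # 39 successes of 47
        se = bootstrap_se(obs, n_boot=10_000, seed=1)
        p_hat = 39 / 47
        analytic = 100.0 * np.sqrt(p_hat * (1 - p_hat) / 47)
        assert abs(se - analytic) / analytic < 0.10

    def test_seed_reproducibility(self):
        obs = np.r_[np.ones(10), np.zeros(5)]
        assert bootstrap_se(obs, seed=7, n_boot=2000) == bootstrap_se(obs, seed=7, n_boot=2000)

    def test_composition_input_gives_per_category_se(self):
        rng = np.random.default_rng(4)
        comps = rng.dirichlet(np.ones(3), size=12) * 100.0
        se = bootstrap_se(comps, statistic=lambda x: np.mean(x, axis=0), n_boot=2000, seed=0)
        assert se.shape == (3,)
        assert (se > 0).all()

    def test_convergence_between_resample_counts(self):
        obs = np.r_[np.ones(30), np.zeros(17)]
        se1 = bootstrap_se(obs, n_boot=10_000, seed=5)
        se2 = bootstrap_se(obs, n_boot=100_000, seed=6)
        assert abs(se1 - se2) / se2 < 0.05

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_se(np.array([]))


class TestFourPL:
    def test_noiseless_round_trip_from_spec_params(self):
        params = FourPLParams(a=20.0, b=1.5, c=0.5, d=0.0)
        concs = np.array([0.1, 0.4, 1.6, 5.0, 15.0])  # inside the asymptotes
        x = params.od_for(concs)
        fit, rss = fit_4pl(x, concs)
        assert rss <= 1e-10
        assert abs(fit.a - 20.0) / 20.0 < 1e-4
        assert abs(fit.b - 1.5) / 1.5 < 1e-4
        assert abs(fit.c - 0.5) / 0.5 < 1e-4
        assert abs(fit.d) < 1e-4  # d = 0: absolute scale

    def test_generated_plate_round_trip(self):
        plate = gen_elisa_plate(DEFAULT_4PL_PARAMS, blank_od=0.05, noise_sd=0.0)
        std = plate[plate.well_type == "standard"]
        blank = plate[plate.well_type == "blank"].od.mean()
        x = blank_subtract(std.groupby("concentration").od.mean().to_numpy(), blank)
        concs = np.sort(std.concentration.unique())
        fit, rss = fit_4pl(x, concs)
        assert rss <= 1e-10
        for got, want in [
            (fit.a, DEFAULT_4PL_PARAMS.a), (fit.b, DEFAULT_4PL_PARAMS.b),
            (fit.c, DEFAULT_4PL_PARAMS.c), (fit.d, DEFAULT_4PL_PARAMS.d),
        ]:
            assert abs(got - want) / abs(want) < 1e-4

    def test_midpoint_identity(self):
        p = FourPLParams(a=20.0, b=1.5, c=0.5, d=0.0)
        assert p.concentration(p.c) == pytest.approx((p.a + p.d) / 2)
        assert invert_4pl(p, p.c) == pytest.approx(10.0)

    def test_asymptotes(self):
        p = FourPLParams(a=20.0, b=1.5, c=0.5, d=0.0)
        assert p.concentration(1e9) == pytest.approx(p.d, abs=1e-6)
        assert p.concentration(1e-12) == pytest.approx(p.a, rel=1e-6)

    def test_inversion_recovers_standard_concentration(self):
        p = FourPLParams(a=20.0, b=1.5, c=0.5, d=0.0)
        x = float(p.od_for(1.6))
        assert invert_4pl(p, x) == pytest.approx(1.6, rel=1e-4)

    def test_extrapolation_flagged(self):
        p = DEFAULT_4PL_PARAMS
        with pytest.warns(UserWarning, match="extrapolat"):
            invert_4pl(p, 50.0, standard_od_range=(0.1, 4.0))

    def test_non_positive_od_rows_excluded_with_warning(self):
        params = FourPLParams(a=20.0, b=1.5, c=0.5, d=0.0)
        concs = np.array([0.1, 0.4, 1.6, 5.0, 10.0, 15.0])
        x = params.od_for(concs)
        x[0] = -0.01
        with pytest.warns(UserWarning, match="excluded"):
            fit, _ = fit_4pl(x, concs)
        assert abs(fit.c - 0.5) / 0.5 < 1e-3
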