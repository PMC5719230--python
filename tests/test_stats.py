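"""Inferential layer against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import sstlab as sl
from sstlab.stats import PowerSpec, chisq_power, interpret_bf


# ---------------------------------------------------------------------------
# independent oracles


def km_oracle(times):
    """Brute-force product-limit estimate, no censoring."""
    times = np.asarray(times, dtype=float)
    uniq = np.unique(times)
    s = 1.0
    out = []
    for t in uniq:
        at_risk = (times >= t).sum()
        deaths = (times == t).sum()
        s *= 1.0 - deaths / at_risk
        out.append((t, s))
    return out


def anova_oracle(values, labels):
    """One-way ANOVA by least squares on a dummy design matrix."""
    values = np.asarray(values, dtype=float)
    groups = pd.unique(labels)
    X = np.column_stack([np.asarray(labels) == g for g in groups]).astype(float)
    beta, _, _, _ = np.linalg.lstsq(X, values, rcond=None)
    fitted = X @ beta
    ss_res = ((values - fitted) ** 2).sum()
    ss_tot = ((values - values.mean()) ** 2).sum()
    df_b, df_w = len(groups) - 1, len(values) - len(groups)
    f = ((ss_tot - ss_res) / df_b) / (ss_res / df_w)
    return f, (ss_tot - ss_res) / ss_tot


def jzs_oracle(t, n1, n2, r=0.707):
    """Fine-grid quadrature in the Zellner-Siow g parameterization:
    delta | g ~ N(0, g r^2), g ~ InverseGamma(1/2, 1/2) — an independent
    route to the same Bayes factor."""
    nu = n1 + n2 - 2
    N = n1 * n2 / (n1 + n2)
    g = np.exp(np.linspace(np.log(1e-8), np.log(1e6), 60_000))

    def marginal(tt):
        a = 1.0 + N * g * r * r
        like = (
            a ** -0.5
            * (1.0 + tt * tt / (a * nu)) ** (-(nu + 1) / 2.0)
        )
        prior = (2 * np.pi) ** -0.5 * g ** -1.5 * np.exp(-0.5 / g)
        return np.trapezoid(like * prior, g)

    null = (1.0 + t * t / nu) ** (-(nu + 1) / 2.0)
    return marginal(t) / null


def irls_logit_oracle(x, y, iters=50):
    """Hand-rolled iteratively reweighted least squares for the logit."""
    X = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    for _ in range(iters):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        W = p * (1.0 - p)
        z = eta + (y - p) / W
        beta = np.linalg.solve(X.T @ (W[:, None] * X), X.T @ (W * z))
    cov = np.linalg.inv(X.T @ (W[:, None] * X))
    return beta, np.sqrt(np.diag(cov))


# ---------------------------------------------------------------------------


class TestKaplanMeier:
    def test_empirical_survivor_no_censoring(self):
        km = sl.km_estimate([4, 4, 10, 10])
        assert km.survival_at(4) == pytest.approx(0.5)
        assert km.survival_at(10) == pytest.approx(0.0)
        assert km.survival_at(3.9) == pytest.approx(1.0)

    def test_single_participant_step(self):
        km = sl.km_estimate([6])
        assert km.survival_at(5.9) == 1.0 and km.survival_at(6) == 0.0

    def test_matches_product_limit_oracle(self, rng):
        """Agreement with the brute-force product-limit estimate on 100
        random datasets."""
        for _ in range(100):
            times = rng.integers(1, 11, size=rng.integers(1, 30))
            km = sl.km_estimate(times)
            for t, s in km_oracle(times):
                assert km.survival_at(t) == pytest.approx(s, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sl.km_estimate([])


class TestLogrank:
    def test_identical_groups_near_zero(self):
        g = {"a": [4, 5, 6, 7, 8, 10], "b": [4, 5, 6, 7, 8, 10]}
        res = sl.logrank_test(g)
        assert res.statistic == pytest.approx(0.0, abs=1e-10)
        assert res.df == (1,)

    def test_three_groups_df_two(self):
        g = {"a": [4, 5, 6], "b": [5, 6, 7], "c": [4, 6, 10]}
        assert sl.logrank_test(g).df == (2,)

    def test_censoring_mode_coincides_at_study_cap(self):
        """When the censoring time equals the latest exit time, the time-cap
        contribution to the log-rank statistic is identically zero (observed
        equals expected and the hypergeometric variance vanishes), so both
        handling modes give the same statistic."""
        g = {"a": [4, 4, 10, 10], "b": [6, 7, 10, 10]}
        r1 = sl.logrank_test(g, censor_last=True)
        r2 = sl.logrank_test(g, censor_last=False)
        assert r1.statistic == pytest.approx(r2.statistic, abs=1e-10)

    def test_label_permutation_invariance(self, rng):
        times_a = list(rng.integers(4, 11, 20))
        times_b = list(rng.integers(4, 11, 20))
        r1 = sl.logrank_test({"a": times_a, "b": times_b})
        r2 = sl.logrank_test({"b": times_b, "a": times_a})
        assert r1.statistic == pytest.approx(r2.statistic)


class TestOnewayAnova:
    def test_two_groups_f_is_t_squared(self, rng):
        a, b = rng.normal(0, 1, 20), rng.normal(0.4, 1, 25)
        res = sl.oneway_anova(np.r_[a, b], np.r_[["a"] * 20, ["b"] * 25])
        tres = sl.posthoc_t(a, b)
        assert res.statistic == pytest.approx(tres.statistic**2, rel=1e-9)

    def test_identical_means(self):
        vals = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        res = sl.oneway_anova(vals, ["a"] * 3 + ["b"] * 3)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.effect_size == pytest.approx(0.0, abs=1e-12)

    def test_matches_least_squares_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(9, 40))
            labels = rng.choice(["a", "b", "c"], size=n)
            while min((labels == g).sum() for g in "abc") < 2:
                labels = rng.choice(["a", "b", "c"], size=n)
            values = rng.normal(0, 1, n) + (labels == "b") * 0.5
            res = sl.oneway_anova(values, labels)
            f, eta = anova_oracle(values, labels)
            assert res.statistic == pytest.approx(f, rel=1e-9)
            assert res.effect_size == pytest.approx(eta, rel=1e-9)

    def test_pvalues_in_unit_interval(self, rng):
        for _ in range(20):
            vals = rng.normal(0, 1, 30)
            res = sl.oneway_anova(vals, ["a"] * 15 + ["b"] * 15)
            assert 0.0 <= res.p_value <= 1.0


class TestMixedAnova:
    def frame(self, rng, interaction=0.0, time_effect=-5.0):
        rows = []
        for i in range(60):
            v = ["nongame", "points", "theme"][i % 3]
            base = rng.normal(55, 8)
            for s in (1, 4):
                shift = time_effect if s == 4 else 0.0
                if s == 4 and v == "points":
                    shift += interaction
                rows.append(dict(participant_id=f"P{i}", variant=v,
                                 session_number=s,
                                 score=base + shift + rng.normal(0, 3)))
        return pd.DataFrame(rows)

    def test_pure_time_effect_has_null_interaction(self):
        res = sl.rm_anova_2x3(self.frame(np.random.default_rng(61), interaction=0.0))
        assert res["interaction"].p_value > 0.05
        assert res["within"].p_value < 1e-6

    def test_within_f_equals_paired_t_squared(self, rng):
        df = self.frame(rng)
        res = sl.rm_anova_2x3(df)
        assert res["within"].df[0] == 1.0

    def test_difference_score_oracle(self, rng):
        """The interaction F in a 2-level mixed design equals the one-way
        ANOVA F on per-subject difference scores."""
        df = self.frame(rng, interaction=4.0)
        res = sl.rm_anova_2x3(df)
        wide = df.pivot_table(index=["participant_id", "variant"],
                              columns="session_number", values="score").reset_index()
        diffs = (wide[4] - wide[1]).to_numpy()
        f, _ = anova_oracle(diffs, wide["variant"].to_numpy())
        assert res["interaction"].statistic == pytest.approx(f, rel=1e-6)


class TestPosthocT:
    def test_identical_groups(self):
        res = sl.posthoc_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0 and res.effect_size == 0.0

    def test_df_convention(self, rng):
        res = sl.posthoc_t(rng.normal(0, 1, 86), rng.normal(0, 1, 85))
        assert res.df == (169.0,)

    def test_hand_oracle_three_plus_three(self):
        a, b = np.array([1.0, 2.0, 3.0]), np.array([2.0, 4.0, 6.0])
        # pooled sd: sp2 = (2*1 + 2*4)/4 = 2.5 ; se = sqrt(2.5*(2/3))
        se = np.sqrt(2.5 * (2.0 / 3.0))
        t_expected = (2.0 - 4.0) / se
        res = sl.posthoc_t(a, b)
        assert res.statistic == pytest.approx(t_expected)
        assert res.df == (4.0,)
        assert res.effect_size == pytest.approx(-2.0 / np.sqrt(2.5))
        lo, hi = res.ci_95
        assert lo < -2.0 < hi

    def test_welch_switch(self, rng):
        a = rng.normal(0, 1, 30)
        b = rng.normal(0, 5, 10)
        pooled = sl.posthoc_t(a, b)
        welch = sl.posthoc_t(a, b, welch=True)
        assert welch.df[0] < pooled.df[0]


class TestJZSBayes:
    def test_null_favoring_at_t_zero(self):
        res = sl.jzs_bayes_t(t=0.0, n1=86, n2=86)
        assert res.bf10 < 1.0 / 3.0
        assert res.interpretation == "Positive" and res.favors == "null"

    def test_grid_agreement_with_quadrature_oracle(self):
        """<= 1% disagreement with the fine-grid g-integral oracle across a
        (t, n1, n2) grid."""
        for t in (0.0, 0.5, 1.5, 2.5, 3.5):
            for n1, n2 in ((10, 10), (30, 25), (86, 85)):
                mine = sl.jzs_bf10_from_t(t, n1, n2)
                ref = jzs_oracle(t, n1, n2)
                assert mine == pytest.approx(ref, rel=0.01)

    def test_cross_check_pingouin(self):
        import pingouin as pg
        for t, n in ((1.2, 40), (2.4, 86)):
            mine = sl.jzs_bf10_from_t(t, n, n)
            ref = float(pg.bayesfactor_ttest(t, n, n, paired=False, r=0.707))
            assert mine == pytest.approx(ref, rel=0.01)

    def test_bf10_times_bf01_is_one(self):
        res = sl.jzs_bayes_t(t=1.7, n1=30, n2=28)
        assert res.bf10 * (1.0 / res.bf10) == pytest.approx(1.0)
        assert res.to_dict()["bf01"] == pytest.approx(1.0 / res.bf10)

    def test_monotone_in_prior_width(self):
        """Widening the Cauchy prior spreads H1's mass over implausible
        effects, driving BF10 toward 0 for fixed data."""
        bfs = [sl.jzs_bf10_from_t(1.0, 20, 20, prior_scale=r)
               for r in (0.5, 1.0, 2.0, 5.0, 20.0)]
        assert all(b > a for a, b in zip(bfs[1:], bfs))
        assert bfs[-1] < 0.2

    def test_interpretation_bands(self):
        assert interpret_bf(0.5) == ("No support either way", "neither")
        assert interpret_bf(0.2) == ("Positive", "null")
        assert interpret_bf(0.05) == ("Strong", "null")
        assert interpret_bf(0.005) == ("Decisive", "null")
        assert interpret_bf(5.0) == ("Positive", "alternative")
        assert interpret_bf(500.0) == ("Decisive", "alternative")


class TestLogisticReturn:
    def test_independence_gives_unit_odds_ratio(self, rng):
        x = rng.uniform(0, 100, 600)
        y = rng.random(600) < 0.6
        res = sl.logistic_return_model(x, y)
        assert res.odds_ratio == pytest.approx(1.0, abs=0.02)
        assert res.p_value > 0.01

    def test_wald_equals_squared_z(self, rng):
        x = rng.uniform(0, 100, 200)
        y = rng.random(200) < 1 / (1 + np.exp(-(x - 50) / 30))
        res = sl.logistic_return_model(x, y)
        assert res.wald_chi2 == pytest.approx((res.beta / res.se) ** 2)

    def test_matches_irls_oracle_on_fixture(self):
        x = np.array([10, 20, 25, 30, 35, 40, 45, 50, 55, 60,
                      62, 65, 70, 72, 75, 80, 85, 90, 95, 99], dtype=float)
        y = np.array([0, 0, 1, 0, 0, 1, 0, 1, 1, 0,
                      1, 1, 0, 1, 1, 1, 0, 1, 1, 1], dtype=float)
        res = sl.logistic_return_model(x, y)
        beta, se = irls_logit_oracle(x, y)
        assert res.beta == pytest.approx(beta[1], rel=1e-5)
        assert res.se == pytest.approx(se[1], rel=1e-4)

    def test_separation_detected(self):
        x = np.linspace(0, 100, 30)
        y = (x > 50).astype(float)
        res = sl.logistic_return_model(x, y)
        assert res.separation


class TestChisqPower:
    def test_study_sample_size(self):
        assert sl.chisq_power_n(PowerSpec(0.231, 2, 0.05, 0.95)) == 290
        assert sl.chisq_power_n(PowerSpec(0.231, 2, 0.05, 0.95), multiple_of=3) == 291

    def test_doubling_phi_quarters_n(self):
        n1 = sl.chisq_power_n(PowerSpec(0.231, 2, 0.05, 0.95))
        n2 = sl.chisq_power_n(PowerSpec(0.462, 2, 0.05, 0.95))
        assert n1 / n2 == pytest.approx(4.0, rel=0.05)

    def test_monotonicity(self):
        n_low_phi = sl.chisq_power_n(PowerSpec(0.15, 2, 0.05, 0.95))
        n_high_phi = sl.chisq_power_n(PowerSpec(0.3, 2, 0.05, 0.95))
        assert n_low_phi > n_high_phi
        n_low_pow = sl.chisq_power_n(PowerSpec(0.231, 2, 0.05, 0.80))
        assert n_low_pow < 290

    def test_returned_n_is_minimal(self):
        spec = PowerSpec(0.231, 2, 0.05, 0.95)
        n = sl.chisq_power_n(spec)
        assert chisq_power(n, 0.231, 2) >= 0.95
        assert chisq_power(n - 1, 0.231, 2) < 0.95

    def test_monte_carlo_power_at_returned_n(self):
        """Simulated power of a df=2 goodness-of-fit chi-square at the
        returned n is at least the target within Monte-Carlo error."""
        phi = 0.231
        n = sl.chisq_power_n(PowerSpec(phi, 2, 0.05, 0.95))
        d = phi / np.sqrt(6.0)  # cells (1/3+d, 1/3-d, 1/3) give this phi
        p1 = np.array([1 / 3 + d, 1 / 3 - d, 1 / 3])
        rng = np.random.default_rng(17)
        reps = 4000
        counts = rng.multinomial(n, p1, size=reps)
        expected = n / 3.0
        chi2 = ((counts - expected) ** 2 / expected).sum(axis=1)
        crit = sps.chi2.ppf(0.95, 2)
        power = (chi2 > crit).mean()
        se = np.sqrt(0.95 * 0.05 / reps)
        assert power >= 0.95 - 3 * se

    def test_unattainable_rejected(self):
        with pytest.raises(ValueError):
            sl.chisq_power_n(PowerSpec(1e-6, 2, 0.05, 0.95), n_max=1000)
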