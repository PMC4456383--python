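"""Association statistics: WLS, nested ANOVA, Spearman, BH-FDR, candidates."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from poolcoev.assoc import (
    SingularDesignError,
    bh_fdr,
    candidate_region_filter,
    nested_anova,
    spearman_correlation,
    weighted_least_squares,
)


def _wls_normal_equations(x, y, w):
    """Independent oracle: solve the weighted normal equations directly."""
    X = np.column_stack([np.ones_like(x), x])
    W = np.diag(w)
    beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ y)
    return beta  # [intercept, slope]


class TestWls:
    def test_perfect_line(self):
        r = weighted_least_squares([1, 2, 3], [1, 2, 3], [2.0, 0.5, 7.0])
        assert r.slope == pytest.approx(1.0, abs=1e-12)
        assert r.intercept == pytest.approx(0.0, abs=1e-12)
        assert r.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_unit_weights_equal_ols_oracle(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=30)
        y = 2.0 + 0.7 * x + rng.normal(size=30)
        r = weighted_least_squares(x, y, np.ones(30))
        b0, b1 = _wls_normal_equations(x, y, np.ones(30))
        assert r.intercept == pytest.approx(b0, abs=1e-10)
        assert r.slope == pytest.approx(b1, abs=1e-10)

    def test_matches_statsmodels_wls(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        x = rng.normal(size=25)
        y = 1.0 - 0.4 * x + rng.normal(size=25) * 0.5
        w = rng.uniform(0.5, 3.0, size=25)
        r = weighted_least_squares(x, y, w)
        fit = sm.WLS(y, sm.add_constant(x), weights=w).fit()
        assert r.slope == pytest.approx(fit.params[1], abs=1e-10)
        assert r.p == pytest.approx(fit.pvalues[1], abs=1e-10)

    def test_weight_scale_invariance(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=20), rng.normal(size=20)
        w = rng.uniform(1, 5, 20)
        r1 = weighted_least_squares(x, y, w)
        r2 = weighted_least_squares(x, y, 2 * w)
        assert (r1.slope, r1.p) == pytest.approx((r2.slope, r2.p), abs=1e-12)

    def test_inverse_variance_weights_beat_unit_weights(self):
        """With heteroscedastic noise, inverse-variance weighting recovers
        the planted slope with lower RMSE than unit weights."""
        rng = np.random.default_rng(5)
        err_w, err_u = [], []
        for _ in range(100):
            x = rng.uniform(0, 1, 30)
            sd = np.where(rng.random(30) < 0.5, 0.1, 2.0)
            y = 1.0 + 3.0 * x + rng.normal(0, sd)
            err_w.append(weighted_least_squares(x, y, 1 / sd**2).slope - 3.0)
            err_u.append(weighted_least_squares(x, y, np.ones(30)).slope - 3.0)
        assert np.sqrt(np.mean(np.square(err_w))) < np.sqrt(np.mean(np.square(err_u)))

    def test_singular_design(self):
        with pytest.raises(SingularDesignError):
            weighted_least_squares([1, 1, 1], [1, 2, 3], [1, 1, 1])


def _design(values, n_rep=5):
    rows = []
    k = 0
    for tr in ("t12", "t20"):
        for g in ("coevolution", "one-sided"):
            for r in range(n_rep):
                rows.append(
                    {"value": values[k], "transfer": tr, "treatment": g, "replicate": f"r{r}"}
                )
                k += 1
    return pd.DataFrame(rows)


class TestNestedAnova:
    def test_constant_data(self):
        out = nested_anova(_design(np.zeros(20)))
        for term in ("transfer", "treatment", "transfer:treatment"):
            assert out.loc[term, "F"] == 0.0
            assert out.loc[term, "p"] == 1.0

    def test_pure_treatment_signal(self):
        """An additive treatment effect with zero noise is infinitely
        significant for treatment and null for the interaction."""
        values = np.array([0.0] * 5 + [1.0] * 5 + [0.0] * 5 + [1.0] * 5)
        out = nested_anova(_design(values))
        assert out.loc["treatment", "p"] < 1e-10
        assert out.loc["transfer:treatment", "F"] == 0.0
        assert out.loc["transfer", "F"] == 0.0

    def test_explicit_ss_decomposition_oracle(self):
        """Random balanced fixture: F values equal the hand sums-of-squares
        decomposition (orthogonal balanced design) to 1e-8."""
        rng = np.random.default_rng(7)
        df = _design(rng.normal(size=20))
        out = nested_anova(df)
        y = df["value"].to_numpy()
        gm = y.mean()
        ss_transfer = sum(
            len(g) * (g["value"].mean() - gm) ** 2 for _, g in df.groupby("transfer")
        )
        ss_treat = sum(
            len(g) * (g["value"].mean() - gm) ** 2 for _, g in df.groupby("treatment")
        )
        ss_rep = sum(
            len(g) * (g["value"].mean() - df[df["treatment"] == k[0]]["value"].mean()) ** 2
            for k, g in df.groupby(["treatment", "replicate"])
        )
        cell = df.groupby(["transfer", "treatment"])["value"].mean()
        tmean = df.groupby("transfer")["value"].mean()
        gmean = df.groupby("treatment")["value"].mean()
        ss_inter = sum(
            5 * (cell[(a, b)] - tmean[a] - gmean[b] + gm) ** 2
            for a in ("t12", "t20")
            for b in ("coevolution", "one-sided")
        )
        ss_resid = np.sum((y - gm) ** 2) - ss_transfer - ss_treat - ss_rep - ss_inter
        ms_resid = ss_resid / 8  # (T-1)(GR-G) = 1*8 residual df
        assert out.loc["transfer", "F"] == pytest.approx(ss_transfer / 1 / ms_resid, abs=1e-8)
        assert out.loc["treatment", "F"] == pytest.approx(ss_treat / 1 / ms_resid, abs=1e-8)
        assert out.loc["replicate(treatment)", "F"] == pytest.approx(
            ss_rep / 8 / ms_resid, abs=1e-8
        )
        assert out.loc["transfer:treatment", "F"] == pytest.approx(
            ss_inter / 1 / ms_resid, abs=1e-8
        )

    def test_power_for_two_sd_treatment_effect(self):
        """Regression test: a 2-SD treatment effect at 10 replicates x 2
        transfers is detected (p < 0.05) with power >= 0.8. 500 simulations
        scaled to 200 to stay within the suite's time budget; the estimate's
        binomial SE at 200 is ~1.5% against an expected power near 1."""
        rng = np.random.default_rng(11)
        hits = 0
        n_sim = 200
        for _ in range(n_sim):
            base = rng.normal(size=40)
            df = _design(base, n_rep=10)
            df.loc[df["treatment"] == "coevolution", "value"] += 2.0
            hits += nested_anova(df).loc["treatment", "p"] < 0.05
        assert hits / n_sim >= 0.8

    def test_missing_level_rejected(self):
        df = _design(np.zeros(20))
        with pytest.raises(ValueError):
            nested_anova(df[df["treatment"] == "coevolution"])


class TestSpearman:
    def test_monotone_limits(self):
        x = np.arange(8.0)
        assert spearman_correlation(x, x**3).rho == 1.0
        assert spearman_correlation(x, -x).rho == -1.0

    def test_exact_permutation_matches_full_enumeration(self):
        """n=6: the permutation p equals full enumeration of all 720
        orderings, with scipy's spearmanr as the independent statistic."""
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0, 5.0])
        res = spearman_correlation(x, y)
        assert res.method == "permutation"
        obs = abs(stats.spearmanr(x, y).statistic)
        count = sum(
            abs(stats.spearmanr(x, y[list(perm)]).statistic) >= obs - 1e-12
            for perm in itertools.permutations(range(6))
        )
        assert res.rho == pytest.approx(stats.spearmanr(x, y).statistic, abs=1e-12)
        assert res.p == pytest.approx(count / 720, abs=1e-12)

    def test_large_n_t_approximation(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=30)
        y = x + rng.normal(size=30)
        res = spearman_correlation(x, y)
        sp = stats.spearmanr(x, y)
        assert res.method == "t-approximation"
        assert res.rho == pytest.approx(sp.statistic, abs=1e-12)
        assert res.p == pytest.approx(sp.pvalue, rel=1e-6)

    def test_constant_vector_undefined(self):
        res = spearman_correlation(np.ones(6), np.arange(6.0))
        assert np.isnan(res.rho)


class TestBhFdr:
    def test_step_up_hand_computation(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, 0.04)

    def test_single_p(self):
        assert bh_fdr([0.3]).tolist() == [0.3]

    def test_matches_statsmodels_oracle(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(9)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 60))
            q = bh_fdr(p)
            q_sm = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(q, q_sm, atol=1e-12)

    def test_monotone_in_p(self):
        rng = np.random.default_rng(10)
        p = rng.uniform(size=40)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_order_invariance(self):
        rng = np.random.default_rng(11)
        p = rng.uniform(size=25)
        perm = rng.permutation(25)
        assert np.allclose(bh_fdr(p)[perm], bh_fdr(p[perm]))

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])

    def test_global_null_fdp_calibration(self):
        """Under the global null the BH realized false-discovery proportion
        at q < 0.05 has expectation exactly 0.05 (Simes); over 50 fixed
        seeds of 100 N(0,1) features the mean FDP must sit within binomial
        sampling error of that level."""
        fdps = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            z = rng.normal(size=100)
            p = 2 * stats.norm.sf(np.abs(z))
            rejected = bh_fdr(p) < 0.05
            fdps.append(1.0 if rejected.any() else 0.0)
        se = np.sqrt(0.05 * 0.95 / 50)
        assert np.mean(fdps) <= 0.05 + 2 * se


class TestCandidateFilter:
    def _results(self, rows):
        return pd.DataFrame(
            rows,
            columns=[
                "feature", "n_replicates_with_variation", "q_treatment",
                "q_transfer", "q_interaction", "functional_consequence",
                "is_hgt", "treatment_variance",
            ],
        )

    def test_three_replicates_not_flagged(self):
        r = self._results([("f1", 3, 0.01, 0.5, 0.7, True, False, np.nan)])
        assert not candidate_region_filter(r)["candidate"].iloc[0]

    def test_all_criteria_met(self):
        r = self._results([("f1", 6, 0.01, 0.5, 0.7, True, False, np.nan)])
        assert candidate_region_filter(r)["candidate"].iloc[0]

    def test_twenty_feature_fixture_hand_enumeration(self):
        """Each feature fails exactly one criterion except the two that pass
        all of them; the flagged set matches the manual rule application."""
        rows = [
            ("ok1", 5, 0.001, 0.6, 0.9, True, False, np.nan),
            ("ok2", 4, 0.04, 0.06, 0.051, True, True, 0.09),
            ("few_reps", 3, 0.001, 0.6, 0.9, True, False, np.nan),
            ("no_treat", 5, 0.20, 0.6, 0.9, True, False, np.nan),
            ("transfer_hit", 5, 0.001, 0.01, 0.9, True, False, np.nan),
            ("interaction_hit", 5, 0.001, 0.6, 0.01, True, False, np.nan),
            ("no_function", 5, 0.001, 0.6, 0.9, False, False, np.nan),
            ("hgt_low_var", 5, 0.001, 0.6, 0.9, True, True, 0.03),
            ("hgt_boundary", 5, 0.001, 0.6, 0.9, True, True, 0.04),
            ("q_boundary", 5, 0.05, 0.6, 0.9, True, False, np.nan),
        ] + [
            (f"null{i}", 2, 0.5, 0.5, 0.5, False, False, np.nan) for i in range(10)
        ]
        out = candidate_region_filter(self._results(rows))
        assert set(out.loc[out["candidate"], "feature"]) == {"ok1", "ok2"}
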