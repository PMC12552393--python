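"""Statistical layer against closed-form and independent-library oracles."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from statsmodels.stats.anova import anova_lm

from epiradkit import stats


def _welch_oracle(x, y):
    """Brute-force evaluation of the Welch statistic and Satterthwaite df."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    vx, vy = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
    t = (x.mean() - y.mean()) / np.sqrt(vx + vy)
    df = (vx + vy) ** 2 / (vx**2 / (len(x) - 1) + vy**2 / (len(y) - 1))
    p = 2 * scipy.stats.t.sf(abs(t), df)
    return t, df, p


class TestWelch:
    def test_identical_samples(self):
        t, df, p = stats.welch_t_test([1.0, 2, 3], [1.0, 2, 3])
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_matches_formula_oracle(self):
        x, y = [1.0, 2, 3], [1.0, 2, 3, 4, 5, 6]
        t, df, p = stats.welch_t_test(x, y)
        to, dfo, po = _welch_oracle(x, y)
        assert t == pytest.approx(to, rel=1e-12)
        assert df == pytest.approx(dfo, rel=1e-12)
        assert p == pytest.approx(po, rel=1e-9)

    def test_equal_variance_equal_n_df(self):
        """With equal variances and sizes the Satterthwaite df is 2n-2."""
        x = np.array([1.0, 2, 3, 4])
        _, df, _ = stats.welch_t_test(x, x + 10)
        assert df == pytest.approx(2 * len(x) - 2)

    @pytest.mark.parametrize("x,y", [([1.0], [1.0, 2]), ([2.0, 2.0], [3.0, 3.0])])
    def test_degenerate_inputs_raise(self, x, y):
        with pytest.raises(ValueError):
            stats.welch_t_test(x, y)

    def test_null_type_i_error_rate(self):
        """Two Normal samples, equal means, unequal variances: rejection rate
        at alpha=0.05 stays within 0.05 +/- 0.01 over 10,000 replicates."""
        rng = np.random.default_rng(123)
        n_rep, n1, n2 = 10_000, 12, 8
        x = rng.normal(0.0, 1.0, size=(n_rep, n1))
        y = rng.normal(0.0, 2.5, size=(n_rep, n2))
        res = scipy.stats.ttest_ind(x, y, axis=1, equal_var=False)
        rate = float(np.mean(res.pvalue < 0.05))
        # vectorised scipy call is the same Welch computation the package wraps
        assert abs(rate - 0.05) < 0.01


class TestModelSpec:
    def test_interaction_requires_main_effects(self):
        with pytest.raises(ValueError, match="requires main effect"):
            stats.ModelSpec("y", ("AGE×SEX",))

    def test_unknown_term_rejected(self):
        with pytest.raises(ValueError, match="unknown terms"):
            stats.ModelSpec("y", ("WEIGHT",))

    def test_formula_rendering(self):
        spec = stats.ModelSpec("y", ("AGE", "SEX"))
        assert spec.formula.startswith("y ~ ")
        assert "Treatment('AGE1')" in spec.formula


class TestOLS:
    def test_exact_linear_response(self):
        data = pd.DataFrame({"fin_value": np.arange(10.0)})
        data["y"] = 2.0 + 3.0 * data.fin_value
        fit = stats.fit_linear_model(stats.ModelSpec("y", ("fin_value",)), data)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.rss == pytest.approx(0.0, abs=1e-18)

    def test_normal_equation_oracle(self):
        """n=5 toy solved by the normal equations directly."""
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([2.0, 4, 5, 4, 5])
        X = np.column_stack([np.ones(5), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        data = pd.DataFrame({"fin_value": x, "y": y})
        fit = stats.fit_linear_model(stats.ModelSpec("y", ("fin_value",)), data)
        assert fit.coef.loc["Intercept", "estimate"] == pytest.approx(beta[0])
        assert fit.coef.loc["fin_value", "estimate"] == pytest.approx(beta[1])
        # hand solution for this table: intercept 2.2, slope 0.6
        assert beta == pytest.approx([2.2, 0.6])

    def test_residuals_orthogonal_to_design(self, small_dataset):
        telo = small_dataset.telomeres
        sub = telo[telo.tissue == "fin"].rename(columns={"median_kb": "response"})
        fit = stats.fit_linear_model(
            stats.ModelSpec("response", ("AGE", "SEX")), sub
        )
        X = fit.result.model.exog
        assert np.allclose(X.T @ fit.result.resid, 0.0, atol=1e-8)

    def test_adjusted_r2_not_above_r2(self, small_dataset):
        telo = small_dataset.telomeres
        sub = telo[telo.tissue == "gonad"].rename(columns={"median_kb": "response"})
        fit = stats.fit_linear_model(
            stats.ModelSpec("response", ("AGE", "SEX")), sub
        )
        assert fit.adj_r_squared <= fit.r_squared

    def test_rank_deficiency_raises(self):
        data = pd.DataFrame(
            {"fin_value": [1.0, 2, 3, 4], "body_size_mm": [2.0, 4, 6, 8],
             "y": [1.0, 2, 3, 4]}
        )
        with pytest.raises(ValueError, match="rank-deficient"):
            stats.fit_linear_model(
                stats.ModelSpec("y", ("fin_value", "body_size")), data
            )


class TestAicc:
    def test_plugged_in_value(self):
        # k=2, n=10, llf=-12.5 -> AIC 29 plus correction 12/7
        assert stats.aicc(-12.5, n_coef=1, nobs=10) == pytest.approx(29 + 12 / 7)

    def test_converges_to_aic_for_large_n(self):
        llf, n_coef = -100.0, 3
        aic = -2 * llf + 2 * (n_coef + 1)
        diffs = [stats.aicc(llf, n_coef, n) - aic for n in (20, 200, 2000)]
        assert diffs[0] > diffs[1] > diffs[2]
        assert diffs[2] < 0.05

    def test_undefined_for_tiny_n(self):
        with pytest.raises(ValueError, match="AICc undefined"):
            stats.aicc(-1.0, n_coef=3, nobs=5)

    def test_useless_parameter_never_lowers_aicc_at_fixed_fit(self):
        """Same log-likelihood, one more parameter -> strictly larger AICc."""
        for k in range(1, 5):
            assert stats.aicc(-10.0, k + 1, 30) > stats.aicc(-10.0, k, 30)


class TestSelection:
    def _structured(self, n=60, effect=5.0, seed=0):
        rng = np.random.default_rng(seed)
        age = np.repeat(["AGE1", "AGE2", "AGE3"], n // 3)
        sex = np.tile(["F", "M"], n // 2)
        y = (effect * (age == "AGE3") + rng.normal(0, 1, n))
        return pd.DataFrame({"age_group": age, "sex": sex, "response": y})

    def test_structured_data_prefers_structured_model(self):
        data = self._structured(effect=5.0)
        table, _ = stats.select_model(
            [stats.ModelSpec("response", (), name="empty"),
             stats.ModelSpec("response", ("AGE", "SEX"), name="AGE+SEX")],
            data,
        )
        assert table.name.iloc[0] == "AGE+SEX"

    def test_null_data_prefers_empty_model_in_majority(self):
        wins = 0
        for seed in range(40):
            data = self._structured(effect=0.0, seed=seed)
            table, _ = stats.select_model(
                [stats.ModelSpec("response", (), name="empty"),
                 stats.ModelSpec("response", ("AGE", "SEX"), name="AGE+SEX")],
                data,
            )
            wins += table.name.iloc[0] == "empty"
        assert wins > 20

    def test_selection_consistency_grows_with_effect(self):
        """Probability of picking the generating model rises with effect size."""
        def win_rate(effect):
            wins = 0
            for seed in range(30):
                data = self._structured(effect=effect, seed=100 + seed)
                table, _ = stats.select_model(
                    [stats.ModelSpec("response", (), name="empty"),
                     stats.ModelSpec("response", ("AGE", "SEX"), name="AGE+SEX")],
                    data,
                )
                wins += table.name.iloc[0] == "AGE+SEX"
            return wins / 30
        assert win_rate(2.0) >= win_rate(0.2)
        assert win_rate(2.0) > 0.9

    def test_single_candidate_returned(self):
        data = self._structured()
        table, fits = stats.select_model(
            [stats.ModelSpec("response", (), name="empty")], data
        )
        assert table.name.tolist() == ["empty"]
        assert table.delta_aicc.iloc[0] == 0.0

    def test_differing_row_subsets_raise(self):
        data = self._structured()
        data.loc[0, "age_group"] = np.nan
        with pytest.raises(ValueError, match="differing row subsets"):
            stats.select_model(
                [stats.ModelSpec("response", (), name="empty"),
                 stats.ModelSpec("response", ("AGE", "SEX"), name="AGE+SEX")],
                data,
            )


class TestEstimatedMeans:
    def test_intercept_only_gives_grand_mean(self):
        data = pd.DataFrame(
            {"response": [1.0, 2, 3, 4], "age_group": ["AGE1"] * 4,
             "sex": ["F", "M", "F", "M"]}
        )
        fit = stats.fit_linear_model(stats.ModelSpec("response", ()), data)
        grid = pd.DataFrame({"age_group": ["AGE1"], "sex": ["F"]})
        means = stats.estimated_means(fit, grid)
        assert means["mean"].iloc[0] == pytest.approx(2.5)

    def test_balanced_one_factor_equals_group_means(self):
        data = pd.DataFrame(
            {"response": [1.0, 3, 2, 6], "sex": ["F", "F", "M", "M"]}
        )
        fit = stats.fit_linear_model(stats.ModelSpec("response", ("SEX",)), data)
        means = stats.estimated_means(fit, pd.DataFrame({"sex": ["F", "M"]}))
        assert means["mean"].tolist() == pytest.approx([2.0, 4.0])

    def test_ci_width_shrinks_with_replication(self):
        rng = np.random.default_rng(5)

        def width(n):
            data = pd.DataFrame(
                {"response": rng.normal(0, 1, n), "sex": ["F", "M"] * (n // 2)}
            )
            fit = stats.fit_linear_model(stats.ModelSpec("response", ("SEX",)), data)
            m = stats.estimated_means(fit, pd.DataFrame({"sex": ["F"]}))
            return float(m.ci_high.iloc[0] - m.ci_low.iloc[0])

        assert width(400) < width(40) < width(8)

    def test_unseen_level_raises(self):
        data = pd.DataFrame(
            {"response": [1.0, 2, 3, 4], "sex": ["F", "M", "F", "M"]}
        )
        fit = stats.fit_linear_model(stats.ModelSpec("response", ("SEX",)), data)
        with pytest.raises(ValueError, match="not in fitted data"):
            stats.estimated_means(fit, pd.DataFrame({"sex": ["X"]}))


class TestTermFTests:
    def _data(self, n=32, seed=1):
        rng = np.random.default_rng(seed)
        age = np.array((["AGE1"] * 10) + (["AGE2"] * 11) + (["AGE3"] * 11))[:n]
        sex = np.array((["F", "M"] * 16))[:n]
        y = 1.0 * (age == "AGE3") + 0.5 * (sex == "M") + rng.normal(0, 1, n)
        return pd.DataFrame({"age_group": age, "sex": sex, "response": y})

    def test_age_has_two_numerator_df(self):
        fit = stats.fit_linear_model(
            stats.ModelSpec("response", ("AGE", "SEX")), self._data()
        )
        table = stats.term_f_tests(fit).set_index("term")
        assert table.loc["AGE", "df1"] == 2
        assert table.loc["AGE", "df2"] == 28  # n=32 minus 4 coefficients

    def test_two_level_factor_f_equals_t_squared(self):
        data = self._data()
        fit = stats.fit_linear_model(stats.ModelSpec("response", ("SEX",)), data)
        table = stats.term_f_tests(fit).set_index("term")
        t = fit.coef.loc["C(sex, Treatment('F'))[T.M]", "t"]
        assert table.loc["SEX", "F"] == pytest.approx(t**2, rel=1e-10)

    def test_matches_statsmodels_type_ii_anova(self):
        """Independent cross-check: additive model Type II table from
        statsmodels agrees with the drop-term implementation."""
        data = self._data()
        fit = stats.fit_linear_model(
            stats.ModelSpec("response", ("AGE", "SEX")), data
        )
        ours = stats.term_f_tests(fit).set_index("term")
        theirs = anova_lm(fit.result, typ=2)
        assert ours.loc["AGE", "F"] == pytest.approx(
            theirs.loc["C(age_group, Treatment('AGE1'))", "F"], rel=1e-8
        )
        assert ours.loc["SEX", "F"] == pytest.approx(
            theirs.loc["C(sex, Treatment('F'))", "F"], rel=1e-8
        )

    def test_null_term_rejection_rate_near_alpha(self):
        """A term with zero true effect is rejected at ~5%."""
        rejections = 0
        n_rep = 400
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            data = self._data(seed=seed)
            data["response"] = rng.normal(0, 1, len(data))
            fit = stats.fit_linear_model(
                stats.ModelSpec("response", ("AGE", "SEX")), data
            )
            table = stats.term_f_tests(fit).set_index("term")
            rejections += table.loc["AGE", "p"] < 0.05
        rate = rejections / n_rep
        assert abs(rate - 0.05) < 0.03

    def test_main_effect_with_interaction_uses_marginal_models(self, caplog):
        import logging

        data = self._data()
        fit = stats.fit_linear_model(
            stats.ModelSpec("response", ("AGE", "SEX", "AGE×SEX")), data
        )
        with caplog.at_level(logging.INFO, logger="epiradkit.stats"):
            table = stats.term_f_tests(fit).set_index("term")
        assert "excluded" in caplog.text
        # the AGE test must equal the one from the additive model
        additive = stats.fit_linear_model(
            stats.ModelSpec("response", ("AGE", "SEX")), data
        )
        expected = stats.term_f_tests(additive).set_index("term")
        assert table.loc["AGE", "F"] == pytest.approx(expected.loc["AGE", "F"])


class TestQQ:
    def test_normal_residuals_near_unit_slope(self):
        rng = np.random.default_rng(7)
        data = pd.DataFrame(
            {"response": rng.normal(0, 1, 500), "sex": ["F", "M"] * 250}
        )
        fit = stats.fit_linear_model(stats.ModelSpec("response", ("SEX",)), data)
        qq = stats.qq_normality_check(fit)
        slope = np.polyfit(qq.theoretical, qq["sample"], 1)[0]
        assert slope == pytest.approx(1.0, abs=0.1)

    def test_heavy_tails_detectable(self):
        """Cauchy-like residuals deviate more from the normal line."""
        rng = np.random.default_rng(8)

        def max_dev(values):
            data = pd.DataFrame({"response": values, "sex": ["F", "M"] * 250})
            fit = stats.fit_linear_model(stats.ModelSpec("response", ("SEX",)), data)
            qq = stats.qq_normality_check(fit)
            return float(np.max(np.abs(qq["sample"] - qq.theoretical)))

        normal = max_dev(rng.normal(0, 1, 500))
        heavy = max_dev(rng.standard_t(1, 500))
        assert heavy > normal

    def test_single_observation(self):
        data = pd.DataFrame({"response": [3.0], "sex": ["F"]})
        fit = stats.fit_linear_model(stats.ModelSpec("response", ()), data)
        qq = stats.qq_normality_check(fit)
        assert len(qq) == 1
        assert qq.theoretical.iloc[0] == pytest.approx(0.0)
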