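import numpy as np
import pandas as pd
import pytest

from qpref import (
    factor_score_anova,
    fit_ordered_probit,
    lr_variable_test,
    nominal_test,
    preference_by_factor_model,
    scale_test,
    wald_variable_test,
    weights_anova,
    worked_example,
)


@pytest.fixture(scope="module")
def standin_fit(request):
    from qpref.synthetic import packaged_fixture

    data, design, _ = packaged_fixture()
    return fit_ordered_probit(data, design), data, design


def oneway_oracle(y, labels):
    """Closed-form one-way ANOVA F from group means and total SS."""
    y = np.asarray(y, float)
    grand = y.mean()
    total_ss = ((y - grand) ** 2).sum()
    groups = pd.Series(y).groupby(list(labels))
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for _, g in groups)
    df1 = groups.ngroups - 1
    df2 = len(y) - groups.ngroups
    return (ssb / df1) / ((total_ss - ssb) / df2)


class TestOrderedProbitPreference:
    def test_pooled_observation_count(self, standin_fit):
        fit, data, _ = standin_fit
        assert fit.results.model.nobs == data.n_stimuli * data.n_participants

    def test_reference_levels_from_design(self, standin_fit):
        fit, _, design = standin_fit
        table = fit.coefficient_table()
        # references (first listed levels) never appear as terms
        for ref in ["SizeLarge", "TextureRough", "ContourAngular",
                    "BehaviorQuiescent"]:
            assert ref not in set(table["term"])
        assert {"SizeSmall", "TextureSmooth", "ContourRound",
                "BehaviorVibrate", "BehaviorLight", "BehaviorSound"} <= set(
            table["term"]
        )

    def test_wald_block_df(self, standin_fit):
        fit, _, _ = standin_fit
        wald = wald_variable_test(fit).set_index("variable")
        assert wald.loc["Size", "df"] == 1
        assert wald.loc["Behavior", "df"] == 3
        assert (wald["statistic"] >= 0).all()

    def test_wald_equals_z_squared_single_df(self, standin_fit):
        fit, _, _ = standin_fit
        z = fit.results.zvalues["SizeSmall"]
        wald = wald_variable_test(fit, "Size").iloc[0]
        assert wald["statistic"] == pytest.approx(float(z**2), abs=1e-6)

    def test_assumption_tests_nonnegative_with_correct_df(self, standin_fit):
        fit, _, _ = standin_fit
        nom = nominal_test(fit).set_index("variable")
        sca = scale_test(fit).set_index("variable")
        J = fit.results.model.n_cat
        assert nom.loc["Size", "df"] == J - 2
        assert nom.loc["Behavior", "df"] == 3 * (J - 2)
        assert sca.loc["Size", "df"] == 1
        assert sca.loc["Behavior", "df"] == 3
        assert (nom["statistic"].dropna() >= 0).all()
        assert (sca["statistic"].dropna() >= 0).all()

    def test_lr_variable_test_agrees_with_wald_in_magnitude(self, standin_fit):
        fit, _, _ = standin_fit
        wald = wald_variable_test(fit).set_index("variable")["statistic"]
        lrt = lr_variable_test(fit).set_index("variable")["statistic"]
        # asymptotically equivalent tests: same order of magnitude
        ratio = (lrt / wald).replace([np.inf], np.nan).dropna()
        assert ((ratio > 0.5) & (ratio < 2.0)).all()


class TestWeightsAnova:
    def test_brute_force_sums_of_squares(self, rng):
        weights = pd.DataFrame(
            rng.random((9, 3)), columns=["A", "B", "C"],
            index=[f"P{i}" for i in range(9)],
        )
        _, anova = weights_anova(weights)
        long = weights.stack()
        F = oneway_oracle(long.to_numpy(),
                          long.index.get_level_values(1))
        assert anova.set_index("term").loc["variable", "F"] == pytest.approx(F)
        assert anova.set_index("term").loc["Residual", "df"] == 9 * 3 - 3

    def test_printed_weights_reproduce_published_lm(self):
        weights = worked_example.participant_weights()
        coef, anova = weights_anova(weights)
        coef = coef.set_index("term")
        assert coef.loc["Intercept", "estimate"] == pytest.approx(0.13, abs=0.005)
        assert coef.loc["Behavior", "estimate"] == pytest.approx(0.37, abs=0.005)
        assert anova.set_index("term").loc["Residual", "df"] == 68

    def test_interaction_form_uses_flagged_only(self):
        weights = worked_example.participant_weights()
        flags = worked_example.factor_flags()
        coef, anova = weights_anova(weights, factors=flags)
        assert anova.set_index("term").loc["Residual", "df"] == 56  # 17*4 - 12
        terms = set(coef["term"])
        assert "Behavior*F3" in terms

    def test_factor_without_flagged_units_errors(self):
        weights = worked_example.participant_weights()
        flags = pd.Series(None, index=weights.index, dtype=object)
        with pytest.raises(ValueError, match="flagged"):
            weights_anova(weights, factors=flags)


class TestFactorScoreAnova:
    def test_matches_closed_form_on_any_valid_column(self, io_design, io_grid, rng):
        scores = pd.DataFrame(
            {"F1": rng.permutation(io_grid.multiset())},
            index=io_design.stimulus_ids,
        )
        # the canonical grid's total SS is fixed at 200 for every valid sort
        assert ((scores["F1"] - scores["F1"].mean()) ** 2).sum() == 200
        table = factor_score_anova(scores, io_design).set_index("variable")
        for v in io_design.variables:
            labels = io_design.level_of(v)
            expected = oneway_oracle(scores["F1"].to_numpy(), labels)
            assert table.loc[v, "F"] == pytest.approx(expected)

    def test_dfs_follow_level_counts(self, io_design, io_scores):
        table = factor_score_anova(io_scores, io_design)
        sub = table[table["factor"] == "F1"].set_index("variable")
        assert (sub.loc[["Size", "Texture", "Contour"], "df1"] == 1).all()
        assert (sub.loc[["Size", "Texture", "Contour"], "df2"] == 30).all()
        assert sub.loc["Behavior", ["df1", "df2"]].tolist() == [3, 28]

    def test_degenerate_grouping_flagged(self):
        ids = [f"S{i}" for i in range(4)]
        from qpref import VariableDesign

        design = VariableDesign(
            ids, pd.DataFrame({"V": ["x", "x", "y", "y"]}, index=ids)
        )
        scores = pd.DataFrame({"F1": [1.0, 1.0, 2.0, 2.0]}, index=ids)
        row = factor_score_anova(scores, design).iloc[0]
        assert np.isinf(row["F"]) and row["degenerate"]


class TestPreferenceByFactor:
    def test_interaction_dfs(self, io_scores, io_design):
        _, wald = preference_by_factor_model(io_scores, io_design)
        wald = wald.set_index("variable")
        assert wald.loc["Factor*Size", "df"] == 2
        assert wald.loc["Factor*Behavior", "df"] == 6

    def test_identical_profiles_zero_interactions(self, io_scores, io_design):
        same = pd.DataFrame(
            {f: io_scores["F1"] for f in ["F1", "F2", "F3"]}
        )
        fit, _ = preference_by_factor_model(same, io_design)
        inter = [t for t in fit.terms if t.startswith("Factor*")]
        for block in inter:
            for term in fit.terms[block]:
                assert fit.results.params_series[term] == pytest.approx(
                    0.0, abs=1e-4
                )
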