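"""Group statistics: Type III ANOVA, correlation, PCA, OLS regression."""

import math

import numpy as np
import pandas as pd
import pytest

from songsyntax import (
    anova_table,
    generate_metrics_table,
    ols_regression,
    pca_unrotated,
    pearson_correlation,
    regressions_by_sex,
    two_way_anova,
)
from songsyntax.types import ValidationError

# Unbalanced 2x2 layout; expected values frozen from an independent
# sum-contrast Type III computation (R car::Anova, type = 3).
UNBALANCED = pd.DataFrame(
    {
        "treatment": ["T", "T", "T", "T", "T", "T+E2", "T+E2", "T+E2", "T+E2",
                      "T+E2", "T+E2", "T", "T", "T+E2"],
        "sex": ["male", "male", "male", "female", "female", "male", "male",
                "female", "female", "female", "female", "female", "male", "male"],
        "y": [12.0, 15, 14, 6, 7, 13, 11, 5, 9, 8, 6, 7, 16, 12],
    }
)

R_CAR_ANOVA = {
    "treatment": (1.470261, 0.2531723, 0.1281803),
    "sex": (63.37132, 1.229486e-05, 0.863707),
    "interaction": (2.670928, 0.1332433, 0.2107918),
}


def test_type3_anova_matches_independent_computation():
    res = two_way_anova(UNBALANCED, "y")
    assert res.n_obs == 14
    for term, (f_exp, p_exp, eta_exp) in R_CAR_ANOVA.items():
        t = res[term]
        assert t.F == pytest.approx(f_exp, rel=1e-5)
        assert t.p == pytest.approx(p_exp, rel=1e-4)
        assert t.partial_eta_sq == pytest.approx(eta_exp, rel=1e-5)
        assert t.df_num == 1.0 and t.df_den == 10.0


def test_anova_equal_cell_means_give_zero_f():
    rows = []
    for trt in ("T", "T+E2"):
        for sex in ("male", "female"):
            rows += [{"treatment": trt, "sex": sex, "y": v} for v in (9.0, 10.0, 11.0)]
    res = two_way_anova(pd.DataFrame(rows), "y")
    for term in ("treatment", "sex", "interaction"):
        assert res[term].F == pytest.approx(0.0, abs=1e-10)
        assert res[term].partial_eta_sq == pytest.approx(0.0, abs=1e-12)


def test_anova_empty_cell_error_names_the_cell():
    df = UNBALANCED[~((UNBALANCED.treatment == "T+E2") & (UNBALANCED.sex == "female"))]
    with pytest.raises(ValidationError, match="T\\+E2"):
        two_way_anova(df, "y")


def test_anova_constant_response_gives_nan_f():
    df = UNBALANCED.assign(y=5.0)
    res = two_way_anova(df, "y")
    assert math.isnan(res["sex"].F)


def test_partial_eta_squared_invariant_to_affine_response_rescale():
    res1 = two_way_anova(UNBALANCED, "y")
    res2 = two_way_anova(UNBALANCED.assign(y=UNBALANCED.y * 3.7 - 12.0), "y")
    for term in ("treatment", "sex", "interaction"):
        assert res1[term].partial_eta_sq == pytest.approx(res2[term].partial_eta_sq)
        assert res1[term].F == pytest.approx(res2[term].F)


def test_anova_table_listwise_drop_reduces_df_for_network_rows():
    table = generate_metrics_table(seed=5)
    table.loc[table.index[:2], ["network_path_length", "network_density"]] = np.nan
    out = anova_table(table)
    out = out.set_index("metric")
    assert out.loc["syllable_type_repertoire", "sex_df2"] == 24.0
    assert out.loc["network_path_length", "sex_df2"] == 22.0
    assert out.loc["network_density", "sex_df2"] == 22.0


@pytest.mark.parametrize(
    "x, y, expected",
    [
        ([1, 2, 3, 4], [3, 5, 7, 9], 1.0),  # y = 2x + 1
        ([1, 2, 3, 4], [-1, -2, -3, -4], -1.0),
        ([1, 2, 3, 4], [1, 3, 2, 4], 0.8),
    ],
)
def test_pearson_known_values(x, y, expected):
    assert pearson_correlation(x, y) == pytest.approx(expected)


def test_pearson_rejects_constant_or_short_input():
    with pytest.raises(ValidationError):
        pearson_correlation([1, 1, 1], [1, 2, 3])
    with pytest.raises(ValidationError):
        pearson_correlation([1, 2], [1, 2])


def test_pca_two_variable_closed_form():
    rng = np.random.default_rng(0)
    x = rng.normal(size=200)
    y = 0.6 * x + 0.8 * rng.normal(size=200)
    df = pd.DataFrame({"x": x, "y": y})
    rho = pearson_correlation(x, y)
    res = pca_unrotated(df)
    assert res.eigenvalues == pytest.approx([1 + rho, 1 - rho])
    assert res.proportion_explained == pytest.approx([(1 + rho) / 2, (1 - rho) / 2])


def test_pca_eigenvalues_sum_to_variable_count_and_scores_match():
    table = generate_metrics_table(seed=11)
    cols = [c for c in table.columns if c not in ("bird_id", "sex", "treatment")]
    res = pca_unrotated(table, variables=cols)
    assert res.eigenvalues.sum() == pytest.approx(len(cols))
    assert np.all(np.diff(res.eigenvalues) <= 1e-12)
    assert res.proportion_explained.sum() == pytest.approx(1.0)
    # scores are uncorrelated with variance equal to the eigenvalues
    scores = res.scores.to_numpy()
    cov = np.cov(scores, rowvar=False)
    assert np.allclose(np.diag(cov), res.eigenvalues, atol=1e-10)
    off = cov - np.diag(np.diag(cov))
    assert np.all(np.abs(off) < 1e-10)
    # sign convention: dominant loading of each component is positive
    for comp in res.loadings.columns:
        col = res.loadings[comp]
        assert col.iloc[np.argmax(np.abs(col.to_numpy()))] > 0


def test_pca_constant_variable_error_names_it():
    df = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [2.0, 2, 2, 2], "c": [0.5, 1, 2, 4]})
    with pytest.raises(ValidationError, match="b"):
        pca_unrotated(df)


def test_pca_drops_and_reports_incomplete_rows():
    table = generate_metrics_table(seed=3)
    table.loc[table.index[0], "network_density"] = np.nan
    res = pca_unrotated(table, variables=["network_density", "network_path_length", "svi"])
    assert res.dropped_rows == [table.index[0]]
    assert len(res.scores) == len(table) - 1


def test_ols_exact_linear_relationship_gives_r2_one():
    rng = np.random.default_rng(1)
    x = pd.DataFrame({"a": rng.normal(size=10), "b": rng.normal(size=10)})
    y = 2.0 * x["a"] + 1.0
    res = ols_regression(y, x)
    assert res.r_squared == pytest.approx(1.0)
    assert res.coefficients.loc["a", "estimate"] == pytest.approx(2.0)
    assert res.coefficients.loc["b", "estimate"] == pytest.approx(0.0, abs=1e-10)


def test_ols_intercept_only_recovers_mean():
    y = pd.Series([1.0, 2.0, 4.0, 5.0])
    res = ols_regression(y, pd.DataFrame(index=y.index))
    assert res.coefficients.loc["const", "estimate"] == pytest.approx(3.0)


def test_ols_matches_normal_equations_on_toy_design():
    x = pd.DataFrame({"u": [0.0, 1, 2, 3, 4, 5], "v": [1.0, 0, 1, 0, 1, 0]})
    y = pd.Series([3.0, 4, 7, 8, 11, 12])
    design = np.column_stack([np.ones(6), x.to_numpy()])
    beta = np.linalg.solve(design.T @ design, design.T @ y.to_numpy())
    res = ols_regression(y, x)
    assert res.coefficients["estimate"].to_numpy() == pytest.approx(beta)


def test_ols_rank_deficient_design_names_collinear_columns():
    x = pd.DataFrame({"a": [1.0, 2, 3, 4, 5, 6], "twice_a": [2.0, 4, 6, 8, 10, 12]})
    y = pd.Series([1.0, 2, 1, 2, 1, 2])
    with pytest.raises(ValidationError, match="collinear"):
        ols_regression(y, x)


def test_regressions_by_sex_shapes_and_planted_null():
    table = generate_metrics_table(seed=21)
    cols = [c for c in table.columns if c.endswith(("repertoire", "_song", "_second")) or c in ("svi", "levenshtein_distance")]
    pca = pca_unrotated(table, variables=cols)
    out = regressions_by_sex(table, pca.scores[["PC1", "PC2", "PC3"]])
    # 2 sexes x 3 components x (4 predictors + intercept)
    assert len(out) == 2 * 3 * 5
    assert set(out["predictor"]) == {"const", "hvc_volume", "ra_volume", "x_volume", "body_mass"}
    # male model df: 12+ birds, 4 predictors -> df1 = 4
    assert (out["model_df1"] == 4.0).all()
    assert ((out["model_r2"] >= 0) & (out["model_r2"] <= 1)).all()
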