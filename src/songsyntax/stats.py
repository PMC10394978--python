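"""Group-level statistics for per-bird metric tables.

The analysis design is a two-factor crossed layout (hormone treatment x sex)
with modestly unbalanced cells, so the two-way ANOVA uses Type III (marginal)
sums of squares with sum-to-zero factor coding.  Effect sizes are partial
eta squared, ``SS_effect / (SS_effect + SS_residual)``.

Dimension reduction standardizes each metric to mean 0 / SD 1 and
eigendecomposes the resulting correlation matrix (unrotated PCA); component
scores feed per-sex ordinary least-squares regressions on the volumes of the
vocal control nuclei (HVC, RA, Area X) with body mass as a covariate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from .types import DIVERSITY_COLUMNS, METRIC_COLUMNS, SongSyntaxError, ValidationError

ANOVA_TERMS = ("treatment", "sex", "interaction")


@dataclass(frozen=True)
class TermResult:
    F: float
    df_num: float
    df_den: float
    p: float
    partial_eta_sq: float


@dataclass
class AnovaResult:
    """Two-way ANOVA for one metric: one :class:`TermResult` per term."""

    metric: str
    terms: dict[str, TermResult]
    n_obs: int

    def __getitem__(self, term: str) -> TermResult:
        return self.terms[term]


def two_way_anova(
    table: pd.DataFrame,
    metric: str,
    factors: tuple[str, str] = ("treatment", "sex"),
) -> AnovaResult:
    """Type III two-way ANOVA of ``metric`` on two crossed factors.

    Rows with a missing response are dropped (listwise per metric).  Every
    factor-level cell must keep at least one observation.  A constant
    response yields ``nan`` F statistics rather than an error.
    """
    fa, fb = factors
    data = table.dropna(subset=[metric])
    cells = data.groupby([fa, fb], observed=True).size()
    levels_a = data[fa].unique()
    levels_b = data[fb].unique()
    for la in levels_a:
        for lb in levels_b:
            if (la, lb) not in cells.index:
                raise ValidationError(f"empty cell: {fa}={la!r}, {fb}={lb!r}")

    if np.ptp(data[metric].to_numpy(dtype=float)) == 0:
        nan_term = TermResult(math.nan, 1.0, float(len(data) - 4), math.nan, math.nan)
        return AnovaResult(
            metric=metric,
            terms={fa: nan_term, fb: nan_term, "interaction": nan_term},
            n_obs=len(data),
        )

    formula = f"Q('{metric}') ~ C(Q('{fa}'), Sum) * C(Q('{fb}'), Sum)"
    fit = smf.ols(formula, data=data).fit()
    aov = anova_lm(fit, typ=3)

    names = {
        fa: f"C(Q('{fa}'), Sum)",
        fb: f"C(Q('{fb}'), Sum)",
        "interaction": f"C(Q('{fa}'), Sum):C(Q('{fb}'), Sum)",
    }
    ss_resid = float(aov.loc["Residual", "sum_sq"])
    df_resid = float(aov.loc["Residual", "df"])
    terms: dict[str, TermResult] = {}
    for label, row_name in names.items():
        ss = float(aov.loc[row_name, "sum_sq"])
        df_num = float(aov.loc[row_name, "df"])
        f_val = float(aov.loc[row_name, "F"])
        p_val = float(aov.loc[row_name, "PR(>F)"])
        denom = ss + ss_resid
        eta = ss / denom if denom > 0 else math.nan
        terms[label] = TermResult(f_val, df_num, df_resid, p_val, eta)
    return AnovaResult(metric=metric, terms=terms, n_obs=len(data))


def anova_table(
    table: pd.DataFrame,
    metrics: Sequence[str] | None = None,
    factors: tuple[str, str] = ("treatment", "sex"),
) -> pd.DataFrame:
    """Two-way ANOVAs for several metrics, one row per metric.

    Missing metric values (e.g. network metrics of excluded birds) reduce
    that row's residual df only.  Columns are ``<term>_F``, ``<term>_df1``,
    ``<term>_df2``, ``<term>_p``, ``<term>_eta_p2`` for each of treatment,
    sex and interaction.
    """
    if metrics is None:
        metrics = [m for m in METRIC_COLUMNS if m in table.columns]
    rows = []
    for metric in metrics:
        res = two_way_anova(table, metric, factors=factors)
        row: dict[str, object] = {"metric": metric, "n": res.n_obs}
        for term in ANOVA_TERMS:
            t = res[term]
            row.update(
                {
                    f"{term}_F": t.F,
                    f"{term}_df1": t.df_num,
                    f"{term}_df2": t.df_den,
                    f"{term}_p": t.p,
                    f"{term}_eta_p2": t.partial_eta_sq,
                }
            )
        rows.append(row)
    return pd.DataFrame(rows)


def pearson_correlation(x: Iterable[float], y: Iterable[float]) -> float:
    """Pearson product-moment correlation coefficient."""
    xv = np.asarray(list(x), dtype=float)
    yv = np.asarray(list(y), dtype=float)
    if xv.shape != yv.shape or xv.size < 3:
        raise ValidationError("pearson correlation needs two equal-length vectors, n >= 3")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise ValidationError("pearson correlation undefined for a constant input")
    return float(scipy.stats.pearsonr(xv, yv).statistic)


@dataclass
class PcaResult:
    """Unrotated PCA of standardized variables (correlation matrix).

    ``loadings`` is variables x components (columns PC1, PC2, ...); each
    component's sign is fixed so its largest-magnitude loading is positive.
    ``scores`` (rows = input rows) have variance equal to the eigenvalues.
    """

    eigenvalues: np.ndarray
    proportion_explained: np.ndarray
    loadings: pd.DataFrame
    scores: pd.DataFrame
    dropped_rows: list = field(default_factory=list)


def pca_unrotated(table: pd.DataFrame, variables: Sequence[str] | None = None) -> PcaResult:
    """PCA of the correlation matrix of the selected columns.

    Rows with any missing value among ``variables`` are dropped (and listed
    in ``dropped_rows``); a constant column is an error.
    """
    if variables is None:
        variables = list(table.columns)
    sub = table[list(variables)]
    keep = sub.notna().all(axis=1)
    dropped = list(sub.index[~keep])
    sub = sub.loc[keep]
    if sub.shape[1] < 2 or sub.shape[0] < 3:
        raise ValidationError("PCA needs >= 2 variables and >= 3 complete rows")
    x = sub.to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [v for v, s in zip(variables, sd) if s == 0]
        raise ValidationError(f"constant variable(s) in PCA input: {bad}")
    z = (x - x.mean(axis=0)) / sd
    corr = np.corrcoef(z, rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = eigvec[:, order]
    # sign convention: the largest-magnitude loading of each component is positive
    for j in range(eigvec.shape[1]):
        k = np.argmax(np.abs(eigvec[:, j]))
        if eigvec[k, j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    comps = [f"PC{i + 1}" for i in range(len(eigval))]
    loadings = pd.DataFrame(eigvec, index=list(variables), columns=comps)
    scores = pd.DataFrame(z @ eigvec, index=sub.index, columns=comps)
    return PcaResult(
        eigenvalues=eigval,
        proportion_explained=eigval / eigval.sum(),
        loadings=loadings,
        scores=scores,
        dropped_rows=dropped,
    )


@dataclass
class RegressionResult:
    """OLS fit summary: per-predictor table plus model-level F, df and R^2."""

    coefficients: pd.DataFrame  # index = predictors + const; estimate, se, t, p
    f_statistic: float
    df_model: float
    df_resid: float
    f_pvalue: float
    r_squared: float
    n_obs: int


def ols_regression(response: pd.Series, predictors: pd.DataFrame) -> RegressionResult:
    """Ordinary least squares of ``response`` on ``predictors`` with intercept."""
    y = pd.Series(response).astype(float)
    x = predictors.astype(float)
    if len(y) < x.shape[1] + 2:
        raise ValidationError(
            f"regression needs >= {x.shape[1] + 2} rows for {x.shape[1]} predictors"
        )
    design = sm.add_constant(x, has_constant="add")
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        _, s, vt = np.linalg.svd(design.to_numpy())
        weights = np.abs(vt[-1])
        suspects = [c for c, w in zip(design.columns, weights) if w > 0.1]
        raise ValidationError(f"rank-deficient design; collinear columns involve {suspects}")
    fit = sm.OLS(y, design).fit()
    coefs = pd.DataFrame(
        {
            "estimate": fit.params,
            "se": fit.bse,
            "t": fit.tvalues,
            "p": fit.pvalues,
        }
    )
    return RegressionResult(
        coefficients=coefs,
        f_statistic=float(fit.fvalue),
        df_model=float(fit.df_model),
        df_resid=float(fit.df_resid),
        f_pvalue=float(fit.f_pvalue),
        r_squared=float(fit.rsquared),
        n_obs=int(fit.nobs),
    )


NUCLEUS_PREDICTORS = ("hvc_volume", "ra_volume", "x_volume", "body_mass")


def regressions_by_sex(
    table: pd.DataFrame,
    scores: pd.DataFrame,
    components: Sequence[str] = ("PC1", "PC2", "PC3"),
    predictors: Sequence[str] = NUCLEUS_PREDICTORS,
) -> pd.DataFrame:
    """Per-sex OLS of each PC score on nucleus volumes + body mass.

    ``table`` supplies sex and the predictor columns; ``scores`` is indexed
    like ``table`` (rows dropped from the PCA are absent).  Returns a long
    table: sex, component, predictor, estimate, se, t, p plus model F, df
    and R^2 repeated per row.
    """
    missing = [c for c in predictors if c not in table.columns]
    if missing:
        raise SongSyntaxError(f"predictor columns absent from table: {missing}")
    rows = []
    merged = table.loc[scores.index].copy()
    for sex, g in merged.groupby("sex"):
        sub = g.dropna(subset=list(predictors))
        for comp in components:
            y = scores.loc[sub.index, comp]
            res = ols_regression(y, sub[list(predictors)])
            for pred, crow in res.coefficients.iterrows():
                rows.append(
                    {
                        "sex": sex,
                        "component": comp,
                        "predictor": pred,
                        "estimate": crow["estimate"],
                        "se": crow["se"],
                        "t": crow["t"],
                        "p": crow["p"],
                        "model_F": res.f_statistic,
                        "model_df1": res.df_model,
                        "model_df2": res.df_resid,
                        "model_p": res.f_pvalue,
                        "model_r2": res.r_squared,
                        "n": res.n_obs,
                    }
                )
    return pd.DataFrame(rows)


def diversity_variables(table: pd.DataFrame) -> list[str]:
    """The eight diversity metric columns present in a table."""
    return [c for c in DIVERSITY_COLUMNS if c in table.columns]
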