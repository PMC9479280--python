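"""Univariate post-hoc regressions and cohort descriptives.

Step 3 of the analytic strategy: once the effect-size analysis names the
ROIs carrying a multivariate group difference, each such ROI is examined
descriptively with an ordinary least-squares regression of its
standardized volume on a two-group indicator plus age and sex.  The
outcome is the T-scored column rescaled to unit SD ((T - 50) / 10), so
coefficients are standardized mean differences; this is the scale on
which the reported group contrasts (and their SEs ~ sqrt(1/n_a + 1/n_b))
live.  No multiplicity correction is applied, matching the descriptive
framing.

``cohort_summary`` produces the sample-characteristics report: group x
sex counts, mean (SD) of TBV and any supplied continuous scores, OLS
group contrasts on those scores, and Pearson chi-square tests of
independence for the ordinal covariates.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .normalize import T_MEAN, T_SD
from .tabular import GROUPS

__all__ = ["univariate_regression", "posthoc_table", "cohort_summary"]


def univariate_regression(
    tscores: pd.Series,
    cohort: pd.DataFrame,
    contrast: tuple[str, str],
    covariates: tuple[str, ...] = ("age", "sex"),
) -> dict:
    """OLS of one standardized ROI column on a two-group contrast.

    ``contrast = (reference, other)``: the coefficient is the adjusted
    mean difference (other - reference) in SD units.
    """
    ref, other = contrast
    groups = cohort["group"].astype(str)
    mask = groups.isin([ref, other]).to_numpy()
    if mask.sum() < 4 or not {(groups[mask] == g).any() for g in (ref, other)} == {True}:
        raise ValueError(f"contrast groups {contrast} not both present")
    y = (tscores.to_numpy(dtype=float)[mask] - T_MEAN) / T_SD
    sub = cohort.loc[mask]
    cols = {"const": np.ones(mask.sum()), "contrast": (groups[mask] == other).to_numpy(float)}
    if "age" in covariates:
        cols["age"] = sub["age_years"].to_numpy(float)
    if "sex" in covariates:
        cols["sex"] = (sub["sex"].astype(str) == "female").to_numpy(float)
    X = pd.DataFrame(cols)
    fit = sm.OLS(y, X).fit()
    return {
        "column": tscores.name,
        "contrast": f"{other} vs {ref}",
        "beta": float(fit.params["contrast"]),
        "se": float(fit.bse["contrast"]),
        "p": float(fit.pvalues["contrast"]),
        "n": int(mask.sum()),
        "adjusted_for": "+".join(covariates),
    }


def posthoc_table(
    tscores: pd.DataFrame,
    cohort: pd.DataFrame,
    columns: list[str],
    contrasts: list[tuple[str, str]],
    covariates: tuple[str, ...] = ("age", "sex"),
    correction: str | None = None,
) -> pd.DataFrame:
    """Post-hoc rows for each (column, contrast) pair.

    ``correction=None`` (default) reports raw p-values, matching the
    descriptive framing; ``correction="holm"`` adds a Holm-adjusted
    column across all rows of the table.
    """
    rows = [
        univariate_regression(tscores[c], cohort, pair, covariates)
        for pair in contrasts for c in columns
    ]
    tab = pd.DataFrame(rows)
    if correction == "holm":
        from statsmodels.stats.multitest import multipletests
        tab["p_holm"] = multipletests(tab["p"], method="holm")[1]
    elif correction is not None:
        raise ValueError(f"unknown correction {correction!r}")
    return tab


def _chi2_independence(cohort: pd.DataFrame, column: str) -> dict:
    if column not in cohort.columns or cohort[column].dropna().nunique() < 2:
        return {"covariate": column, "status": "not_applicable"}
    tab = pd.crosstab(cohort["group"].astype(str), cohort[column])
    tab = tab.loc[(tab.sum(axis=1) > 0), (tab.sum(axis=0) > 0)]
    chi2, p, dof, _ = stats.chi2_contingency(tab, correction=False)
    return {"covariate": column, "status": "ok", "chi2": float(chi2),
            "df": int(dof), "p": float(p)}


def cohort_summary(
    cohort: pd.DataFrame,
    continuous: tuple[str, ...] = ("tbv_cm3",),
) -> dict:
    """Sample-characteristics report for a validated cohort table.

    ``continuous`` names numeric columns to summarize per group x sex and
    contrast across groups (TBV always qualifies; callers may add e.g. a
    developmental-quotient or severity-score column if present).
    """
    counts = (cohort.groupby(["group", "sex"], observed=False).size()
              .unstack("sex").reindex(GROUPS))
    assert int(counts.to_numpy().sum()) == len(cohort)

    means: dict[str, pd.DataFrame] = {}
    anova: dict[str, dict] = {}
    ols_contrasts: dict[str, list[dict]] = {}
    for col in continuous:
        if col not in cohort.columns:
            anova[col] = {"status": "absent"}
            continue
        g = cohort.groupby(["group", "sex"], observed=False)[col]
        means[col] = pd.DataFrame({"mean": g.mean(), "sd": g.std(ddof=1)})
        by_group = [cohort.loc[cohort["group"].astype(str) == lev, col].to_numpy()
                    for lev in GROUPS]
        f, p = stats.f_oneway(*by_group)
        anova[col] = {"status": "ok", "F": float(f),
                      "df1": len(GROUPS) - 1, "df2": len(cohort) - len(GROUPS),
                      "p": float(p)}
        rows = []
        for ref, other in combinations(GROUPS, 2):
            mask = cohort["group"].astype(str).isin([ref, other])
            sub = cohort.loc[mask]
            X = sm.add_constant((sub["group"].astype(str) == other).astype(float))
            fit = sm.OLS(sub[col].to_numpy(float), X).fit()
            rows.append({"contrast": f"{other} vs {ref}",
                         "b": float(fit.params.iloc[1]),
                         "se": float(fit.bse.iloc[1]),
                         "p": float(fit.pvalues.iloc[1])})
        ols_contrasts[col] = rows

    return {
        "n": len(cohort),
        "counts": counts,
        "means": means,
        "anova": anova,
        "ols_contrasts": ols_contrasts,
        "chi2": {
            "income_bracket": _chi2_independence(cohort, "income_bracket"),
            "parental_education": _chi2_independence(cohort, "parental_education"),
        },
    }
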