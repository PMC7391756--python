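"""Descriptive summaries: stratum tables and secular-trend regressions.

``summarize`` reproduces the layout of a gender x birth-decade x region
table of Ns, means and SDs of education years.  ``trend_per_decade``
estimates the gender-specific secular increase in education (years per
decade of birth) by OLS, optionally excluding the most recent decade where
education may still be unfinished, and reports the female-minus-male
interaction contrast with its confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .harmonize import decade_label

__all__ = ["StratumSummary", "TrendResult", "summarize", "trend_per_decade"]


@dataclass
class TrendResult:
    """Per-gender slopes (years/decade) and the F-minus-M contrast, each
    as (estimate, ci_low, ci_high) at the requested level."""

    slopes: dict[str, tuple[float, float, float]]
    interaction: tuple[float, float, float] | None
    n: int
    excluded_decades: tuple[str, ...]


#: alias kept for symmetry with the domain vocabulary
StratumSummary = pd.DataFrame


def summarize(
    records: pd.DataFrame,
    by: tuple[str, ...] = ("sex", "decade", "region"),
    pheno: str = "education_years",
) -> pd.DataFrame:
    """N, mean and SD of the phenotype per stratum; empty strata omitted.

    The sum of stratum Ns equals the number of records with an observed
    phenotype.
    """
    df = records.copy()
    if "decade" in by and "decade" not in df.columns:
        df["decade"] = decade_label(df["birth_year"])
    obs = df[df[pheno].notna()]
    out = (
        obs.groupby(list(by), observed=True)[pheno]
        .agg(n="size", mean="mean", sd="std")
        .reset_index()
        .sort_values(list(by), kind="mergesort")
        .reset_index(drop=True)
    )
    return out


def trend_per_decade(
    records: pd.DataFrame,
    exclude_decades: tuple[str, ...] = ("1980-1989",),
    by_gender: bool = True,
    registry_dummies: bool = True,
    pheno: str = "education_years",
    level: float = 0.95,
) -> TrendResult:
    """OLS secular trend of education on birth year, in years per decade.

    The regressor is birth year / 10, so the coefficient is directly the
    change per decade.  Conventional OLS standard errors are used, without
    clustering on the twin pair (a documented simplification).
    """
    df = records[records[pheno].notna()].copy()
    df["decade"] = decade_label(df["birth_year"])
    df = df[~df["decade"].isin(exclude_decades)]
    if df["birth_year"].nunique() < 2:
        raise ValueError("need >= 2 distinct birth years after exclusions")
    alpha = 1.0 - level

    def _fit(sub: pd.DataFrame, extra: list[np.ndarray] | None = None):
        cols = [np.ones(len(sub)), sub["birth_year"].to_numpy(float) / 10.0]
        names = ["const", "per_decade"]
        if extra:
            cols += extra[0]
            names += extra[1]
        if registry_dummies and sub["registry"].nunique() > 1:
            for lev in sorted(sub["registry"].unique())[1:]:
                cols.append((sub["registry"] == lev).to_numpy(float))
                names.append(f"reg_{lev}")
        X = np.column_stack(cols)
        res = sm.OLS(sub[pheno].to_numpy(float), X).fit()
        ci = res.conf_int(alpha=alpha)
        return res, names, ci

    slopes: dict[str, tuple[float, float, float]] = {}
    genders = ("M", "F") if by_gender else ("all",)
    for g in genders:
        sub = df if g == "all" else df[df["sex"] == g]
        if sub["birth_year"].nunique() < 2:
            raise ValueError(f"degenerate birth-year support for gender {g}")
        res, names, ci = _fit(sub)
        j = names.index("per_decade")
        slopes[g] = (float(res.params[j]), float(ci[j, 0]), float(ci[j, 1]))

    interaction = None
    if by_gender:
        female = (df["sex"] == "F").to_numpy(float)
        x = df["birth_year"].to_numpy(float) / 10.0
        res, names, ci = _fit(df, extra=[[female, female * x], ["female", "female_x"]])
        j = names.index("female_x")
        interaction = (float(res.params[j]), float(ci[j, 0]), float(ci[j, 1]))

    return TrendResult(
        slopes=slopes,
        interaction=interaction,
        n=len(df),
        excluded_decades=tuple(exclude_decades),
    )
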