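"""Harmonization of raw twin records into analysis-ready phenotypes.

Three steps: (1) map registry-specific education categories to years using
each category's mean years; (2) apply inclusion filters — minimum age at
measurement (25 by default, 30 for birth-cohort comparisons so unfinished
education cannot bias the later cohorts), minimum birth year 1900, and a
minimum stratum cell size that removes region/gender/decade cells too small
to support stratified variance decomposition; (3) residualize education
years on birth year and registry dummies by ordinary least squares, pooling
both co-twins, so the twin model sees variation net of secular trends and
between-registry classification differences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "CodingTable",
    "InclusionPolicy",
    "MappingError",
    "map_education",
    "apply_inclusion",
    "residualize",
    "decade_label",
]


def decade_label(birth_year) -> str | pd.Series:
    """Closed 10-year bin label, e.g. 1947 -> '1940-1949'."""
    d = (birth_year // 10) * 10
    if isinstance(d, pd.Series):
        return d.astype(int).astype(str) + "-" + (d + 9).astype(int).astype(str)
    return f"{int(d)}-{int(d) + 9}"


class MappingError(ValueError):
    """A (registry, category) pair has no entry in the coding table."""


@dataclass
class CodingTable:
    """Per-registry category -> mean-education-years mapping."""

    table: pd.DataFrame  # columns: registry, category, years

    def __post_init__(self) -> None:
        need = {"registry", "category", "years"}
        if not need <= set(self.table.columns):
            raise ValueError(f"coding table needs columns {sorted(need)}")
        if self.table.duplicated(["registry", "category"]).any():
            raise ValueError("duplicate (registry, category) entries")
        if (self.table["years"] < 0).any():
            raise ValueError("coded years must be non-negative")

    @classmethod
    def from_csv(cls, path) -> "CodingTable":
        return cls(pd.read_csv(path))


def map_education(
    records: pd.DataFrame,
    coding: CodingTable | None,
    on_missing: str = "error",
) -> tuple[pd.DataFrame, dict]:
    """Fill ``education_years`` from category codes via the coding table.

    Rows whose years are already populated pass through unchanged.  Rows
    with a category absent from the table raise :class:`MappingError`
    listing the offending codes per registry (``on_missing="error"``) or are
    dropped with a logged count (``on_missing="drop"``).  Returns the mapped
    records and a report of counts.
    """
    df = records.copy()
    years_na = df["education_years"].isna()
    if "education_category" in df.columns:
        has_cat = df["education_category"].notna()
    else:
        has_cat = pd.Series(False, index=df.index)
    # rows with neither years nor a category are missing phenotypes
    # (e.g. non-responding co-twins) and pass through untouched
    need = years_na & has_cat
    report = {
        "input": len(df),
        "already_populated": int((~years_na).sum()),
        "missing_phenotype": int((years_na & ~has_cat).sum()),
        "mapped": 0,
        "dropped": 0,
    }
    if not need.any():
        report["output"] = len(df)
        return df, report
    if coding is None or coding.table.empty:
        if on_missing == "error":
            raise MappingError(
                f"{int(need.sum())} records carry category codes but no coding table given"
            )
        log.warning("dropping %d coded records without a coding table", int(need.sum()))
        df = df[~need]
        report["dropped"] = int(need.sum())
        report["output"] = len(df)
        return df, report
    key = coding.table.set_index(["registry", "category"])["years"]
    idx = pd.MultiIndex.from_frame(
        df.loc[need, ["registry", "education_category"]].rename(
            columns={"education_category": "category"}
        )
    )
    mapped = key.reindex(idx).to_numpy(float)
    unmappable = np.isnan(mapped)
    if unmappable.any():
        bad = (
            df.loc[need][unmappable]
            .groupby("registry")["education_category"]
            .unique()
            .to_dict()
        )
        if on_missing == "error":
            raise MappingError(
                "unmapped (registry, category) codes: "
                + "; ".join(f"{r}: {sorted(map(int, v))}" for r, v in bad.items())
            )
        log.warning("dropping %d records with unmapped categories: %s",
                    int(unmappable.sum()), bad)
    df.loc[need, "education_years"] = mapped
    dropped_mask = df["education_years"].isna() & has_cat
    report["dropped"] = int(dropped_mask.sum())
    report["mapped"] = int(need.sum()) - report["dropped"]
    df = df[~dropped_mask]
    report["output"] = len(df)
    return df, report


@dataclass
class InclusionPolicy:
    """Filters applied, in order: age, birth year, region, cell size."""

    min_age: int = 25
    min_birth_year: int = 1900
    min_cell_size: int = 200
    cell_keys: tuple[str, ...] = ("region", "sex", "decade")
    regions: tuple[str, ...] | None = None  # restrict to these regions if set

    def __post_init__(self) -> None:
        if self.min_age <= 0:
            raise ValueError("min_age must be positive")
        if self.min_cell_size < 0:
            raise ValueError("min_cell_size must be non-negative")


def apply_inclusion(
    records: pd.DataFrame, policy: InclusionPolicy
) -> tuple[pd.DataFrame, dict]:
    """Apply the inclusion policy; returns (filtered records, exclusion report).

    The report counts removals per rule in application order, and retained +
    excluded always equals the input count.  An empty result is signalled in
    the report (``empty: True``) rather than silently returned.
    """
    df = records
    report: dict = {"input": len(df)}
    kept = df["age"] >= policy.min_age
    report["age"] = int((~kept).sum())
    df = df[kept]
    kept = df["birth_year"] >= policy.min_birth_year
    report["birth_year"] = int((~kept).sum())
    df = df[kept]
    if policy.regions is not None:
        kept = df["region"].isin(policy.regions)
        report["region"] = int((~kept).sum())
        df = df[kept]
    if policy.min_cell_size > 0 and len(df):
        cells = df.copy()
        if "decade" in policy.cell_keys and "decade" not in cells.columns:
            cells["decade"] = decade_label(cells["birth_year"])
        sizes = cells.groupby(list(policy.cell_keys), observed=True)["person_id"].transform("size")
        kept = (sizes >= policy.min_cell_size).to_numpy()
        report["cell_size"] = int((~kept).sum())
        df = df[kept]
    else:
        report["cell_size"] = 0
    report["retained"] = len(df)
    report["empty"] = len(df) == 0
    return df.copy(), report


def residualize(
    records: pd.DataFrame,
    covariates: tuple[str, ...] = ("birth_year", "registry"),
    pheno: str = "education_years",
    out: str = "education_resid",
    per_registry: bool = False,
) -> pd.DataFrame:
    """OLS-residualize the phenotype on birth year and registry dummies.

    Residuals are computed over all individuals with an observed phenotype
    (co-twins pooled, pair clustering ignored) and have mean zero and zero
    inner product with every covariate column.  ``per_registry=True``
    adjusts for birth year separately within each registry, the convention
    for registry-specific analyses.  Missing phenotypes yield missing
    residuals; pair structure is untouched.  Residuals are not rescaled:
    standardized components come from the fitted variances, not from the
    residual scale.
    """
    df = records.copy()
    y_all = df[pheno]
    resid = pd.Series(np.nan, index=df.index, dtype=float)
    if per_registry:
        for _, idx in df.groupby("registry").groups.items():
            sub = df.loc[idx]
            obs = sub[pheno].notna()
            if obs.sum() == 0:
                continue
            X = _design(sub[obs], ("birth_year",))
            y = sub.loc[obs, pheno].to_numpy(float)
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid.loc[sub.index[obs]] = y - X @ beta
    else:
        obs = y_all.notna()
        if obs.sum() == 0:
            raise ValueError("no observed phenotypes to residualize")
        X = _design(df[obs], covariates)
        y = y_all[obs].to_numpy(float)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid[obs] = y - X @ beta
    df[out] = resid
    return df


def _design(df: pd.DataFrame, covariates: tuple[str, ...]) -> np.ndarray:
    """Intercept + covariates; categorical registry becomes drop-first dummies."""
    cols = [np.ones(len(df))]
    for cov in covariates:
        if cov == "registry":
            levels = sorted(df["registry"].unique())
            if len(levels) > 1:  # drop-first convention avoids collinearity
                for lev in levels[1:]:
                    cols.append((df["registry"] == lev).to_numpy(float))
        else:
            cols.append(df[cov].to_numpy(float))
    return np.column_stack(cols)
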