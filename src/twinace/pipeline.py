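"""Stratified ACE estimation across gender, birth-cohort and region strata.

Each stratum spec selects records (gender, decades or broad 1900-1949 /
1950-1989 cohorts, region, registry, minimum age), residualizes education
within the selected analysis set (birth year + registry dummies pooled, or
birth year only within a single registry), pivots to a pair table and fits
the ACE model.  Strata that cannot support a fit — too few individuals or
no MZ/DZ pairs — are reported as skipped with a reason, never dropped
silently.  Broad-cohort comparisons force the stricter 30-year age minimum
and are restricted to Europe and North America and Australia, where both
cohorts are observed; registries labelled "other" never enter
region-specific analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd

from .ace import ACEFit, ACEFitError, MZ_GROUPS, build_pair_table, fit_ace
from .harmonize import InclusionPolicy, apply_inclusion, decade_label, residualize

__all__ = [
    "StratumSpec",
    "StratumResult",
    "RegionMap",
    "COHORT_DECADES",
    "run_strata",
    "strata_table",
    "compare_cohorts",
]

COHORT_DECADES = {
    "1900-1949": tuple(f"{d}-{d + 9}" for d in range(1900, 1950, 10)),
    "1950-1989": tuple(f"{d}-{d + 9}" for d in range(1950, 1990, 10)),
}
_COHORT_REGIONS = ("Europe", "North America and Australia")


@dataclass(frozen=True)
class RegionMap:
    """Registry -> cultural-geographic region lookup.

    Registries mapping to "other" (geographically distinct cohorts) are
    excluded from region-specific analyses.
    """

    mapping: dict[str, str]

    def region_of(self, registry: str) -> str:
        try:
            return self.mapping[registry]
        except KeyError:
            raise KeyError(f"registry {registry!r} not in region map") from None

    def apply(self, records: pd.DataFrame) -> pd.DataFrame:
        df = records.copy()
        df["region"] = df["registry"].map(self.mapping)
        unknown = df["region"].isna()
        if unknown.any():
            missing = sorted(df.loc[unknown, "registry"].unique())
            raise KeyError(f"registries missing from region map: {missing}")
        return df


@dataclass(frozen=True)
class StratumSpec:
    """Declarative selection of one analysis stratum."""

    name: str
    gender: str = "all"                      # all | M | F
    decades: tuple[str, ...] | None = None   # e.g. ("1950-1959",)
    cohort: str | None = None                # "1900-1949" | "1950-1989"
    region: str | None = None                # None = all regions
    registry: str | None = None
    min_age: int = 25

    def __post_init__(self) -> None:
        if self.gender not in ("all", "M", "F"):
            raise ValueError("gender must be 'all', 'M' or 'F'")
        if self.cohort is not None:
            if self.cohort not in COHORT_DECADES:
                raise ValueError(f"cohort must be one of {sorted(COHORT_DECADES)}")
            if self.decades is not None:
                raise ValueError("give either decades or cohort, not both")
            # broad-cohort comparisons require finished education and
            # regions observed in both cohorts
            object.__setattr__(self, "min_age", max(self.min_age, 30))
            if self.region is not None and self.region not in _COHORT_REGIONS:
                raise ValueError(
                    f"cohort comparisons are restricted to {_COHORT_REGIONS}"
                )

    @property
    def selected_decades(self) -> tuple[str, ...] | None:
        if self.cohort is not None:
            return COHORT_DECADES[self.cohort]
        return self.decades

    @classmethod
    def from_dict(cls, d: dict) -> "StratumSpec":
        d = dict(d)
        if "decades" in d and d["decades"] is not None:
            d["decades"] = tuple(d["decades"])
        return cls(**d)


@dataclass
class StratumResult:
    spec: StratumSpec
    fit: ACEFit | None
    skipped: str | None = None
    n_individuals: int = 0

    @property
    def ok(self) -> bool:
        return self.fit is not None


def _select(records: pd.DataFrame, spec: StratumSpec, policy: InclusionPolicy) -> tuple[pd.DataFrame, dict]:
    df = records
    if spec.registry is not None:
        df = df[df["registry"] == spec.registry]
    if spec.region is not None:
        df = df[df["region"] == spec.region]
    elif spec.cohort is not None:
        df = df[df["region"].isin(_COHORT_REGIONS)]
    sel = spec.selected_decades
    if sel is not None:
        dec = decade_label(df["birth_year"])
        df = df[dec.isin(sel)]
    pol = replace(policy, min_age=max(policy.min_age, spec.min_age))
    return apply_inclusion(df, pol)


def run_strata(
    records: pd.DataFrame,
    specs: list[StratumSpec],
    policy: InclusionPolicy | None = None,
    region_map: RegionMap | None = None,
    dz_genetic_corr: float = 0.5,
    compute_ci: bool = True,
    seed: int = 0,
) -> list[StratumResult]:
    """Run the ACE analysis for every stratum spec.

    Records must be harmonized (education years populated).  Residualization
    happens inside each stratum's analysis set: birth year + registry
    dummies for pooled strata, birth year alone for single-registry strata.
    Gender-stratified specs fit in single-sex mode (that sex's MZ and SSDZ
    pairs); ``gender="all"`` pools all five zygosity groups including OSDZ.
    """
    policy = policy or InclusionPolicy()
    if region_map is not None:
        records = region_map.apply(records)
    if "region" not in records.columns:
        raise ValueError("records need a 'region' column or a region_map")
    results: list[StratumResult] = []
    for spec in specs:
        df, _report = _select(records, spec, policy)
        n_obs = int(df["education_years"].notna().sum())
        if n_obs < max(policy.min_cell_size, 4):
            results.append(
                StratumResult(spec, None, f"too few individuals ({n_obs})", n_obs)
            )
            continue
        df = residualize(df, per_registry=spec.registry is not None)
        pairs = build_pair_table(df, pheno="education_resid")
        if spec.gender in ("M", "F"):
            pairs = pairs[pairs["group"].isin((f"MZ{spec.gender}", f"DZ{spec.gender}"))]
        try:
            fit = fit_ace(
                pairs,
                mode="combined" if spec.gender == "all" else spec.gender,
                dz_genetic_corr=dz_genetic_corr,
                compute_ci=compute_ci,
                seed=seed,
            )
        except ACEFitError as exc:
            results.append(StratumResult(spec, None, str(exc), n_obs))
            continue
        results.append(StratumResult(spec, fit, None, n_obs))
    return results


def strata_table(results: list[StratumResult]) -> pd.DataFrame:
    """Tidy one-row-per-stratum summary of fits (full precision).

    Rounding to two decimals is a presentation concern, applied only when
    tables are written out.
    """
    rows = []
    for r in results:
        row = {
            "stratum": r.spec.name,
            "gender": r.spec.gender,
            "region": r.spec.region or "all",
            "cohort": r.spec.cohort or (",".join(r.spec.decades) if r.spec.decades else "all"),
            "n_individuals": r.n_individuals,
            "skipped": r.skipped or "",
        }
        if r.fit is not None:
            f = r.fit
            row.update(
                a2=f.components.a2, c2=f.components.c2, e2=f.components.e2,
                a2_lo=f.cis.get("a2", (float("nan"),) * 2)[0],
                a2_hi=f.cis.get("a2", (float("nan"),) * 2)[1],
                c2_lo=f.cis.get("c2", (float("nan"),) * 2)[0],
                c2_hi=f.cis.get("c2", (float("nan"),) * 2)[1],
                e2_lo=f.cis.get("e2", (float("nan"),) * 2)[0],
                e2_hi=f.cis.get("e2", (float("nan"),) * 2)[1],
                n_pairs=f.n_complete_pairs,
                n_singletons=f.n_singletons,
            )
        rows.append(row)
    return pd.DataFrame(rows)


def compare_cohorts(fit_early: ACEFit, fit_late: ACEFit) -> pd.DataFrame:
    """Component differences between two cohort fits with CI-overlap flags.

    No formal test is performed: the comparison reports point differences
    (early minus late) and whether the two 95% intervals overlap.
    """
    rows = []
    for comp in ("a2", "c2", "e2"):
        e = getattr(fit_early.components, comp)
        l = getattr(fit_late.components, comp)
        ci_e = fit_early.cis.get(comp)
        ci_l = fit_late.cis.get(comp)
        overlap = None
        if ci_e is not None and ci_l is not None:
            overlap = bool(ci_e[0] <= ci_l[1] and ci_l[0] <= ci_e[1])
        rows.append(
            {
                "component": comp,
                "early": e, "early_lo": ci_e[0] if ci_e else None,
                "early_hi": ci_e[1] if ci_e else None,
                "late": l, "late_lo": ci_l[0] if ci_l else None,
                "late_hi": ci_l[1] if ci_l else None,
                "difference": e - l,
                "ci_overlap": overlap,
            }
        )
    return pd.DataFrame(rows)
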