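"""Synthetic twin-registry generator with ACE-structured phenotypes.

Real multi-registry education data are access-restricted, so analyses are
developed and validated against synthetic cohorts that carry the exact
statistical structure the twin model assumes: additive-genetic effects
correlated 1.0 within MZ and ``dz_genetic_corr`` within DZ pairs, a fully
shared C component, independent E, gender-specific secular trends in
education years, a small MZ-minus-DZ mean offset, incomplete pairs, and
registry/region labels.  Assortative mating enters only through the DZ
genetic correlation (1+mu)/2; parental genotypes are never simulated.

Education categories can be produced by binning the continuous years on
configured cut points; the per-registry category means form the coding
table that the harmonization step later inverts, mirroring how registry
surveys record education in classification systems rather than years.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .ace import GROUPS, MZ_GROUPS, VarianceComponents

__all__ = [
    "StratumSim",
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_pair_phenotypes",
    "simulate_registry",
    "simulate_dataset",
    "simulate_parental_education",
    "simulate_correlation_study",
    "default_config",
    "save_dataset",
    "load_config",
]

REGIONS = ("Europe", "North America and Australia", "East Asia", "other")


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


@dataclass
class StratumSim:
    """One simulated registry (or registry x birth-cohort block)."""

    registry: str
    region: str = "Europe"
    pair_counts: dict[str, int] = field(default_factory=dict)  # by zygosity group
    components: VarianceComponents = field(
        default_factory=lambda: VarianceComponents(0.43, 0.31, 0.26)
    )
    total_variance: float = 14.44  # years^2; SD 3.8, typical of pooled registries
    birth_year_range: tuple[int, int] = (1920, 1979)
    survey_year: int = 2015

    def __post_init__(self) -> None:
        if self.total_variance <= 0:
            raise ValueError("total_variance must be positive")
        for g, n in self.pair_counts.items():
            if g not in GROUPS:
                raise ValueError(f"unknown zygosity group {g!r}")
            if n < 0:
                raise ValueError("pair counts must be non-negative")
        if self.region not in REGIONS:
            raise ValueError(f"region must be one of {REGIONS}")


@dataclass
class SimulationConfig:
    """Full generative configuration for a synthetic twin dataset.

    ``trend_per_decade`` gives the gender-specific secular increase in
    education years per decade of birth; ``mz_mean_offset`` the mean excess
    of MZ over DZ twins; ``singleton_fraction`` the share of pairs in which
    one co-twin's education is missing; ``mu`` the spousal additive-genetic
    correlation, which raises the DZ genetic correlation to (1+mu)/2.
    """

    strata: list[StratumSim]
    trend_per_decade: dict[str, float] = field(
        default_factory=lambda: {"M": 0.55, "F": 0.92}
    )
    base_mean: float = 12.5           # years at the reference birth year
    reference_birth_year: int = 1950
    mz_mean_offset: float = 0.3       # years, MZ minus DZ
    singleton_fraction: float = 0.27  # fraction of pairs missing one co-twin
    mu: float = 0.0                   # spousal additive-genetic correlation
    categorize: bool = False
    category_cut_points: tuple[float, ...] = (9.0, 12.0, 15.0, 17.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.singleton_fraction <= 1.0:
            raise ValueError("singleton_fraction must lie in [0, 1]")
        if not 0.0 <= self.mu < 1.0:
            raise ValueError("mu must lie in [0, 1)")

    @property
    def dz_genetic_corr(self) -> float:
        return (1.0 + self.mu) / 2.0

    def to_dict(self) -> dict:
        d = asdict(self)
        for s in d["strata"]:
            s["components"] = dict(
                a2=s["components"]["a2"], c2=s["components"]["c2"], e2=s["components"]["e2"]
            )
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        strata = []
        for s in d.pop("strata"):
            s = dict(s)
            comps = s.pop("components", None)
            if comps is not None:
                s["components"] = VarianceComponents(**comps)
            if "birth_year_range" in s:
                s["birth_year_range"] = tuple(s["birth_year_range"])
            strata.append(StratumSim(**s))
        if "trend_per_decade" in d:
            d["trend_per_decade"] = dict(d["trend_per_decade"])
        if "category_cut_points" in d:
            d["category_cut_points"] = tuple(d["category_cut_points"])
        return cls(strata=strata, **d)


@dataclass
class SimulatedDataset:
    """Simulated records plus the coding table and generating config."""

    records: pd.DataFrame
    coding: pd.DataFrame | None
    config: SimulationConfig


def simulate_pair_phenotypes(
    components: VarianceComponents,
    total_variance: float,
    genetic_corr: float,
    n_pairs: int,
    seed,
) -> np.ndarray:
    """Draw mean-zero ACE phenotype pairs; returns an (n_pairs, 2) array.

    The additive-genetic effect is split into a shared and a twin-specific
    standard-normal part weighted so the within-pair A-correlation equals
    ``genetic_corr`` (1.0 for MZ, 0.5 for DZ under random mating, (1+mu)/2
    under assortment); C is one shared draw, E independent.  The expected
    within-pair covariance is (genetic_corr*a2 + c2) * total_variance and the
    marginal variance is total_variance.
    """
    if total_variance <= 0:
        raise ValueError("total_variance must be positive")
    if not 0.0 <= genetic_corr <= 1.0:
        raise ValueError("genetic_corr must lie in [0, 1]")
    if n_pairs < 0:
        raise ValueError("n_pairs must be non-negative")
    rng = _rng(seed)
    a = np.sqrt(components.a2)
    c = np.sqrt(components.c2)
    e = np.sqrt(components.e2)
    ag = rng.standard_normal(n_pairs)
    au = rng.standard_normal((n_pairs, 2))
    cs = rng.standard_normal(n_pairs)
    eu = rng.standard_normal((n_pairs, 2))
    A = np.sqrt(genetic_corr) * ag[:, None] + np.sqrt(1.0 - genetic_corr) * au
    y = a * A + c * cs[:, None] + e * eu
    return np.sqrt(total_variance) * y


def simulate_correlation_study(
    r_mz: float,
    r_dz: float,
    n_mz: int,
    n_dz: int,
    seed,
    total_variance: float = 1.0,
    dz_genetic_corr: float = 0.5,
) -> pd.DataFrame:
    """Pair table for a two-group design with target twin correlations.

    Components are obtained by inverting Falconer's formulas, so the
    expected MZ and DZ intraclass correlations equal ``r_mz`` and ``r_dz``
    exactly when ``dz_genetic_corr`` is 0.5.  One generator stream drives
    both groups (MZ first), making the table deterministic under the seed.
    """
    from .ace import falconer

    comps = falconer(r_mz, r_dz)
    rng = _rng(seed)
    mz = simulate_pair_phenotypes(comps, total_variance, 1.0, n_mz, rng)
    dz = simulate_pair_phenotypes(comps, total_variance, dz_genetic_corr, n_dz, rng)
    return pd.DataFrame(
        {
            "pair_id": np.arange(n_mz + n_dz),
            "group": ["MZM"] * n_mz + ["DZM"] * n_dz,
            "y1": np.concatenate([mz[:, 0], dz[:, 0]]),
            "y2": np.concatenate([mz[:, 1], dz[:, 1]]),
        }
    )


_GROUP_SEXES = {"MZM": ("M", "M"), "MZF": ("F", "F"), "DZM": ("M", "M"),
                "DZF": ("F", "F"), "OSDZ": ("M", "F")}
_GROUP_ZYG = {"MZM": "MZ", "MZF": "MZ", "DZM": "SSDZ", "DZF": "SSDZ", "OSDZ": "OSDZ"}


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate a full registry table (and coding table if categorizing).

    Deterministic under a fixed config seed: identical configs produce
    byte-identical CSV output.
    """
    rng = _rng(config.seed)
    frames = []
    pair_counter = 0
    empty = [s.registry for s in config.strata if sum(s.pair_counts.values()) == 0]
    if empty and any(sum(s.pair_counts.values()) > 0 for s in config.strata):
        import warnings

        warnings.warn(f"strata with zero pairs requested: {empty}", stacklevel=2)
    for stratum in config.strata:
        for group in GROUPS:
            n = int(stratum.pair_counts.get(group, 0))
            if n == 0:
                continue
            rg = 1.0 if group in MZ_GROUPS else config.dz_genetic_corr
            dev = simulate_pair_phenotypes(
                stratum.components, stratum.total_variance, rg, n, rng
            )
            by = rng.integers(
                stratum.birth_year_range[0], stratum.birth_year_range[1] + 1, n
            )
            sex1, sex2 = _GROUP_SEXES[group]
            sexes = np.stack(
                [np.repeat(sex1, n), np.repeat(sex2, n)], axis=1
            )
            if group == "OSDZ":  # randomize which co-twin is male
                flip = rng.random(n) < 0.5
                sexes[flip] = sexes[flip][:, ::-1]
            offset = config.mz_mean_offset if group in MZ_GROUPS else 0.0
            trend = np.vectorize(config.trend_per_decade.get)(sexes).astype(float)
            mean = (
                config.base_mean
                + offset
                + trend * (by[:, None] - config.reference_birth_year) / 10.0
            )
            years = np.clip(mean + dev, 0.0, None)
            if config.singleton_fraction > 0:
                miss_pair = rng.random(n) < config.singleton_fraction
                victim = rng.integers(0, 2, n)
                years[np.arange(n)[miss_pair], victim[miss_pair]] = np.nan
            pair_ids = pair_counter + np.arange(n)
            pair_counter += n
            frames.append(
                pd.DataFrame(
                    {
                        "person_id": np.repeat(pair_ids, 2) * 10
                        + np.tile([1, 2], n),
                        "pair_id": np.repeat(pair_ids, 2),
                        "registry": stratum.registry,
                        "region": stratum.region,
                        "zygosity": _GROUP_ZYG[group],
                        "sex": sexes.ravel(),
                        "birth_year": np.repeat(by, 2),
                        "age": np.repeat(stratum.survey_year - by, 2),
                        "education_years": years.ravel(),
                    }
                )
            )
    if frames:
        records = pd.concat(frames, ignore_index=True)
    else:
        records = pd.DataFrame(
            columns=["person_id", "pair_id", "registry", "region", "zygosity",
                     "sex", "birth_year", "age", "education_years"]
        )
    coding = None
    if config.categorize and len(records):
        cuts = np.asarray(config.category_cut_points, float)
        obs = records["education_years"].notna()
        cat = pd.Series(pd.NA, index=records.index, dtype="Int64")
        cat[obs] = np.digitize(records.loc[obs, "education_years"], cuts)
        records["education_category"] = cat
        coding = (
            records[obs]
            .groupby(["registry", "education_category"], observed=True)["education_years"]
            .mean()
            .rename("years")
            .reset_index()
            .rename(columns={"education_category": "category"})
        )
        records["education_years"] = np.nan
    else:
        records["education_category"] = pd.NA
    return SimulatedDataset(records=records, coding=coding, config=config)


def simulate_registry(config: SimulationConfig) -> pd.DataFrame:
    """Convenience wrapper returning only the record table."""
    return simulate_dataset(config).records


def simulate_parental_education(
    pairs: pd.DataFrame | int,
    spousal_corr: float,
    seed,
    sd: float = 3.0,
    mean: float = 11.0,
    registry_shift_sd: float = 0.0,
    trend_per_decade: float = 0.0,
    reference_birth_year: int = 1950,
) -> pd.DataFrame:
    """Draw mother/father education values with a given spousal correlation.

    ``pairs`` is either a pair-level frame with ``pair_id`` (and optionally
    ``registry``/``birth_year`` columns, used to inject registry mean shifts
    and a secular trend so that the adjusted spousal correlation differs
    from the crude one) or simply a family count.  ``spousal_corr`` = 1 is
    honoured as exact duplication of the two parents' values.
    """
    if not -1.0 <= spousal_corr <= 1.0:
        raise ValueError("spousal_corr must lie in [-1, 1]")
    rng = _rng(seed)
    if isinstance(pairs, int):
        fam = pd.DataFrame({"pair_id": np.arange(pairs)})
    else:
        fam = pairs.drop_duplicates("pair_id")[
            [c for c in ("pair_id", "registry", "birth_year") if c in pairs.columns]
        ].reset_index(drop=True)
    n = len(fam)
    z1 = rng.standard_normal(n)
    if abs(spousal_corr) == 1.0:
        z2 = np.sign(spousal_corr) * z1
    else:
        z2 = spousal_corr * z1 + np.sqrt(1.0 - spousal_corr**2) * rng.standard_normal(n)
    base = np.full(n, mean)
    if registry_shift_sd > 0 and "registry" in fam.columns:
        regs = fam["registry"].unique()
        shifts = dict(zip(regs, rng.normal(0.0, registry_shift_sd, len(regs))))
        base = base + fam["registry"].map(shifts).to_numpy(float)
    if trend_per_decade != 0 and "birth_year" in fam.columns:
        base = base + trend_per_decade * (
            fam["birth_year"].to_numpy(float) - reference_birth_year
        ) / 10.0
    out = fam.copy()
    out["mother_years"] = base + sd * z1
    out["father_years"] = base + sd * z2
    return out


def default_config(
    n_pairs: int = 2000,
    components: VarianceComponents | None = None,
    seed: int = 0,
    **overrides,
) -> SimulationConfig:
    """A realistic default cohort mix scaled to ``n_pairs`` complete pairs.

    Registries span the three cultural-geographic regions plus an "other"
    registry, with region shares, the 40/39/21 MZ/SSDZ/OSDZ zygosity mix and
    a modest female excess resembling large pooled twin collections.
    """
    comps = components or VarianceComponents(0.43, 0.31, 0.26)
    registries = [
        ("FIN", "Europe", 0.20), ("SWE", "Europe", 0.20), ("NLD", "Europe", 0.12),
        ("USA", "North America and Australia", 0.30),
        ("AUS", "North America and Australia", 0.15),
        ("KOR", "East Asia", 0.02), ("LKA", "other", 0.01),
    ]
    # zygosity mix among complete pairs; sexes split 46/54 within same-sex groups
    group_share = {"MZM": 0.40 * 0.46, "MZF": 0.40 * 0.54,
                   "DZM": 0.39 * 0.46, "DZF": 0.39 * 0.54, "OSDZ": 0.21}
    strata = []
    for reg, region, share in registries:
        counts = {
            g: max(1, round(n_pairs * share * gs)) for g, gs in group_share.items()
        }
        by_range = (1950, 1979) if region == "East Asia" else (1910, 1979)
        strata.append(
            StratumSim(
                registry=reg,
                region=region,
                pair_counts=counts,
                components=comps,
                birth_year_range=by_range,
            )
        )
    return SimulationConfig(strata=strata, seed=seed, **overrides)


def save_dataset(ds: SimulatedDataset, csv_path, sidecar_path=None) -> None:
    """Write records to CSV with a JSON sidecar recording config + coding."""
    ds.records.to_csv(csv_path, index=False)
    if sidecar_path is not None:
        sidecar = {"config": ds.config.to_dict()}
        if ds.coding is not None:
            sidecar["coding"] = ds.coding.to_dict(orient="records")
        with open(sidecar_path, "w") as fh:
            json.dump(sidecar, fh, indent=1, default=float)


def load_config(path) -> SimulationConfig:
    """Load a SimulationConfig from a JSON or YAML file."""
    text = open(path).read()
    try:
        d = json.loads(text)
    except json.JSONDecodeError:
        import yaml

        d = yaml.safe_load(text)
    if "config" in d:  # accept a sidecar file too
        d = d["config"]
    return SimulationConfig.from_dict(d)
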