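"""Harmonization tests: category mapping, inclusion filters, residualization."""

import numpy as np
import pandas as pd
import pytest

from twinace import (
    CodingTable,
    InclusionPolicy,
    apply_inclusion,
    decade_label,
    default_config,
    map_education,
    residualize,
    simulate_dataset,
)
from twinace.harmonize import MappingError


def _records(**cols):
    base = {
        "person_id": None, "pair_id": None, "registry": "X", "region": "Europe",
        "zygosity": "MZ", "sex": "M", "birth_year": 1950, "age": 40,
        "education_category": pd.NA, "education_years": np.nan,
    }
    n = max(len(v) for v in cols.values() if hasattr(v, "__len__"))
    df = pd.DataFrame({k: [v] * n for k, v in base.items()})
    for k, v in cols.items():
        df[k] = v
    if df["person_id"].isna().all():
        df["person_id"] = range(n)
    if df["pair_id"].isna().all():
        df["pair_id"] = np.arange(n) // 2
    return df


class TestMapEducation:
    def test_simple_lookup(self):
        rec = _records(education_category=[3], registry=["X"])
        coding = CodingTable(pd.DataFrame(
            {"registry": ["X"], "category": [3], "years": [12.0]}
        ))
        out, report = map_education(rec, coding)
        assert out["education_years"].tolist() == [12.0]
        assert report["mapped"] == 1

    def test_identity_when_years_present(self):
        rec = _records(education_years=[10.0, 14.0])
        out, report = map_education(rec, None)
        assert out["education_years"].tolist() == [10.0, 14.0]
        assert report["already_populated"] == 2

    def test_missing_mapping_raises_with_codes(self):
        rec = _records(education_category=[3, 9], registry=["X", "X"])
        coding = CodingTable(pd.DataFrame(
            {"registry": ["X"], "category": [3], "years": [12.0]}
        ))
        with pytest.raises(MappingError, match=r"X: \[9\]"):
            map_education(rec, coding)

    def test_drop_mode_counts_dropped(self):
        rec = _records(education_category=[3, 9], registry=["X", "X"])
        coding = CodingTable(pd.DataFrame(
            {"registry": ["X"], "category": [3], "years": [12.0]}
        ))
        out, report = map_education(rec, coding, on_missing="drop")
        assert len(out) == 1 and report["dropped"] == 1
        assert report["input"] == report["output"] + report["dropped"]

    def test_synthetic_coding_roundtrip(self):
        """Mapped years equal the generating bin means from the sidecar."""
        ds = simulate_dataset(default_config(n_pairs=400, seed=12, categorize=True))
        out, _ = map_education(ds.records, CodingTable(ds.coding))
        merged = out.merge(
            ds.coding,
            left_on=["registry", "education_category"],
            right_on=["registry", "category"],
        )
        assert np.allclose(merged["education_years"], merged["years"])

    def test_duplicate_coding_entries_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            CodingTable(pd.DataFrame(
                {"registry": ["X", "X"], "category": [3, 3], "years": [12.0, 13.0]}
            ))


class TestInclusion:
    def test_age_filter(self):
        rec = _records(age=[24, 25, 30])
        out, report = apply_inclusion(rec, InclusionPolicy(min_cell_size=0))
        assert len(out) == 2 and report["age"] == 1

    def test_pre_1900_births_removed(self):
        rec = _records(birth_year=[1895] * 20, age=[60] * 20)
        out, report = apply_inclusion(rec, InclusionPolicy(min_cell_size=0))
        assert len(out) == 0
        assert report["birth_year"] == 20
        assert report["empty"] is True

    def test_small_region_cells_removed(self):
        """A small pre-1950 East-Asia cell falls below the stratum threshold
        while large European cells survive."""
        ea_m = _records(region=["East Asia"] * 113, sex=["M"] * 113,
                        birth_year=[1945] * 113, age=[70] * 113)
        ea_f = _records(region=["East Asia"] * 106, sex=["F"] * 106,
                        birth_year=[1948] * 106, age=[70] * 106)
        eu = _records(region=["Europe"] * 500, sex=["M"] * 500,
                      birth_year=[1945] * 500, age=[70] * 500)
        rec = pd.concat([ea_m, ea_f, eu], ignore_index=True)
        rec["person_id"] = range(len(rec))
        out, report = apply_inclusion(rec, InclusionPolicy(min_cell_size=200))
        assert report["cell_size"] == 219
        assert set(out["region"]) == {"Europe"}

    def test_counts_conserve_records(self):
        rec = _records(age=[20, 30, 40, 50], birth_year=[1890, 1950, 1960, 1970])
        out, report = apply_inclusion(rec, InclusionPolicy(min_cell_size=0))
        removed = report["age"] + report["birth_year"] + report["cell_size"]
        assert report["input"] == len(out) + removed

    def test_age_and_birth_year_filters_commute(self):
        rng = np.random.default_rng(0)
        rec = _records(
            age=rng.integers(20, 80, 200),
            birth_year=rng.integers(1890, 1990, 200),
        )
        p = InclusionPolicy(min_cell_size=0)
        ab, _ = apply_inclusion(rec, p)
        # reverse order: birth year first, then age
        kept = rec[rec["birth_year"] >= p.min_birth_year]
        kept = kept[kept["age"] >= p.min_age]
        assert ab.reset_index(drop=True).equals(kept.reset_index(drop=True))


class TestResidualize:
    def test_intercept_only(self):
        rec = _records(education_years=[10.0, 12.0, 14.0])
        out = residualize(rec)
        assert np.allclose(out["education_resid"], [-2.0, 0.0, 2.0])

    def test_mean_zero_and_orthogonal(self, small_records):
        out = residualize(small_records)
        r = out["education_resid"].dropna()
        sub = out[out["education_resid"].notna()]
        assert abs(r.mean()) < 1e-8
        assert abs(np.dot(r, sub["birth_year"] - sub["birth_year"].mean())) < 1e-5 * len(r)
        for reg in sub["registry"].unique():
            assert abs(r[sub["registry"] == reg].sum()) < 1e-6

    def test_idempotent(self, small_records):
        once = residualize(small_records)
        twice = residualize(once, pheno="education_resid", out="again")
        obs = once["education_resid"].notna()
        assert np.allclose(
            once.loc[obs, "education_resid"], twice.loc[obs, "again"], atol=1e-8
        )

    def test_registry_means_removed(self):
        rec = pd.concat([
            _records(registry=["A"] * 50, education_years=list(np.random.default_rng(1).normal(10, 1, 50))),
            _records(registry=["B"] * 50, education_years=list(np.random.default_rng(2).normal(14, 1, 50))),
        ], ignore_index=True)
        rec["person_id"] = range(len(rec))
        out = residualize(rec)
        for reg in ("A", "B"):
            assert abs(out.loc[out["registry"] == reg, "education_resid"].mean()) < 1e-8

    def test_secular_trend_removed(self):
        cfg = default_config(n_pairs=3000, seed=13, singleton_fraction=0.0)
        rec = simulate_dataset(cfg).records  # trends 0.55 / 0.92 by default
        out = residualize(rec)
        slope = np.polyfit(out["birth_year"], out["education_resid"], 1)[0]
        assert abs(slope * 10) < 1e-6

    def test_per_registry_mode_centers_within_registry(self):
        cfg = default_config(n_pairs=1000, seed=14, singleton_fraction=0.0)
        rec = simulate_dataset(cfg).records
        out = residualize(rec, per_registry=True)
        for _, sub in out.groupby("registry"):
            assert abs(sub["education_resid"].mean()) < 1e-8
            s = np.polyfit(sub["birth_year"], sub["education_resid"], 1)[0]
            assert abs(s) < 1e-8


def test_decade_label_scalar_and_series():
    assert decade_label(1947) == "1940-1949"
    s = decade_label(pd.Series([1900, 1989]))
    assert s.tolist() == ["1900-1909", "1980-1989"]
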