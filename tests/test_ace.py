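"""ACE model tests: covariance algebra, likelihood oracles, ML recovery,
boundary behaviour and profile confidence intervals."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from twinace import (
    ACEFitError,
    VarianceComponents,
    build_pair_table,
    falconer,
    fit_ace,
    group_covariance,
    intraclass_corr,
    pair_loglik,
    profile_ci,
    simulate_correlation_study,
    simulate_pair_phenotypes,
)
from twinace.ace import _class_stats, _loglik

from conftest import POOLED


class TestGroupCovariance:
    @pytest.mark.parametrize(
        "A,C,E,group,off",
        [
            (1.0, 0.0, 0.0, "MZM", 1.0),
            (1.0, 0.0, 0.0, "DZM", 0.5),
            (0.43, 0.31, 0.26, "DZF", 0.525),
            (0.43, 0.31, 0.26, "OSDZ", 0.525),
            (0.2, 0.3, 0.5, "MZF", 0.5),
        ],
    )
    def test_structure(self, A, C, E, group, off):
        cov = group_covariance(A, C, E, group)
        assert cov[0, 0] == pytest.approx(A + C + E)
        assert cov[0, 1] == pytest.approx(off)
        assert np.allclose(cov, cov.T)

    def test_assortment_raises_dz_correlation(self):
        cov = group_covariance(1.0, 0.0, 0.0, "DZM", dz_genetic_corr=0.565)
        assert cov[0, 1] == pytest.approx(0.565)

    def test_negative_components_rejected(self):
        with pytest.raises(ValueError):
            group_covariance(-0.1, 0.5, 0.6, "MZM")


class TestPairLoglik:
    def test_singleton_at_group_mean_unit_variance(self):
        assert pair_loglik(5.0, None, 0.4, 0.3, 0.3, mean=5.0) == pytest.approx(
            -0.5 * math.log(2 * math.pi)
        )

    def test_e_only_model_factorizes(self):
        ll = pair_loglik(1.3, -0.4, 0.0, 0.0, 2.0, mean=0.2, genetic_corr=0.5)
        expect = stats.norm.logpdf(1.3, 0.2, math.sqrt(2.0)) + stats.norm.logpdf(
            -0.4, 0.2, math.sqrt(2.0)
        )
        assert ll == pytest.approx(expect)

    def test_matches_multivariate_normal_density(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            A, C, E = rng.uniform(0.05, 2.0, 3)
            rg = rng.choice([1.0, 0.5])
            m = rng.normal(0, 2)
            y = rng.normal(0, 2, 2)
            cov = group_covariance(A, C, E, "MZM" if rg == 1.0 else "DZM")
            expect = stats.multivariate_normal.logpdf(y, mean=[m, m], cov=cov)
            assert pair_loglik(y[0], y[1], A, C, E, m, rg) == pytest.approx(expect)

    def test_zero_total_variance_fails(self):
        with pytest.raises(ValueError):
            pair_loglik(1.0, 2.0, 0.0, 0.0, 0.0, mean=0.0)

    def test_sufficient_statistics_equal_per_pair_sum(self):
        """The pooled likelihood must be the sum of per-pair contributions."""
        rng = np.random.default_rng(3)
        pairs = simulate_correlation_study(0.7, 0.5, 40, 40, 4)
        pairs.loc[pairs.index[:10], "y2"] = np.nan  # inject singletons
        A, C, E, m_mz, m_dz = 0.35, 0.25, 0.4, 0.1, -0.05
        classes = _class_stats(pairs, 0.5)
        pooled = _loglik(A, C, E, m_mz, m_dz, classes)
        brute = 0.0
        for _, row in pairs.iterrows():
            mz = row["group"] in ("MZM", "MZF")
            brute += pair_loglik(
                row["y1"], row["y2"], A, C, E,
                m_mz if mz else m_dz, 1.0 if mz else 0.5,
            )
        assert pooled == pytest.approx(brute, rel=1e-12)


class TestFalconer:
    @pytest.mark.parametrize(
        "r_mz,r_dz,expect",
        [
            (0.5, 0.25, (0.5, 0.0, 0.5)),
            (1.0, 0.5, (1.0, 0.0, 0.0)),
            (0.74, 0.525, (0.43, 0.31, 0.26)),
        ],
    )
    def test_closed_form(self, r_mz, r_dz, expect):
        comps = falconer(r_mz, r_dz)
        assert comps.as_array() == pytest.approx(np.array(expect), abs=1e-12)

    def test_negative_values_truncated_with_warning(self):
        # r_dz > r_mz implies negative a2; truncate and renormalize
        with pytest.warns(UserWarning, match="truncated"):
            comps = falconer(0.3, 0.4)
        assert comps.a2 == 0.0
        assert comps.as_array().sum() == pytest.approx(1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            falconer(1.2, 0.5)


class TestIntraclassCorrelation:
    def test_identical_within_pair(self):
        pairs = pd.DataFrame(
            {"group": "MZM", "y1": [1.0, 2.0, 3.0], "y2": [1.0, 2.0, 3.0]}
        )
        assert intraclass_corr(pairs) == pytest.approx(1.0)

    def test_independent_members(self):
        rng = np.random.default_rng(5)
        pairs = pd.DataFrame(
            {"group": "DZF", "y1": rng.normal(size=20_000), "y2": rng.normal(size=20_000)}
        )
        assert abs(intraclass_corr(pairs)) < 0.02

    def test_agrees_with_anova_estimator(self):
        y = simulate_pair_phenotypes(VarianceComponents(0.4, 0.2, 0.4), 1.0, 0.5, 10_000, 6)
        pairs = pd.DataFrame({"group": "DZM", "y1": y[:, 0], "y2": y[:, 1]})
        # one-way random-effects ANOVA intraclass estimator for k=2
        n = len(y)
        pair_means = y.mean(axis=1)
        grand = y.mean()
        msb = 2 * np.sum((pair_means - grand) ** 2) / (n - 1)
        msw = np.sum((y[:, 0] - y[:, 1]) ** 2) / (2 * n)
        anova = (msb - msw) / (msb + msw)
        assert intraclass_corr(pairs) == pytest.approx(anova, abs=0.005)

    def test_zero_variance_fails(self):
        pairs = pd.DataFrame({"group": "MZM", "y1": [1.0] * 5, "y2": [1.0] * 5})
        with pytest.raises(ACEFitError):
            intraclass_corr(pairs)


class TestFitACE:
    def test_ml_matches_falconer_on_sample_correlations(self):
        pairs = simulate_correlation_study(0.74, 0.525, 20_000, 20_000, 7)
        fit = fit_ace(pairs, compute_ci=False)
        fal = falconer(intraclass_corr(pairs, "MZ"), intraclass_corr(pairs, "DZ"))
        assert fit.components.as_array() == pytest.approx(fal.as_array(), abs=0.01)

    def test_a2_boundary_when_correlations_equal(self):
        # rMZ = rDZ carries no genetic signal: a2 pinned at 0, c2 = r
        pairs = simulate_correlation_study(0.4, 0.4, 20_000, 20_000, 8)
        fit = fit_ace(pairs)
        assert fit.components.a2 < 0.02
        assert fit.components.c2 == pytest.approx(0.4, abs=0.02)
        assert fit.cis["a2"][0] == 0.0

    def test_independent_twins_are_all_e(self):
        pairs = simulate_correlation_study(0.0, 0.0, 10_000, 10_000, 9)
        fit = fit_ace(pairs, compute_ci=False)
        assert fit.components.e2 > 0.97

    def test_parameter_recovery_grid(self):
        """Mean absolute error < 0.01 over a grid of generating components."""
        errs = []
        seed = 40
        for a2 in (0.2, 0.4, 0.6):
            for c2 in (0.1, 0.3):
                truth = VarianceComponents(a2, c2, 1.0 - a2 - c2)
                pairs = simulate_correlation_study(
                    a2 + c2, 0.5 * a2 + c2, 50_000, 50_000, seed
                )
                fit = fit_ace(pairs, compute_ci=False)
                errs.append(abs(fit.components.a2 - a2))
                errs.append(abs(fit.components.c2 - c2))
                seed += 1
        assert np.mean(errs) < 0.01

    def test_likelihood_invariant_to_twin_order(self):
        pairs = simulate_correlation_study(0.7, 0.5, 2000, 2000, 10)
        swapped = pairs.rename(columns={"y1": "y2", "y2": "y1"})
        f1 = fit_ace(pairs, compute_ci=False)
        f2 = fit_ace(swapped, compute_ci=False)
        assert f1.loglik == pytest.approx(f2.loglik, abs=1e-6)
        assert f1.components.a2 == pytest.approx(f2.components.a2, abs=1e-5)

    def test_mz_dz_mean_difference_recovered(self):
        pairs = simulate_correlation_study(0.74, 0.525, 50_000, 50_000, 11)
        mz_mask = pairs["group"].isin(["MZM", "MZF"])
        pairs.loc[mz_mask, ["y1", "y2"]] += 0.3
        fit = fit_ace(pairs, compute_ci=False)
        assert fit.mean_mz - fit.mean_dz == pytest.approx(0.3, abs=0.05)

    def test_singletons_enter_via_marginal_likelihood(self):
        pairs = simulate_correlation_study(0.74, 0.525, 5000, 5000, 12)
        pairs.loc[pairs.index[:1000], "y2"] = np.nan
        fit = fit_ace(pairs, compute_ci=False)
        assert fit.n_singletons == 1000
        assert fit.n_complete_pairs == 9000
        # dropping singletons changes the likelihood but not validity
        complete = pairs.dropna(subset=["y1", "y2"])
        fit_c = fit_ace(complete, compute_ci=False)
        assert fit.components.a2 == pytest.approx(fit_c.components.a2, abs=0.05)

    def test_standardized_components_sum_to_one(self):
        pairs = simulate_correlation_study(0.6, 0.45, 3000, 3000, 13)
        fit = fit_ace(pairs, compute_ci=False)
        assert sum(fit.components.as_array()) == pytest.approx(1.0, abs=1e-8)
        assert all(r >= 0 for r in fit.raw)

    def test_too_few_pairs_rejected(self):
        pairs = pd.DataFrame(
            {"group": ["MZM", "DZM"], "y1": [1.0, 2.0], "y2": [1.1, 2.2]}
        )
        with pytest.raises(ACEFitError, match="MZ"):
            fit_ace(pairs)

    def test_invalid_arguments_rejected(self):
        pairs = simulate_correlation_study(0.7, 0.5, 10, 10, 0)
        with pytest.raises(ValueError):
            fit_ace(pairs, mode="X")
        with pytest.raises(ValueError):
            fit_ace(pairs, dz_genetic_corr=1.0)


class TestProfileCI:
    def test_interior_interval_contains_estimate(self):
        pairs = simulate_correlation_study(0.74, 0.525, 5000, 5000, 14)
        fit = fit_ace(pairs)
        for comp in ("a2", "c2", "e2"):
            lo, hi = fit.cis[comp]
            est = getattr(fit.components, comp)
            assert 0.0 <= lo < est < hi <= 1.0

    def test_width_shrinks_with_sample_size(self):
        widths = []
        for n in (1000, 5000, 25_000):
            pairs = simulate_correlation_study(0.74, 0.525, n, n, 15)
            fit = fit_ace(pairs, compute_ci=False)
            lo, hi = profile_ci(fit, "a2")
            widths.append(hi - lo)
        assert widths[0] > widths[1] > widths[2]

    def test_unknown_component_rejected(self):
        pairs = simulate_correlation_study(0.7, 0.5, 500, 500, 16)
        fit = fit_ace(pairs, compute_ci=False)
        with pytest.raises(ValueError):
            profile_ci(fit, "d2")


class TestBuildPairTable:
    def test_pivot_and_group_labels(self, small_records):
        pairs = build_pair_table(small_records, pheno="education_years")
        assert set(pairs["group"]) <= {"MZM", "MZF", "DZM", "DZF", "OSDZ"}
        # every retained pair has at least one observed phenotype
        assert not (pairs["y1"].isna() & pairs["y2"].isna()).any()
        # complete + singleton pairs cannot exceed generated pairs
        assert pairs["pair_id"].nunique() <= small_records["pair_id"].nunique()

    def test_triplet_rows_rejected(self):
        bad = pd.DataFrame(
            {
                "pair_id": [1, 1, 1],
                "person_id": [1, 2, 3],
                "zygosity": "MZ",
                "sex": "M",
                "education_years": [10.0, 11.0, 12.0],
            }
        )
        with pytest.raises(ValueError, match="two members"):
            build_pair_table(bad, pheno="education_years")
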