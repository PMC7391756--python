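# Methods

## The model

`twinace` implements the classical twin design for a quantitative trait,
here years of education. Monozygotic (MZ) co-twins share effectively all
segregating genetic variation; dizygotic (DZ) co-twins share half of it on
average under random mating. Writing the phenotypic variance as
A + C + E — additive genetic, shared environment, unique environment
(including measurement error) — the implied within-pair covariances are

    cov(MZ) = A + C
    cov(DZ) = r_g · A + C,   r_g = 0.5 under random mating

with a common marginal variance A + C + E for every twin. Standardized
components are a² = A/(A+C+E), c² = C/(A+C+E), e² = E/(A+C+E). The
closed-form Falconer estimators a² = 2(r_MZ − r_DZ), c² = 2r_DZ − r_MZ,
e² = 1 − r_MZ serve as an independent oracle throughout the test suite,
never as the production estimator.

Assumptions inherited from the design: no dominance or epistatic variance
(no D component), equal shared-environment covariance for MZ and DZ pairs
(the equal-environments assumption), no gene–environment interaction, and
additivity on the years-of-education scale after covariate residualization.

## Estimation

The fit is full-information maximum likelihood on pair-level data.
Complete pairs contribute a bivariate normal log-density with the ACE
covariance; incomplete pairs (one co-twin missing the phenotype) contribute
the univariate marginal. MZ and DZ pairs are given separate means, because
MZ twins tend to report slightly more education than DZ twins; variances
are shared across all groups within a fit.

Non-negativity of A, C, E is enforced by optimizing over standard-deviation
paths (a, c, e) with A = a² and so on, a parameterization that makes
boundary solutions (for example a² = 0 when r_MZ ≤ r_DZ) ordinary interior
points of the search space. Optimization uses L-BFGS on the negative
log-likelihood assembled from per-class sufficient statistics (sums,
squares, cross-products), so one likelihood evaluation costs O(1) in the
number of pairs; a test verifies the sufficient-statistic likelihood equals
the sum of per-pair densities to machine precision. Five starts are used —
Falconer-initialized from the sample intraclass correlations, an equal
split, and three seeded random starts — with ties (log-likelihood within
1e−8) broken toward the lowest a². Convergence tolerances: 1e−12 relative
on the objective, 1e−9 on the gradient.

Two fitting modes mirror the reporting conventions of pooled twin
registries: a combined mode that pools all five zygosity-by-sex groups
(MZM, MZF, DZM, DZF, OSDZ) with components equal across sexes and OSDZ
treated with genetic correlation 0.5, and a single-sex mode restricted to
one sex's MZ and same-sex-DZ pairs. No sex-limitation model is fitted, and
only the full ACE model is reported (no AE/CE/E model selection).

## Profile-likelihood confidence intervals

Intervals are computed on the standardized scale. For a component fixed at
proportion p, the remaining parameters (the other two components' paths and
both means) are re-maximized; the 95% limits are the p where twice the
profile log-likelihood drop equals the χ²₁ critical value 3.841, located by
bisection to 1e−4 and clipped to [0, 1]. When the boundary lies inside the
likelihood region the lower limit is reported as exactly 0.00 — the
behaviour visible in small strata where a² or c² is weakly identified.
Coverage of the a² interval is verified by simulation: across 200
replicates of 1,000 + 1,000 pairs generated at (0.4, 0.3, 0.3), the 95%
interval covers the truth 90–98% of the time.

## The synthetic registry generator

Real pooled twin-registry education data are access-restricted, so the
generator is a first-class module that emulates the features the analysis
depends on:

- **ACE pair structure.** The additive effect is a shared plus a
  twin-specific standard-normal part weighted so the within-pair
  A-correlation is exactly 1 (MZ) or `dz_genetic_corr` (DZ); C is one
  shared draw, E independent. Assortative mating is injected only through
  `dz_genetic_corr = (1+μ)/2`; parental genotypes are never simulated.
- **Secular trends.** Gender-specific linear trends in years per decade of
  birth, defaults 0.55 (men) and 0.92 (women), applied to each
  individual's own sex around a reference birth year of 1950 with a base
  mean of 12.5 years and total variance 14.44 years² (SD 3.8).
- **MZ mean offset.** MZ twins receive +0.3 years by default. The offset
  exists in registry data but its size is conventionally small; 0.3 years
  is a convention here, recovered by the mean-difference tests.
- **Incomplete pairs.** Each pair loses one co-twin's phenotype with
  probability 0.27, matching the relation between total twins and complete
  pairs typical of large pooled registries.
- **Registries and regions.** A default mix of seven registries across
  Europe (~52% of twins), North America and Australia (~45%), East Asia
  (~2%) and an "other" registry, with the 40/39/21 MZ/SSDZ/OSDZ zygosity
  split and a modest female excess.
- **Category coding.** Optionally, continuous years are binned on cut
  points (9, 12, 15, 17) and replaced by category codes; the per-registry
  category means form the coding table that harmonization later inverts,
  so the category→years mapping step has real work to do.

What the generator does **not** emulate: age-dependent measurement error,
non-normal education distributions (real education years are discrete and
skewed), registry-specific zygosity mixes, birth-year-dependent variance,
or household structure beyond the C component. Passing tests therefore
demonstrate correctness of the estimators under the model's own
assumptions, not robustness to the ways real registry data violate them.
Birth years are uniform within configured ranges and age is survey year
minus birth year with a fixed synthetic survey year per registry — a
convention, since no age structure is asserted for real cohorts.

## Harmonization choices

Inclusion filters run in a fixed order — minimum age (default 25; 30 for
birth-cohort comparisons so unfinished education cannot masquerade as a
cohort effect), minimum birth year 1900, optional region restriction, then
a minimum stratum cell size (default 200 individuals per
region × gender × decade cell) that removes cells too small for stratified
variance decomposition. The report counts removals per rule and retained +
excluded always equals the input.

Residualization is ordinary least squares of education years on birth year
plus drop-first registry dummies, pooling both co-twins and ignoring pair
clustering — the conventional pre-adjustment before biometric modeling.
For single-registry analyses only birth year is used, fitted within the
registry. Residuals are not rescaled to unit variance; standardized
components come from the fitted variances, which keeps raw variances in
years². Residualization is idempotent and runs within each stratum's
analysis set before pair construction.

Secular-trend confidence intervals use conventional OLS standard errors
without pair clustering; with ~74% within-pair correlation these intervals
are somewhat anticonservative, a documented limitation rather than a bug.

## Assortative mating

If spouses' education correlates and that correlation is genetic to degree
μ (the spousal additive-genetic correlation), DZ pairs share more than
half their additive variance: r_g = (1+μ)/2. A model that still assumes
0.5 reports apparent components Â = (1−μ)A and Ĉ = C + μA — algebra that
follows directly from matching the MZ and DZ covariances, and which the
end-to-end test verifies by simulating under (1+μ)/2, fitting at 0.5, and
correcting back. The correction module inverts this (A = Â/(1−μ),
C = Ĉ − μA), conserves the total exactly, flags μ large enough to drive C
negative, exposes μ* = Ĉ/(Â+Ĉ) (the μ at which assortment would explain
all of C), and provides the first-order phenotypic-assortment bound
μ = h²·r_P together with the social-homogamy limit μ = 0. The spousal
phenotypic correlation itself is estimated by residualizing each parent's
education on registry dummies and the twins' birth year (a proxy for the
unrecorded parental birth years) before correlating.

## Numerical and design notes

- Tie-breaking, seeds and start points are fixed, so identical inputs and
  seeds give byte-identical outputs end to end, including written TSV/JSON
  bundles.
- Degenerate inputs fail loudly: zero variance, singular pair covariance,
  fewer than two complete pairs per zygosity class, unmapped category
  codes, empty post-filter samples.
- Presentation rounding (two decimals, mirroring the field's tables)
  happens only in the TSV writers; JSON bundles keep full precision.
- Test and validation problem sizes are chosen so Monte-Carlo error is
  small relative to the tolerance being checked: 50,000 pairs per zygosity
  group for component-recovery checks (per-component sd ≈ 0.006), 200
  replicates for interval coverage, 20,000+20,000 for oracle-agreement
  checks. Recovery checks with ±0.01 tolerances average six fixed-seed
  replicates so the check has negligible false-alarm probability while the
  per-replicate design stays at the stated n.
- OSDZ pairs enter combined fits with genetic correlation 0.5 and are
  excluded from single-sex fits; whether real pooled analyses constrain
  means across sexes is not observable from reported tables, so the
  minimal model (one MZ mean, one DZ mean per fit) is used.

## Known limitations

- No dominance, sex-limitation, gene–environment interaction or
  liability-threshold models.
- The equal-environments assumption is untestable within this design.
- OLS trend and spousal-correlation inference ignores pair clustering.
- The assortment correction treats μ as known; it propagates no
  uncertainty from μ into the corrected components.
- Education years are modelled as Gaussian; categorical coding is handled
  by mean-imputation per category, which understates within-category
  variance.
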