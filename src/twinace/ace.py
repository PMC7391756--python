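"""Maximum-likelihood ACE variance decomposition for twin pair data.

The classical twin design contrasts monozygotic (MZ) pairs, who share all
segregating genetic variation, with dizygotic (DZ) pairs, who share half of
it on average under random mating.  The ACE model decomposes the phenotypic
variance into an additive-genetic part A (within-pair correlation 1.0 for MZ,
0.5 for DZ), a shared-environment part C (correlation 1.0 for both) and a
unique-environment part E (uncorrelated; includes measurement error).

The fit here is full-information maximum likelihood on pair-level data:
complete pairs contribute a bivariate-normal density, incomplete pairs
(singletons) the marginal univariate density.  MZ and DZ pairs are allowed
different means, since MZ twins tend to report slightly more education than
DZ twins in registry data.  Confidence intervals are profile-likelihood
intervals on the standardized (proportion-of-variance) scale, so a lower
limit of exactly 0.00 is reported when the boundary lies inside the
likelihood region, as is common for a2 or c2 in small strata.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "GROUPS",
    "MZ_GROUPS",
    "VarianceComponents",
    "ACEFit",
    "ACEFitError",
    "group_covariance",
    "pair_loglik",
    "falconer",
    "intraclass_corr",
    "build_pair_table",
    "fit_ace",
    "profile_ci",
]

#: Zygosity-by-sex groups: monozygotic male/female, same-sex dizygotic
#: male/female, opposite-sex dizygotic.
GROUPS = ("MZM", "MZF", "DZM", "DZF", "OSDZ")
MZ_GROUPS = frozenset({"MZM", "MZF"})

_LOG2PI = math.log(2.0 * math.pi)
_COMPONENT_INDEX = {"a2": 0, "c2": 1, "e2": 2}


class ACEFitError(RuntimeError):
    """Raised when pair data cannot support an ACE fit."""


@dataclass(frozen=True)
class VarianceComponents:
    """Standardized variance components (proportions of total variance).

    a2 is the narrow-sense heritability, c2 the shared-environment and e2
    the unique-environment proportion; they must lie in [0, 1] and sum to 1.
    """

    a2: float
    c2: float
    e2: float

    def __post_init__(self) -> None:
        for name, v in (("a2", self.a2), ("c2", self.c2), ("e2", self.e2)):
            if not (-1e-8 <= v <= 1.0 + 1e-8):
                raise ValueError(f"{name}={v} outside [0, 1]")
        total = self.a2 + self.c2 + self.e2
        if abs(total - 1.0) > 1e-8:
            raise ValueError(f"components sum to {total}, expected 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.a2, self.c2, self.e2], dtype=float)


@dataclass
class ACEFit:
    """Result of a maximum-likelihood ACE fit.

    ``raw`` holds the variance components on the phenotype scale (years^2
    for education); ``components`` the standardized proportions.  ``cis``
    maps component name to its 95% profile-likelihood interval on the
    standardized scale.
    """

    components: VarianceComponents
    raw: tuple[float, float, float]
    mean_mz: float
    mean_dz: float
    loglik: float
    cis: dict[str, tuple[float, float]]
    n_pairs: dict[str, int]
    n_singletons: int
    converged: bool
    dz_genetic_corr: float = 0.5
    message: str = ""
    _classes: list = field(default_factory=list, repr=False)

    @property
    def total_variance(self) -> float:
        return float(sum(self.raw))

    @property
    def n_complete_pairs(self) -> int:
        return int(sum(self.n_pairs.values()))

    def to_dict(self) -> dict:
        return {
            "a2": self.components.a2,
            "c2": self.components.c2,
            "e2": self.components.e2,
            "raw_A": self.raw[0],
            "raw_C": self.raw[1],
            "raw_E": self.raw[2],
            "mean_mz": self.mean_mz,
            "mean_dz": self.mean_dz,
            "loglik": self.loglik,
            "cis": {k: list(v) for k, v in self.cis.items()},
            "n_pairs": dict(self.n_pairs),
            "n_singletons": self.n_singletons,
            "converged": self.converged,
            "dz_genetic_corr": self.dz_genetic_corr,
        }


# ---------------------------------------------------------------------------
# closed forms and per-pair densities


def group_covariance(
    A: float, C: float, E: float, group: str, dz_genetic_corr: float = 0.5
) -> np.ndarray:
    """Expected 2x2 phenotype covariance of a twin pair.

    The diagonal is the total variance A+C+E; the off-diagonal is A+C for MZ
    pairs and ``dz_genetic_corr``*A + C for DZ/OSDZ pairs.  Under random
    mating dz_genetic_corr = 0.5; under assortative mating with spousal
    additive-genetic correlation mu it rises to (1+mu)/2.
    """
    if min(A, C, E) < 0:
        raise ValueError("variance components must be non-negative")
    if group not in GROUPS and group not in ("MZ", "DZ"):
        raise ValueError(f"unknown zygosity group {group!r}")
    rg = 1.0 if (group in MZ_GROUPS or group == "MZ") else dz_genetic_corr
    v = A + C + E
    w = rg * A + C
    return np.array([[v, w], [w, v]], dtype=float)


def pair_loglik(
    y1: float,
    y2: float | None,
    A: float,
    C: float,
    E: float,
    mean: float,
    genetic_corr: float = 1.0,
) -> float:
    """Log-likelihood contribution of one pair (or singleton, if y2 is None/NaN).

    Complete pairs contribute the bivariate normal log-density with common
    mean and the ACE covariance; singletons the univariate normal log-density
    with variance A+C+E.
    """
    v = A + C + E
    if v <= 0:
        raise ValueError("total variance must be positive")
    y1_missing = y1 is None or (isinstance(y1, float) and math.isnan(y1))
    y2_missing = y2 is None or (isinstance(y2, float) and math.isnan(y2))
    if y1_missing and y2_missing:
        raise ValueError("pair with no observed phenotype")
    if y1_missing or y2_missing:
        y = y2 if y1_missing else y1
        return float(-0.5 * (_LOG2PI + math.log(v)) - (y - mean) ** 2 / (2.0 * v))
    w = genetic_corr * A + C
    det = v * v - w * w
    if det <= 0:
        raise ValueError("pair covariance is singular")
    d1, d2 = y1 - mean, y2 - mean
    quad = (v * (d1 * d1 + d2 * d2) - 2.0 * w * d1 * d2) / det
    return float(-_LOG2PI - 0.5 * math.log(det) - 0.5 * quad)


def falconer(r_mz: float, r_dz: float) -> VarianceComponents:
    """Falconer's closed-form component estimates from twin correlations.

    a2 = 2(r_MZ - r_DZ), c2 = 2 r_DZ - r_MZ, e2 = 1 - r_MZ.  Raw values
    falling below 0 are truncated and the triple renormalized to sum to 1;
    a warning flags the truncation.
    """
    for name, r in (("r_mz", r_mz), ("r_dz", r_dz)):
        if not -1.0 <= r <= 1.0:
            raise ValueError(f"{name}={r} outside [-1, 1]")
    raw = np.array([2.0 * (r_mz - r_dz), 2.0 * r_dz - r_mz, 1.0 - r_mz])
    if (raw < 0).any():
        warnings.warn(
            "Falconer estimates truncated at 0 and renormalized", stacklevel=2
        )
        raw = np.clip(raw, 0.0, None)
    total = raw.sum()
    if total <= 0:
        raise ValueError("degenerate correlations: no positive variance share")
    raw = raw / total
    return VarianceComponents(*raw)


def intraclass_corr(pairs: pd.DataFrame, group: str | None = None) -> float:
    """Double-entry intraclass correlation of complete pairs.

    Each pair enters in both orders, making co-twins exchangeable; for
    balanced data this agrees with the one-way ANOVA estimator to O(1/n).
    ``group`` restricts to one zygosity group (or an MZ/DZ shorthand).
    """
    df = pairs
    if group is not None:
        if group == "MZ":
            df = df[df["group"].isin(MZ_GROUPS)]
        elif group == "DZ":
            df = df[~df["group"].isin(MZ_GROUPS)]
        else:
            df = df[df["group"] == group]
    complete = df.dropna(subset=["y1", "y2"])
    if len(complete) < 2:
        raise ACEFitError("need at least 2 complete pairs for a correlation")
    x = np.concatenate([complete["y1"].to_numpy(), complete["y2"].to_numpy()])
    y = np.concatenate([complete["y2"].to_numpy(), complete["y1"].to_numpy()])
    if np.var(x) <= 0:
        raise ACEFitError("zero phenotypic variance")
    return float(np.corrcoef(x, y)[0, 1])


# ---------------------------------------------------------------------------
# pair-table construction

_ZYG_TO_GROUP = {("MZ", "M"): "MZM", ("MZ", "F"): "MZF", ("SSDZ", "M"): "DZM", ("SSDZ", "F"): "DZF"}


def build_pair_table(records: pd.DataFrame, pheno: str = "education_resid") -> pd.DataFrame:
    """Pivot individual twin records into one row per pair.

    Output columns: pair_id, group (MZM/MZF/DZM/DZF/OSDZ), y1, y2 (NaN for a
    missing co-twin), registry, region, birth_year.  Pairs with no observed
    phenotype are dropped.
    """
    needed = {"pair_id", "person_id", "zygosity", "sex", pheno}
    missing = needed - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    d = records.sort_values(["pair_id", "person_id"], kind="mergesort").copy()
    d["_slot"] = d.groupby("pair_id").cumcount()
    if (d["_slot"] > 1).any():
        bad = d.loc[d["_slot"] > 1, "pair_id"].unique()[:5]
        raise ValueError(f"pairs with more than two members, e.g. {list(bad)}")
    wide = d.pivot(index="pair_id", columns="_slot", values=pheno)
    wide = wide.rename(columns={0: "y1", 1: "y2"})
    if "y2" not in wide.columns:
        wide["y2"] = np.nan
    first = d[d["_slot"] == 0].set_index("pair_id")
    out = wide.join(first[["zygosity", "sex"]])
    for col in ("registry", "region", "birth_year"):
        if col in first.columns:
            out[col] = first[col]
    out["group"] = [
        "OSDZ" if z == "OSDZ" else _ZYG_TO_GROUP[(z, s)]
        for z, s in zip(out["zygosity"], out["sex"])
    ]
    out = out.drop(columns=["zygosity", "sex"]).reset_index()
    out = out[~(out["y1"].isna() & out["y2"].isna())]
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# sufficient statistics and likelihood


@dataclass
class _ClassStats:
    """Sufficient statistics for one covariance class (MZ-type or DZ-type)."""

    rg: float        # within-pair additive-genetic correlation
    mz: bool         # uses the MZ mean
    n: int = 0       # complete pairs
    sxx: float = 0.0
    syy: float = 0.0
    sxy: float = 0.0
    sx: float = 0.0
    sy: float = 0.0
    m: int = 0       # singletons
    s1: float = 0.0
    s11: float = 0.0


def _class_stats(pairs: pd.DataFrame, dz_genetic_corr: float) -> list[_ClassStats]:
    classes = []
    for mz in (True, False):
        sel = pairs["group"].isin(MZ_GROUPS) if mz else ~pairs["group"].isin(MZ_GROUPS)
        sub = pairs[sel]
        st = _ClassStats(rg=1.0 if mz else dz_genetic_corr, mz=mz)
        comp = sub.dropna(subset=["y1", "y2"])
        if len(comp):
            x = comp["y1"].to_numpy(float)
            y = comp["y2"].to_numpy(float)
            st.n = len(comp)
            st.sxx = float(x @ x)
            st.syy = float(y @ y)
            st.sxy = float(x @ y)
            st.sx = float(x.sum())
            st.sy = float(y.sum())
        single_mask = sub["y1"].isna() ^ sub["y2"].isna()
        singles = sub[single_mask]
        if len(singles):
            z = singles["y1"].fillna(singles["y2"]).to_numpy(float)
            st.m = len(z)
            st.s1 = float(z.sum())
            st.s11 = float(z @ z)
        classes.append(st)
    return classes


def _loglik(A: float, C: float, E: float, m_mz: float, m_dz: float,
            classes: list[_ClassStats]) -> float:
    """Total log-likelihood from sufficient statistics.

    Equals the sum of ``pair_loglik`` over every pair and singleton.
    """
    v = A + C + E
    if v <= 0:
        return -np.inf
    ll = 0.0
    for st in classes:
        m = m_mz if st.mz else m_dz
        w = st.rg * A + C
        det = v * v - w * w
        if st.n:
            if det <= 0:
                return -np.inf
            q1 = st.sxx + st.syy - 2.0 * m * (st.sx + st.sy) + 2.0 * st.n * m * m
            q2 = st.sxy - m * (st.sx + st.sy) + st.n * m * m
            ll += -st.n * _LOG2PI - 0.5 * st.n * math.log(det) - (v * q1 - 2.0 * w * q2) / (2.0 * det)
        if st.m:
            q = st.s11 - 2.0 * m * st.s1 + st.m * m * m
            ll += -0.5 * st.m * (_LOG2PI + math.log(v)) - q / (2.0 * v)
    return ll


def _double_entry_moments(classes: list[_ClassStats]) -> tuple[float, dict[bool, float], dict[bool, float]]:
    """Pooled variance, per-class double-entry correlation and mean."""
    corr: dict[bool, float] = {}
    means: dict[bool, float] = {}
    var_acc = 0.0
    n_acc = 0
    for st in classes:
        if st.n == 0:
            continue
        mu = (st.sx + st.sy) / (2 * st.n)
        var = (st.sxx + st.syy) / (2 * st.n) - mu * mu
        cov = st.sxy / st.n - mu * mu
        means[st.mz] = mu
        corr[st.mz] = cov / var if var > 0 else 0.0
        var_acc += var * 2 * st.n
        n_acc += 2 * st.n
    pooled_var = var_acc / n_acc if n_acc else 1.0
    return pooled_var, corr, means


def _minimize(nll, z0):
    return optimize.minimize(
        nll, np.asarray(z0, float), method="L-BFGS-B",
        options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-9},
    )


def fit_ace(
    pairs: pd.DataFrame,
    mode: str = "combined",
    dz_genetic_corr: float = 0.5,
    compute_ci: bool = True,
    seed: int = 0,
    n_random_starts: int = 3,
) -> ACEFit:
    """Fit the ACE model by full-information maximum likelihood.

    Parameters
    ----------
    pairs
        Pair table from :func:`build_pair_table` (columns ``group``, ``y1``,
        ``y2``; one of y1/y2 may be NaN for singletons).
    mode
        ``"combined"`` pools all five zygosity groups with components shared
        across sexes; ``"M"``/``"F"`` restrict to that sex's MZ and same-sex
        DZ pairs (OSDZ pairs are excluded from single-sex fits).
    dz_genetic_corr
        Additive-genetic correlation assumed for DZ/OSDZ pairs: 0.5 under
        random mating, (1+mu)/2 for an assortative-mating sensitivity fit.
    compute_ci
        Compute 95% profile-likelihood intervals for a2, c2, e2.

    Non-negativity of A, C, E is enforced by optimizing over standard
    deviation paths (a, c, e) with A = a^2 etc.  Five starts are used: a
    Falconer-initialized start, an equal-split start, and three seeded
    random starts; ties in log-likelihood are broken toward the lowest a2.
    """
    if mode not in ("combined", "M", "F"):
        raise ValueError("mode must be 'combined', 'M' or 'F'")
    if not 0.0 < dz_genetic_corr < 1.0:
        raise ValueError("dz_genetic_corr must lie in (0, 1)")
    df = pairs
    if mode == "M":
        df = df[df["group"].isin(("MZM", "DZM"))]
    elif mode == "F":
        df = df[df["group"].isin(("MZF", "DZF"))]
    n_pairs = {
        g: int(df[(df["group"] == g)].dropna(subset=["y1", "y2"]).shape[0])
        for g in GROUPS
    }
    n_mz = sum(v for g, v in n_pairs.items() if g in MZ_GROUPS)
    n_dz = sum(v for g, v in n_pairs.items() if g not in MZ_GROUPS)
    if n_mz < 2 or n_dz < 2:
        raise ACEFitError(
            f"need >=2 complete MZ and DZ pairs, got {n_mz} MZ / {n_dz} DZ"
        )
    classes = _class_stats(df, dz_genetic_corr)
    n_single = sum(st.m for st in classes)

    pooled_var, corr, means = _double_entry_moments(classes)
    r_mz = corr.get(True, 0.0)
    r_dz = corr.get(False, 0.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fal = falconer(max(min(r_mz, 1.0), -1.0), max(min(r_dz, 1.0), -1.0))
            fal_raw = fal.as_array() * pooled_var
        except ValueError:
            fal_raw = np.full(3, pooled_var / 3.0)
    m_mz0 = means.get(True, 0.0)
    m_dz0 = means.get(False, m_mz0)

    def nll(z):
        ll = _loglik(z[0] ** 2, z[1] ** 2, z[2] ** 2, z[3], z[4], classes)
        return 1e12 if not np.isfinite(ll) else -ll

    starts = [
        np.array([*np.sqrt(np.clip(fal_raw, 1e-8, None)), m_mz0, m_dz0]),
        np.array([*(math.sqrt(pooled_var / 3.0),) * 3, m_mz0, m_dz0]),
    ]
    rng = np.random.default_rng(seed)
    sd0 = math.sqrt(pooled_var)
    for _ in range(n_random_starts):
        props = rng.dirichlet([1.0, 1.0, 1.0])
        starts.append(np.array([
            *np.sqrt(props * pooled_var),
            m_mz0 + rng.normal(0, 0.1 * sd0),
            m_dz0 + rng.normal(0, 0.1 * sd0),
        ]))

    best = None
    any_ok = False
    for z0 in starts:
        res = _minimize(nll, z0)
        any_ok = any_ok or bool(res.success)
        if best is None:
            best = res
            continue
        if res.fun < best.fun - 1e-8:
            best = res
        elif abs(res.fun - best.fun) <= 1e-8 and res.x[0] ** 2 < best.x[0] ** 2:
            best = res
    assert best is not None
    A, C, E = (float(best.x[i] ** 2) for i in range(3))
    total = A + C + E
    if total <= 0 or not np.isfinite(best.fun):
        raise ACEFitError("optimization failed: non-positive total variance")
    comps = VarianceComponents(A / total, C / total, E / total)
    fit = ACEFit(
        components=comps,
        raw=(A, C, E),
        mean_mz=float(best.x[3]),
        mean_dz=float(best.x[4]),
        loglik=float(-best.fun),
        cis={},
        n_pairs={g: n for g, n in n_pairs.items() if n > 0},
        n_singletons=n_single,
        converged=any_ok,
        dz_genetic_corr=dz_genetic_corr,
        message="" if any_ok else "no optimizer start reported success",
        _classes=classes,
    )
    if compute_ci:
        for comp in ("a2", "c2", "e2"):
            fit.cis[comp] = profile_ci(fit, comp)
    return fit


# ---------------------------------------------------------------------------
# profile-likelihood confidence intervals


def _profile_max(fit: ACEFit, comp_idx: int, p: float) -> float:
    """Maximized log-likelihood with component proportion fixed at p."""
    classes = fit._classes
    raw = np.asarray(fit.raw, float)
    V = raw.sum()
    others = [i for i in range(3) if i != comp_idx]

    if p >= 1.0 - 1e-9:
        def nll(z):
            comps = [0.0, 0.0, 0.0]
            comps[comp_idx] = z[0] ** 2
            ll = _loglik(*comps, z[1], z[2], classes)
            return 1e12 if not np.isfinite(ll) else -ll
        res = _minimize(nll, [math.sqrt(V), fit.mean_mz, fit.mean_dz])
        return float(-res.fun)

    other_sum = raw[others].sum()
    shares = (raw[others] / other_sum) if other_sum > 0 else np.array([0.5, 0.5])
    o_init = np.clip((1.0 - p) * V * shares, 1e-10, None)

    def nll(z):
        o1, o2 = z[0] ** 2, z[1] ** 2
        vo = o1 + o2
        comps = [0.0, 0.0, 0.0]
        comps[others[0]] = o1
        comps[others[1]] = o2
        comps[comp_idx] = p / (1.0 - p) * vo
        ll = _loglik(*comps, z[2], z[3], classes)
        return 1e12 if not np.isfinite(ll) else -ll

    res = _minimize(nll, [*np.sqrt(o_init), fit.mean_mz, fit.mean_dz])
    return float(-res.fun)


def profile_ci(
    fit: ACEFit, component: str, level: float = 0.95, tol: float = 1e-4
) -> tuple[float, float]:
    """Profile-likelihood confidence interval on the standardized scale.

    The limits are the component proportions p where twice the drop of the
    profiled log-likelihood from its maximum equals the chi-square(1)
    critical value (3.841 at 95%), located by bisection and clipped to
    [0, 1].  A lower limit of exactly 0.0 (or upper of 1.0) is returned when
    the boundary lies inside the likelihood region.
    """
    if component not in _COMPONENT_INDEX:
        raise ValueError("component must be one of 'a2', 'c2', 'e2'")
    if not fit._classes:
        raise ACEFitError("fit carries no data; refit with fit_ace")
    idx = _COMPONENT_INDEX[component]
    crit = stats.chi2.ppf(level, 1)
    target = fit.loglik - crit / 2.0
    p_hat = fit.components.as_array()[idx]

    def deficit(p: float) -> float:
        """Positive inside the confidence region."""
        return _profile_max(fit, idx, p) - target

    def bisect(lo: float, hi: float, f_lo: float) -> float:
        # f changes sign between lo and hi; keep the sign of f_lo at `lo`
        while hi - lo > tol:
            mid = 0.5 * (lo + hi)
            if (deficit(mid) > 0) == (f_lo > 0):
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    # lower limit
    if p_hat <= tol or deficit(0.0) >= 0:
        lower = 0.0
    else:
        lower = bisect(0.0, p_hat, deficit(0.0))
    # upper limit
    if p_hat >= 1.0 - tol or deficit(1.0) >= 0:
        upper = 1.0
    else:
        upper = bisect(p_hat, 1.0, 1.0)  # deficit(p_hat) > 0 by construction
    lower = min(max(lower, 0.0), p_hat)
    upper = max(min(upper, 1.0), p_hat)
    return (float(lower), float(upper))
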