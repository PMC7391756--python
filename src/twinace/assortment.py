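"""Assortative-mating sensitivity analysis for ACE components.

Spouses resemble each other in education.  If that phenotypic resemblance
induces a spousal additive-genetic correlation mu, the DZ additive-genetic
correlation rises from 0.5 to (1+mu)/2, and a twin model that still assumes
0.5 misattributes part of the genetic variance to the shared environment:

    apparent A = (1 - mu) * A_true,    apparent C = C_true + mu * A_true.

Inverting gives the correction applied here:

    A_true = A_hat / (1 - mu),    C_true = C_hat - mu * A_true,

with E untouched and the total conserved.  Social homogamy — spousal
similarity from shared social environment — produces a phenotypic but no
genetic spousal correlation (mu = 0), so the phenotypic spousal correlation
alone is an upper bound, not an estimate, of mu.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AssortmentParams",
    "CorrectedComponents",
    "spousal_correlation",
    "true_from_apparent",
    "apparent_from_true",
    "max_mu_explaining_c",
    "mu_from_phenotypic_assortment",
]


@dataclass(frozen=True)
class AssortmentParams:
    """Spousal phenotypic correlation and spousal additive-genetic correlation."""

    r_p: float
    mu: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.mu < 1.0:
            raise ValueError("mu must lie in [0, 1)")

    @property
    def dz_genetic_corr(self) -> float:
        return (1.0 + self.mu) / 2.0


@dataclass(frozen=True)
class CorrectedComponents:
    """ACE shares after (or before) the assortment transform.

    Unlike fitted components, ``c2`` may be negative: a mu large enough to
    over-explain the shared environment is flagged rather than hidden.
    """

    a2: float
    c2: float
    e2: float
    mu: float
    over_explains_c: bool = False

    @property
    def total(self) -> float:
        return self.a2 + self.c2 + self.e2


def _shares(components) -> tuple[float, float, float]:
    if hasattr(components, "a2"):
        return float(components.a2), float(components.c2), float(components.e2)
    a2, c2, e2 = components
    return float(a2), float(c2), float(e2)


def true_from_apparent(apparent, mu: float) -> CorrectedComponents:
    """Correct fitted (apparent) components for spousal genetic correlation mu.

    A_true = a2/(1-mu); C_true = c2 - mu*A_true; E unchanged.  The total is
    conserved.  A negative C_true means the assumed mu over-explains the
    shared environment; the result is flagged, not clipped.
    """
    if not 0.0 <= mu < 1.0:
        raise ValueError("mu must lie in [0, 1)")
    a2, c2, e2 = _shares(apparent)
    a_true = a2 / (1.0 - mu)
    c_true = c2 - mu * a_true
    return CorrectedComponents(a_true, c_true, e2, mu, over_explains_c=c_true < 0)


def apparent_from_true(true, mu: float) -> CorrectedComponents:
    """Forward transform: what a 0.5-DZ model reports for true components.

    a2 = (1-mu)*A; c2 = C + mu*A; E unchanged.  Exact inverse of
    :func:`true_from_apparent`.
    """
    if not 0.0 <= mu < 1.0:
        raise ValueError("mu must lie in [0, 1)")
    a2, c2, e2 = _shares(true)
    a_hat = (1.0 - mu) * a2
    c_hat = c2 + mu * a2
    return CorrectedComponents(a_hat, c_hat, e2, mu, over_explains_c=c_hat < 0)


def max_mu_explaining_c(apparent) -> float:
    """Largest mu consistent with the fitted components: C_true = 0 there.

    mu* = c2 / (a2 + c2).  Returns 1.0 (unattainable, since mu < 1) when
    a2 = 0 and c2 > 0.
    """
    a2, c2, _ = _shares(apparent)
    if a2 + c2 <= 0:
        raise ValueError("a2 + c2 must be positive")
    return c2 / (a2 + c2)


def mu_from_phenotypic_assortment(r_p: float, h2: float, social_homogamy: bool = False) -> float:
    """First-order spousal genetic correlation under phenotypic assortment.

    mu = h2 * r_p when mates select on the phenotype itself; under pure
    social homogamy the spousal phenotypic correlation carries no genetic
    correlation, so mu = 0 regardless of r_p.
    """
    if not -1.0 <= r_p <= 1.0:
        raise ValueError("r_p must lie in [-1, 1]")
    if not 0.0 <= h2 <= 1.0:
        raise ValueError("h2 must lie in [0, 1]")
    if social_homogamy:
        return 0.0
    return h2 * r_p


def spousal_correlation(
    parents: pd.DataFrame,
    covariates: tuple[str, ...] = ("registry", "birth_year"),
) -> float:
    """Spousal education correlation, adjusted for registry and twin birth year.

    Each parent's education is residualized by OLS on registry dummies and
    the twins' birth year (a proxy for the unrecorded parental birth years),
    then the Pearson correlation of the residuals is returned.
    """
    need = {"mother_years", "father_years"}
    if not need <= set(parents.columns):
        raise ValueError("parents frame needs mother_years and father_years")
    df = parents.dropna(subset=["mother_years", "father_years"])
    if len(df) < 3:
        raise ValueError("need >= 3 families with both parents observed")
    cols = [np.ones(len(df))]
    for cov in covariates:
        if cov not in df.columns:
            continue
        if cov == "registry":
            levels = sorted(df["registry"].unique())
            for lev in levels[1:]:
                cols.append((df["registry"] == lev).to_numpy(float))
        else:
            cols.append(df[cov].to_numpy(float))
    X = np.column_stack(cols)
    resids = []
    for col in ("mother_years", "father_years"):
        y = df[col].to_numpy(float)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        if np.var(r) <= 0:
            raise ValueError(f"zero residual variance in {col}")
        resids.append(r)
    return float(np.corrcoef(resids[0], resids[1])[0, 1])
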