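"""Spectrally transformed linear mixed model for association testing.

The model for a quantitative trait on n inbred lines is

    y = 1*mu + X*beta + a + eps,   a ~ N(0, K sigma_a^2),  eps ~ N(0, I sigma_e^2),

where X holds the tested genetic unit (one 0/1 column for a SNP or a
haplotype-allele carrier indicator; k-1 indicator columns for a k-allele
block) and K is the marker-based kinship. Writing h2 = sigma_a^2 /
(sigma_a^2 + sigma_e^2) and decomposing K = U S U^T once,

    Var(y | beta) = U (h2/(1-h2) S + I) U^T sigma_e^2,

so rotating everything by U^T turns the mixed model into an independent
weighted linear model with diagonal weights w_i = h2/(1-h2) S_i + 1. Each
tested unit then costs one weighted least-squares solve per candidate h2, and
the profile of -2 log L over h2 is a one-dimensional search:

    -2 log L(h2)  ~  n log sigma_e^2(h2) + sum_i log w_i(h2)   (+ const).

The unit is tested with the nested-model F statistic on weighted residual sums
of squares, F(df_beta, n - df_beta - 1); this keeps the stated F reference
distribution exact for units of any width.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Optional

import numpy as np
from scipy import optimize, stats

from .genotype_io import PhenotypeVector
from .haplotype_builder import UnitDesign
from .kinship import EigenSystem

logger = logging.getLogger(__name__)

H2_EPS = 1e-6  # open-interval guard for the (0, 1) heritability search
P_FLOOR = 1e-300  # only for -log10(p) reporting


class RankDeficientDesign(ValueError):
    """The whitened design lost full column rank; carries the offending column."""

    def __init__(self, column_index: int):
        super().__init__(f"design column {column_index} is linearly dependent")
        self.column_index = column_index


class FitCounter:
    """Counts weighted least-squares solves, i.e. likelihood evaluations.

    Dividing the count by the number of tested units gives the empirical
    number i of genome-wide regression-scan equivalents.
    """

    def __init__(self):
        self.count = 0

    def tick(self):
        self.count += 1


@dataclasses.dataclass
class TransformedData:
    """Phenotype and intercept rotated by U^T, plus what the scan needs later."""

    y_t: np.ndarray
    intercept_t: np.ndarray
    S: np.ndarray
    n: int
    y_raw: np.ndarray  # original-scale phenotype, kept for explained variance


@dataclasses.dataclass
class WLSFit:
    beta: np.ndarray  # intercept first
    sigma2_eps: float  # weighted RSS / (n - 1)
    rss_weighted: float
    h2: float
    df_beta: int  # design columns beyond the intercept
    neg2loglik: float


@dataclasses.dataclass
class NullModelFit:
    h2_genomic: float
    neg2loglik: float
    sigma2_eps: float
    mu_hat: float


@dataclasses.dataclass
class UnitTestResult:
    unit_id: str
    unit_kind: str
    df_beta: int
    df_eps: int
    F: float
    p: float
    neg_log10_p: float
    h2_used: float
    beta: np.ndarray  # unit effect(s), intercept excluded
    explained_var_pct: float
    mode: str  # emmax | exact
    chromosome: str = ""
    span_bp: tuple = (0, 0)
    n_snps: Optional[int] = None
    n_alleles: Optional[int] = None


def transform(y, eig: EigenSystem) -> TransformedData:
    """Rotate the phenotype and the intercept by U^T.

    Unit design columns are rotated lazily, per unit, by the scan.
    """
    values = y.values if isinstance(y, PhenotypeVector) else np.asarray(y, dtype=float)
    n = eig.n
    if values.size != n:
        raise ValueError(f"phenotype length {values.size} != eigen system size {n}")
    U = eig.vectors
    return TransformedData(
        y_t=U.T @ values,
        intercept_t=U.T @ np.ones(n),
        S=eig.values,
        n=n,
        y_raw=values,
    )


def weights(h2: float, S: np.ndarray) -> np.ndarray:
    """Diagonal of W = h2/(1-h2) S + I."""
    if not 0.0 <= h2 < 1.0:
        raise ValueError(f"h2 = {h2} outside [0, 1)")
    return (h2 / (1.0 - h2)) * S + 1.0


def wls_fit(
    td: TransformedData,
    X_t: np.ndarray,
    h2: float,
    counter: Optional[FitCounter] = None,
) -> WLSFit:
    """Weighted least squares of y~ on X~ (intercept column included in X_t).

    Solves beta-hat = (X~^T W^-1 X~)^-1 X~^T W^-1 y~ by whitening with
    W^-1/2 and reports sigma2_eps with the (n-1) divisor; the profile
    objective is n log sigma2_eps + sum log w_i (constants dropped).
    """
    if counter is not None:
        counter.tick()
    w = weights(h2, td.S)
    sw = np.sqrt(w)
    Xs = X_t / sw[:, None]
    ys = td.y_t / sw
    beta, _, rank, _ = np.linalg.lstsq(Xs, ys, rcond=None)
    p = Xs.shape[1]
    if rank < p:
        raise RankDeficientDesign(_offending_column(Xs))
    resid = ys - Xs @ beta
    rss = float(resid @ resid)
    n = td.n
    sigma2 = rss / (n - 1)
    if sigma2 > 0:
        nll = n * math.log(sigma2) + float(np.log(w).sum())
    else:
        nll = -math.inf  # perfect fit; degenerate but well-defined as a limit
    return WLSFit(
        beta=beta,
        sigma2_eps=sigma2,
        rss_weighted=rss,
        h2=h2,
        df_beta=p - 1,
        neg2loglik=nll,
    )


def _offending_column(Xs: np.ndarray) -> int:
    rank = 0
    for j in range(Xs.shape[1]):
        r = np.linalg.matrix_rank(Xs[:, : j + 1])
        if r == rank:
            return j
        rank = r
    return Xs.shape[1] - 1


def profile_h2(
    td: TransformedData,
    X_t: np.ndarray,
    bounds: tuple = (H2_EPS, 1.0 - H2_EPS),
    tol: float = 1e-4,
    n_grid: int = 21,
    counter: Optional[FitCounter] = None,
):
    """Minimize -2 log L over h2 by a coarse grid plus bounded Brent refinement.

    The grid guards against local minima in flat profiles; refinement runs in
    the bracket around the best grid point. Returns (h2_opt, WLSFit at it);
    a boundary optimum is returned as-is with a debug log.
    """
    lo, hi = bounds
    if not 0.0 <= lo < hi < 1.0:
        raise ValueError(f"bad h2 bounds {bounds}")
    lo = max(lo, H2_EPS)
    cache: dict = {}

    def objective(h2: float) -> float:
        h2 = float(min(max(h2, lo), hi))
        if h2 not in cache:
            cache[h2] = wls_fit(td, X_t, h2, counter)
        return cache[h2].neg2loglik

    if n_grid >= 2:
        grid = np.linspace(lo, hi, n_grid)
        vals = [objective(g) for g in grid]
        k = int(np.argmin(vals))
        blo = grid[max(k - 1, 0)]
        bhi = grid[min(k + 1, n_grid - 1)]
    else:
        blo, bhi = lo, hi
    res = optimize.minimize_scalar(
        objective, bounds=(blo, bhi), method="bounded", options={"xatol": tol}
    )
    objective(float(res.x))  # ensure cached
    h2_opt = min(cache, key=lambda h: cache[h].neg2loglik)
    if h2_opt >= hi - 10 * tol or h2_opt <= lo + 10 * tol:
        logger.debug("h2 profile optimum %.5f at search boundary %s", h2_opt, bounds)
    return h2_opt, cache[h2_opt]


def fit_null(td: TransformedData, counter: Optional[FitCounter] = None) -> NullModelFit:
    """Genomic heritability: profile h2 under the intercept-only model."""
    if np.std(td.y_raw) == 0:
        raise ValueError("phenotype is constant; nothing to fit")
    X_t = td.intercept_t[:, None]
    h2, fit = profile_h2(td, X_t, counter=counter)
    return NullModelFit(
        h2_genomic=h2,
        neg2loglik=fit.neg2loglik,
        sigma2_eps=fit.sigma2_eps,
        mu_hat=float(fit.beta[0]),
    )


def unified_f_test(
    fit_null_at_h2: WLSFit,
    fit_full: WLSFit,
    n: int,
    df_beta: int,
    chisq: bool = False,
):
    """Nested-model F for a unit of any width, at a common h2.

    F = ((RSS0 - RSS1)/df_beta) / (RSS1/df_eps) with df_eps = n - df_beta - 1,
    RSS0/RSS1 the weighted residual sums of squares of the intercept-only and
    full fits. With ``chisq`` the large-sample chi^2(df_beta) tail of
    df_beta * F is reported instead of the exact F tail.
    """
    if abs(fit_null_at_h2.h2 - fit_full.h2) > 1e-12:
        raise ValueError("null and full fits were computed at different h2")
    df_eps = n - df_beta - 1
    if df_eps < 1:
        raise ValueError(f"df_eps = {df_eps} < 1 (n too small for df_beta {df_beta})")
    rss0, rss1 = fit_null_at_h2.rss_weighted, fit_full.rss_weighted
    if rss1 <= 0.0:
        logger.warning("perfect fit (weighted RSS = 0); returning p = 0 sentinel")
        return math.inf, 0.0
    F = max((rss0 - rss1) / df_beta / (rss1 / df_eps), 0.0)
    if chisq:
        p = float(stats.chi2.sf(df_beta * F, df_beta))
    else:
        p = float(stats.f.sf(F, df_beta, df_eps))
    return F, p


def explained_variance(beta_unit: np.ndarray, unit: UnitDesign, y_raw: np.ndarray) -> float:
    """Percent phenotypic variance captured by the unit: 100 var(X b)/var(y)."""
    vy = float(np.var(y_raw))
    if vy == 0:
        return 0.0
    g = unit.columns @ np.asarray(beta_unit)
    return float(np.clip(100.0 * np.var(g) / vy, 0.0, 100.0))


def _result(unit, fit0, fit1, td, mode, chisq) -> UnitTestResult:
    F, p = unified_f_test(fit0, fit1, td.n, unit.df_beta, chisq=chisq)
    return UnitTestResult(
        unit_id=unit.unit_id,
        unit_kind=unit.unit_kind,
        df_beta=unit.df_beta,
        df_eps=td.n - unit.df_beta - 1,
        F=F,
        p=p,
        neg_log10_p=-math.log10(max(p, P_FLOOR)),
        h2_used=fit1.h2,
        beta=np.asarray(fit1.beta[1:]),
        explained_var_pct=explained_variance(fit1.beta[1:], unit, td.y_raw),
        mode=mode,
        chromosome=unit.chromosome,
        span_bp=unit.span_bp,
        n_snps=unit.n_snps,
        n_alleles=unit.n_alleles,
    )


def test_unit_emmax(
    td: TransformedData,
    unit: UnitDesign,
    eig: EigenSystem,
    h2_fixed: float,
    null_fit_at_h2: Optional[WLSFit] = None,
    counter: Optional[FitCounter] = None,
    chisq: bool = False,
) -> UnitTestResult:
    """One weighted regression at the fixed genomic heritability (EMMAX pass).

    The intercept-only fit at h2_fixed is shared across units; pass it in to
    avoid recomputing it per unit.
    """
    X_t = np.column_stack([td.intercept_t, eig.vectors.T @ unit.columns])
    fit1 = wls_fit(td, X_t, h2_fixed, counter)
    fit0 = null_fit_at_h2
    if fit0 is None:
        fit0 = wls_fit(td, td.intercept_t[:, None], h2_fixed, counter)
    return _result(unit, fit0, fit1, td, "emmax", chisq)


def test_unit_exact(
    td: TransformedData,
    unit: UnitDesign,
    eig: EigenSystem,
    h2_start: float,
    counter: Optional[FitCounter] = None,
    chisq: bool = False,
    tol: float = 1e-4,
) -> UnitTestResult:
    """Per-unit h2 optimization: search downward from the genomic heritability.

    The unit's polygenic heritability can only lose what the unit itself
    explains, so the search runs over (0, h2_start] plus a 0.05 headroom band
    above h2_start (null units optimize essentially at h2_start, which would
    otherwise sit exactly on the boundary); if the optimum still lands on the
    extended bound the interval keeps growing in 0.05 steps (logged) up to 1.
    The intercept-only model is refit at the unit's optimal h2 before the F
    test so both fits share one covariance.
    """
    X_t = np.column_stack([td.intercept_t, eig.vectors.T @ unit.columns])
    lo = H2_EPS
    cap = 1.0 - H2_EPS
    hi = min(float(np.clip(h2_start, 1e-3, cap)) + 0.05, cap)
    while True:
        h2_opt, fit1 = profile_h2(td, X_t, (lo, hi), tol=tol, n_grid=3, counter=counter)
        if h2_opt < hi - 1e-3 or hi >= cap:
            break
        hi = min(hi + 0.05, cap)
        logger.debug("unit %s: h2 optimum at boundary, extending to %.3f", unit.unit_id, hi)
    if h2_opt > h2_start:
        logger.debug("unit %s: optimal h2 %.4f above the genomic estimate %.4f",
                     unit.unit_id, h2_opt, h2_start)
    fit0 = wls_fit(td, td.intercept_t[:, None], h2_opt, counter)
    return _result(unit, fit0, fit1, td, "exact", chisq)
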