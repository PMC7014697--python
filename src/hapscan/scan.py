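"""Genome-wide scan orchestration: exact, EMMAX, and two-pass modes.

exact  — profile the polygenic heritability per tested unit (slow, reference).
emmax  — fix every unit's heritability at the genomic (null-model) estimate;
         one weighted regression per unit.
two_pass — EMMAX screen over all units, then exact re-testing of units whose
         screening p-value passes ``screen_alpha``; the total cost stays
         between one and two genome-wide regression scans.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import GenotypeMatrix, PhenotypeVector
from .haplotype_builder import BlockSet, encode_units
from .kinship import EigenSystem
from .lmm import (
    FitCounter,
    RankDeficientDesign,
    UnitTestResult,
    fit_null,
    test_unit_emmax,
    test_unit_exact,
    transform,
    wls_fit,
)

logger = logging.getLogger(__name__)

CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, 1))  # 0.45493...


@dataclasses.dataclass
class ScanConfig:
    unit_kind: str = "snp"  # snp | hap_allele | hap_block
    mode: str = "two_pass"  # exact | emmax | two_pass
    screen_alpha: float = 0.05
    alpha: float = 0.05
    fgt_cutoff: float = 0.01
    rare_freq: float = 0.02
    min_maf: float = 0.0
    seed: int = 0
    chisq_pvalues: bool = False
    h2_tol: float = 1e-4

    def __post_init__(self):
        if not 0.0 <= self.screen_alpha <= 1.0:
            raise ValueError("screen_alpha must lie in [0, 1]")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.mode not in ("exact", "emmax", "two_pass"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclasses.dataclass
class ScanResult:
    results: list
    threshold_neg_log10: float
    lambda_gc: float
    n_tests: int
    h2_genomic: float
    mode: str
    pass2_unit_ids: list
    n_fits: int = 0
    scan_rounds: float = float("nan")  # empirical i of the O(imn) cost
    skipped: list = dataclasses.field(default_factory=list)


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """Genome-wide significance on the -log10 scale: -log10(alpha / n_tests)."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    return -math.log10(alpha / n_tests)


def genomic_control_lambda(results) -> float:
    """Inflation factor on a common 1-df chi-square scale.

    Each p-value (whatever the unit's df) is mapped to the chi^2(1) quantile
    it would correspond to; lambda is the median quantile over its null
    median. Exact-zero sentinel p-values are excluded with a warning.
    """
    results = list(results) if not isinstance(results, np.ndarray) else results
    if len(results) and isinstance(results[0], UnitTestResult):
        p = np.array([r.p for r in results], dtype=float)
    else:
        p = np.asarray(results, dtype=float)
    if p.size < 20:
        raise ValueError("need at least 20 tests for a stable genomic-control estimate")
    zero = p <= 0.0
    if zero.any():
        logger.warning("excluding %d zero p-value sentinels from lambda", int(zero.sum()))
        p = p[~zero]
    q = stats.chi2.isf(p, 1)
    return float(np.median(q) / CHI2_1_MEDIAN)


def run_scan(
    G: GenotypeMatrix,
    y: PhenotypeVector,
    blocks: Optional[BlockSet],
    cfg: ScanConfig,
    eig: EigenSystem,
) -> ScanResult:
    """Scan all units of ``cfg.unit_kind``; inputs must already be aligned.

    Degenerate units (rank-deficient or constant designs) are skipped with a
    logged reason. Output order is genome order; in two-pass mode the exact
    re-test result replaces the screening result for every re-tested unit.
    """
    counter = FitCounter()
    td = transform(y, eig)
    null = fit_null(td, counter)
    units = list(encode_units(G, blocks, cfg.unit_kind))
    results: list = []
    kept_units: list = []
    skipped: list = []
    if cfg.mode in ("emmax", "two_pass"):
        fit0 = wls_fit(td, td.intercept_t[:, None], null.h2_genomic, counter)
        for unit in units:
            r, why = _try_unit(
                lambda: test_unit_emmax(
                    td, unit, eig, null.h2_genomic, null_fit_at_h2=fit0,
                    counter=counter, chisq=cfg.chisq_pvalues,
                ),
                unit,
            )
            if r is None:
                skipped.append((unit.unit_id, why))
            else:
                results.append(r)
                kept_units.append(unit)
    else:
        for unit in units:
            r, why = _try_unit(
                lambda: test_unit_exact(
                    td, unit, eig, null.h2_genomic,
                    counter=counter, chisq=cfg.chisq_pvalues, tol=cfg.h2_tol,
                ),
                unit,
            )
            if r is None:
                skipped.append((unit.unit_id, why))
            else:
                results.append(r)
                kept_units.append(unit)
    pass2_ids: list = []
    if cfg.mode == "two_pass":
        for i, r in enumerate(results):
            if r.p <= cfg.screen_alpha:
                r2, why = _try_unit(
                    lambda: test_unit_exact(
                        td, kept_units[i], eig, null.h2_genomic,
                        counter=counter, chisq=cfg.chisq_pvalues, tol=cfg.h2_tol,
                    ),
                    kept_units[i],
                )
                if r2 is not None:
                    results[i] = r2
                    pass2_ids.append(r2.unit_id)
        logger.info(
            "two-pass scan: %d units screened, %d re-tested exactly",
            len(results), len(pass2_ids),
        )
    n_tests = len(results)
    lam = genomic_control_lambda(results) if n_tests >= 20 else float("nan")
    rounds = counter.count / n_tests if n_tests else float("nan")
    logger.info(
        "%s scan of %d %s units: %d fits (i = %.2f scan equivalents), lambda = %.3f",
        cfg.mode, n_tests, cfg.unit_kind, counter.count, rounds, lam,
    )
    return ScanResult(
        results=results,
        threshold_neg_log10=bonferroni_threshold(max(n_tests, 1), cfg.alpha),
        lambda_gc=lam,
        n_tests=n_tests,
        h2_genomic=null.h2_genomic,
        mode=cfg.mode,
        pass2_unit_ids=pass2_ids,
        n_fits=counter.count,
        scan_rounds=rounds,
        skipped=skipped,
    )


def _try_unit(fn, unit):
    cols = unit.columns
    if np.any(cols.std(axis=0) == 0):
        logger.info("skipping %s: constant design column", unit.unit_id)
        return None, "constant column"
    try:
        return fn(), None
    except RankDeficientDesign as exc:
        logger.info("skipping %s: %s", unit.unit_id, exc)
        return None, str(exc)


RESULT_COLUMNS = [
    "unit_id", "unit_kind", "chrom", "start_bp", "end_bp", "n_snps", "n_alleles",
    "df_beta", "F", "neg_log10_p", "h2_used", "explained_var_pct", "mode",
    "significant",
]


def results_frame(res: ScanResult) -> pd.DataFrame:
    rows = []
    for r in res.results:
        rows.append(
            {
                "unit_id": r.unit_id,
                "unit_kind": r.unit_kind,
                "chrom": r.chromosome,
                "start_bp": r.span_bp[0],
                "end_bp": r.span_bp[1],
                "n_snps": r.n_snps if r.n_snps is not None else "",
                "n_alleles": r.n_alleles if r.n_alleles is not None else "",
                "df_beta": r.df_beta,
                "F": r.F,
                "neg_log10_p": r.neg_log10_p,
                "h2_used": r.h2_used,
                "explained_var_pct": r.explained_var_pct,
                "mode": r.mode,
                "significant": bool(r.neg_log10_p >= res.threshold_neg_log10),
            }
        )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def write_results(res: ScanResult, path) -> None:
    """Tab-separated results with a commented header of scan-level statistics."""
    with open(path, "w") as fh:
        fh.write(f"# n_tests={res.n_tests}\n")
        fh.write(f"# threshold_neg_log10={res.threshold_neg_log10:.6f}\n")
        fh.write(f"# lambda_gc={res.lambda_gc:.6f}\n")
        fh.write(f"# h2_genomic={res.h2_genomic:.6f}\n")
        fh.write(f"# mode={res.mode}\n")
        results_frame(res).to_csv(fh, sep="\t", index=False)


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def qq_manhattan_data(res: ScanResult):
    """Plot-ready tables: QQ (expected vs observed -log10 p) and Manhattan.

    QQ expected quantiles use the (i - 0.5)/n plotting positions; both columns
    are sorted descending so row i pairs the i-th largest observed with the
    i-th largest expected. Manhattan coordinates are cumulative bp across
    chromosomes in genome order.
    """
    n = res.n_tests
    obs = np.sort([r.neg_log10_p for r in res.results])[::-1]
    exp = -np.log10((np.arange(1, n + 1) - 0.5) / n)
    qq = pd.DataFrame({"expected_neg_log10_p": exp, "observed_neg_log10_p": obs})
    chroms = [r.chromosome for r in res.results]
    offsets: dict = {}
    running = 0
    for c in dict.fromkeys(chroms):
        offsets[c] = running
        running += max(
            (r.span_bp[1] for r in res.results if r.chromosome == c), default=0
        )
    rows = [
        {
            "unit_id": r.unit_id,
            "chrom": r.chromosome,
            "genome_bp": offsets[r.chromosome] + (r.span_bp[0] + r.span_bp[1]) / 2.0,
            "neg_log10_p": r.neg_log10_p,
        }
        for r in res.results
    ]
    return qq, pd.DataFrame(rows)
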