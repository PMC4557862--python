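"""Case-control association: logistic regression with covariates,
Nagelkerke pseudo-R^2, carrier frequencies, and the step-wise conditional
HLA scan.

Every marker (SNP or HLA allele) is additively coded as 0/1/2 copies and
tested by a Wald z on its log-odds coefficient from a logistic model that
may include age, sex, and principal-component covariates.  The step-wise
conditional scan re-tests all markers conditioning on previously selected
HLA alleles: at each step the most significant HLA allele is selected
(even when a SNP is more significant and even when the allele itself
misses Bonferroni), and the scan stops once no marker of any kind passes
the per-step Bonferroni threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

logger = logging.getLogger(__name__)

__all__ = [
    "LogisticFit",
    "AssocRecord",
    "ConditionalScanResult",
    "logistic_fit",
    "nagelkerke_r2",
    "carrier_frequency",
    "allele_scan",
    "stepwise_conditional_scan",
]

SEPARATION_BOUND = 15.0


@dataclass
class LogisticFit:
    beta: np.ndarray
    se: np.ndarray
    loglik: float
    converged: bool
    separated: bool
    n_iter: int


@dataclass
class AssocRecord:
    marker: str
    beta: float
    se: float
    odds_ratio: float
    p: float
    n: int
    covariates: str = ""
    nagelkerke_r2: float = float("nan")
    separated: bool = False


@dataclass
class ConditionalScanResult:
    selected: list[str]
    steps: list[list[AssocRecord]]
    thresholds: list[float]
    stop_reason: str


def logistic_fit(y: np.ndarray, X: np.ndarray) -> LogisticFit:
    """Maximum-likelihood logistic regression via IRLS.

    Newton/IRLS with tolerance 1e-8 on the deviance and at most 50
    iterations; Wald standard errors from the inverse observed
    information.  Complete separation is flagged (not raised) when any
    coefficient escapes |beta| > 15; the caller should blank the p-value.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    if n <= k:
        raise ValueError("need more observations than parameters")
    if y.min() == y.max():
        raise ValueError("outcome must contain both classes")

    beta = np.zeros(k)
    dev_old = np.inf
    separated = converged = False
    it = 0
    for it in range(1, 51):
        eta = X @ beta
        p = expit(eta)
        p = np.clip(p, 1e-12, 1 - 1e-12)
        w = p * (1 - p)
        XtW = X.T * w
        H = XtW @ X
        g = X.T @ (y - p)
        try:
            delta = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            separated = True
            break
        beta = beta + delta
        if np.max(np.abs(beta)) > SEPARATION_BOUND:
            separated = True
            break
        dev = -2.0 * np.sum(y * np.log(p) + (1 - y) * np.log(1 - p))
        if abs(dev_old - dev) < 1e-8:
            converged = True
            break
        dev_old = dev

    eta = X @ beta
    p = np.clip(expit(eta), 1e-12, 1 - 1e-12)
    loglik = float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))
    w = p * (1 - p)
    H = (X.T * w) @ X
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(k, np.nan)
        separated = True
    return LogisticFit(beta, se, loglik, converged, separated, it)


def nagelkerke_r2(ll_full: float, ll_null: float, n: int) -> float:
    """Nagelkerke's rescaled Cox-Snell pseudo-R^2.

    r^2 = [1 - exp((2/n)(ll_null - ll_full))] / [1 - exp((2/n) ll_null)].
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if ll_full < ll_null - 1e-9:
        raise ValueError("full-model log-likelihood below the null's")
    num = 1.0 - np.exp((2.0 / n) * (ll_null - ll_full))
    den = 1.0 - np.exp((2.0 / n) * ll_null)
    if den == 0:
        return 0.0
    return float(num / den)


def carrier_frequency(dosages: np.ndarray) -> float:
    """Fraction of individuals carrying >= 1 copy, among non-missing calls."""
    d = np.asarray(dosages)
    ok = d >= 0
    if not ok.any():
        raise ValueError("no non-missing dosages")
    return float((d[ok] >= 1).sum() / ok.sum())


def _fit_marker(
    y: np.ndarray,
    dosage: np.ndarray,
    covar: np.ndarray | None,
    marker: str,
    with_r2: bool = False,
) -> AssocRecord | None:
    ok = dosage >= 0
    if covar is not None:
        ok &= ~np.isnan(covar).any(axis=1)
    yv, dv = y[ok], dosage[ok].astype(float)
    if yv.size == 0 or yv.min() == yv.max():
        return None
    carriers = int((dv >= 1).sum())
    if carriers < 5:
        logger.info("marker %s skipped: %d carriers (<5)", marker, carriers)
        return None
    if dv.min() == dv.max():
        logger.info("marker %s skipped: constant dosage", marker)
        return None
    cols = [np.ones(yv.size)]
    names = ["intercept"]
    if covar is not None:
        C = covar[ok]
        cols.append(C)
        names += [f"c{j}" for j in range(C.shape[1])]
    X = np.column_stack(cols + [dv])
    fit = logistic_fit(yv, X)
    b, s = fit.beta[-1], fit.se[-1]
    if fit.separated or not np.isfinite(s) or s == 0:
        return AssocRecord(marker, float(b), float("nan"), float(np.exp(np.clip(b, -50, 50))),
                           float("nan"), int(yv.size),
                           ",".join(names[1:]), float("nan"), True)
    z = b / s
    p = 2.0 * stats.norm.sf(abs(z))
    r2 = float("nan")
    if with_r2:
        null_fit = logistic_fit(yv, X[:, :-1]) if X.shape[1] > 1 else None
        ll_null = null_fit.loglik if null_fit else 0.0
        r2 = nagelkerke_r2(fit.loglik, ll_null, yv.size)
    return AssocRecord(marker, float(b), float(s), float(np.exp(b)),
                       float(p), int(yv.size), ",".join(names[1:]), r2, False)


def allele_scan(
    dosages: pd.DataFrame,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    with_r2: bool = False,
) -> list[AssocRecord]:
    """Per-marker additive logistic association scan.

    ``dosages``: samples x markers 0/1/2 table (negative = missing); the
    outcome and covariate rows must align with it.  Markers with fewer
    than 5 carriers, constant dosage, or all-missing calls are skipped
    with a log entry; separation yields a flagged record with p = NaN.
    """
    y = np.asarray(y, dtype=float)
    if len(dosages) != y.size:
        raise ValueError("phenotype not aligned to dosage rows")
    records = []
    for marker in dosages.columns:
        rec = _fit_marker(
            y, dosages[marker].to_numpy(), covariates, str(marker), with_r2
        )
        if rec is not None:
            records.append(rec)
    return records


def stepwise_conditional_scan(
    dosages: pd.DataFrame,
    hla_markers: list[str],
    y: np.ndarray,
    base_covariates: np.ndarray | None = None,
    alpha: float = 0.05,
    max_steps: int = 20,
) -> ConditionalScanResult:
    """Step-wise conditional association scan anchored on HLA alleles.

    Each step scans every not-yet-selected marker conditioning on the
    base covariates plus all previously selected HLA alleles.  The most
    significant HLA allele is selected (regardless of whether a SNP beats
    it, and regardless of Bonferroni); a separated top allele is flagged
    and the next-best selected.  The scan stops when no marker — SNP or
    HLA — passes the per-step Bonferroni threshold alpha / (markers
    tested that step).
    """
    hla_set = [h for h in hla_markers if h in dosages.columns]
    if not hla_set:
        raise ValueError("no HLA markers present in the dosage table")
    y = np.asarray(y, dtype=float)

    selected: list[str] = []
    steps: list[list[AssocRecord]] = []
    thresholds: list[float] = []
    stop_reason = "max steps reached"
    for _ in range(max_steps):
        if base_covariates is not None:
            covar = base_covariates
        else:
            covar = None
        if selected:
            sel = dosages[selected].to_numpy(dtype=float)
            covar = sel if covar is None else np.column_stack([covar, sel])
        candidates = [c for c in dosages.columns if c not in selected]
        records = []
        for marker in candidates:
            rec = _fit_marker(y, dosages[marker].to_numpy(), covar, str(marker))
            if rec is not None:
                records.append(rec)
        steps.append(records)
        n_tested = len(records)
        if n_tested == 0:
            thresholds.append(float("nan"))
            stop_reason = "no testable markers"
            break
        threshold = alpha / n_tested
        thresholds.append(threshold)
        valid_p = [r.p for r in records if np.isfinite(r.p)]
        if not valid_p or min(valid_p) > threshold:
            stop_reason = "no marker passes Bonferroni"
            break
        hla_recs = [r for r in records if r.marker in hla_set
                    and r.marker not in selected]
        hla_recs = [r for r in hla_recs if not r.separated and np.isfinite(r.p)]
        if not hla_recs:
            stop_reason = "no selectable HLA allele"
            break
        best = min(hla_recs, key=lambda r: r.p)
        selected.append(best.marker)
    return ConditionalScanResult(selected, steps, thresholds, stop_reason)
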