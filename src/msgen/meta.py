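"""Combining association evidence across studies.

Fisher's combined probability reproduces the per-allele meta p-values of
the three-study HLA table (df = 2k); inverse-variance fixed-effect and
DerSimonian-Laird random-effects pooling serve the genome-wide SNP meta;
standard errors can be reconstructed from printed OR/p pairs; and the
Benjamini-Hochberg step-up controls the FDR for genome-wide screens.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "MetaRecord",
    "fisher_combine",
    "se_from_summary",
    "ivw_fixed",
    "dl_random",
    "bh_fdr",
]


@dataclass
class MetaRecord:
    method: str  # "fisher" | "fixed" | "random"
    p: float
    statistic: float = float("nan")  # Fisher X^2, or pooled z
    df: int = 0
    beta: float = float("nan")
    se: float = float("nan")
    tau2: float = float("nan")
    q_het: float = float("nan")
    n_studies: int = 0


def fisher_combine(p_values) -> MetaRecord:
    """Fisher's combined probability: X^2 = -2 sum ln p_i on 2k df."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]; a printed 0 cannot "
                         "be combined")
    x2 = float(-2.0 * np.log(p).sum())
    df = 2 * p.size
    return MetaRecord("fisher", float(stats.chi2.sf(x2, df)), x2, df,
                      n_studies=p.size)


def se_from_summary(odds_ratio: float, p: float) -> float:
    """Reconstruct SE(ln OR) from a printed OR and two-sided p.

    SE = |ln OR| / z with z the two-sided normal quantile; degenerate at
    OR = 1.
    """
    if odds_ratio <= 0:
        raise ValueError("odds ratio must be positive")
    if odds_ratio == 1:
        raise ValueError("SE reconstruction degenerate at OR = 1")
    if not 0 < p < 1:
        raise ValueError("p must lie in (0, 1)")
    z = stats.norm.isf(p / 2.0)
    return float(abs(np.log(odds_ratio)) / z)


def ivw_fixed(betas, ses) -> MetaRecord:
    """Inverse-variance-weighted fixed-effect pooling."""
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    if b.size != s.size or b.size == 0:
        raise ValueError("betas and SEs must be nonempty and equal-length")
    if np.any(s <= 0):
        raise ValueError("SEs must be positive")
    w = 1.0 / s**2
    beta = float((w * b).sum() / w.sum())
    se = float(1.0 / np.sqrt(w.sum()))
    z = beta / se
    q = float((w * (b - beta) ** 2).sum())
    return MetaRecord("fixed", float(2 * stats.norm.sf(abs(z))), float(z),
                      beta=beta, se=se, q_het=q, n_studies=b.size)


def dl_random(betas, ses) -> MetaRecord:
    """DerSimonian-Laird random-effects pooling.

    tau^2 = max(0, (Q - df) / (sum w - sum w^2 / sum w)); weights are
    re-formed as 1/(SE^2 + tau^2).  Homogeneous inputs (Q <= df)
    truncate tau^2 to 0 and coincide with the fixed-effect result.
    """
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    if b.size < 2:
        raise ValueError("random-effects pooling needs >= 2 studies")
    fixed = ivw_fixed(b, s)
    w = 1.0 / s**2
    df = b.size - 1
    denom = w.sum() - (w**2).sum() / w.sum()
    tau2 = max(0.0, (fixed.q_het - df) / denom)
    w_star = 1.0 / (s**2 + tau2)
    beta = float((w_star * b).sum() / w_star.sum())
    se = float(1.0 / np.sqrt(w_star.sum()))
    z = beta / se
    return MetaRecord("random", float(2 * stats.norm.sf(abs(z))), float(z),
                      beta=beta, se=se, tau2=float(tau2),
                      q_het=fixed.q_het, n_studies=b.size)


def bh_fdr(p_values, q: float = 0.1) -> np.ndarray:
    """Benjamini-Hochberg step-up discovery flags at FDR level q."""
    p = np.asarray(p_values, dtype=float)
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject
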