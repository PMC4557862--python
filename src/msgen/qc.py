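"""Variant-level quality control and LD pruning.

Filtering keeps variants with minor allele frequency >= 1 % and missing
call rate <= 0.1 % (the defaults), applied in that order so every removal
is attributed to exactly one category.  Pruning removes one member of any
within-window pair whose squared dosage correlation exceeds the r^2
threshold (default 0.1), PLINK indep-pairwise style with a sliding window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .genio import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = ["QcReport", "filter_variants", "ld_prune"]


@dataclass
class QcReport:
    n_input: int
    n_removed_maf: int
    n_removed_missing: int
    n_removed_prune: int
    surviving_ids: list[str]

    def __post_init__(self) -> None:
        total = (len(self.surviving_ids) + self.n_removed_maf
                 + self.n_removed_missing + self.n_removed_prune)
        if total != self.n_input:
            raise ValueError("QC report does not account for every variant")


def filter_variants(
    G: GenotypeMatrix, maf_min: float = 0.01, miss_max: float = 0.001
) -> tuple[GenotypeMatrix, QcReport]:
    """Drop variants with MAF < maf_min or missing rate > miss_max.

    The MAF criterion is applied first; a variant failing both is counted
    under MAF.  Removing everything returns an empty matrix with a
    warning rather than an error.
    """
    if G.n_variants == 0:
        raise ValueError("empty genotype matrix")
    p = G.allele_frequency()
    maf = np.minimum(p, 1 - p)
    maf = np.where(np.isnan(maf), 0.0, maf)
    miss = G.missing_rate()

    fail_maf = maf < maf_min
    fail_miss = (miss > miss_max) & ~fail_maf
    keep = ~fail_maf & ~fail_miss
    if not keep.any():
        logger.warning("all %d variants removed by QC", G.n_variants)

    report = QcReport(
        n_input=G.n_variants,
        n_removed_maf=int(fail_maf.sum()),
        n_removed_missing=int(fail_miss.sum()),
        n_removed_prune=0,
        surviving_ids=list(G.variants.loc[keep, "id"]),
    )
    return G.take_variants(np.where(keep)[0]), report


def _pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of dosages, pairwise-complete."""
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return 0.0
    xv, yv = x[ok].astype(float), y[ok].astype(float)
    sx, sy = xv.std(), yv.std()
    if sx == 0 or sy == 0:
        return 0.0
    r = np.corrcoef(xv, yv)[0, 1]
    return float(r * r)


def ld_prune(
    G: GenotypeMatrix,
    window: int = 50,
    step: int = 5,
    r2_max: float = 0.1,
) -> list[str]:
    """Greedy sliding-window LD pruning; returns surviving variant ids.

    Within each window of ``window`` variants (advanced by ``step``), for
    every kept pair in position order the later member is removed when
    their squared dosage correlation exceeds ``r2_max``.  Variants must
    be position-sorted within chromosome; the result is deterministic.
    """
    v = G.variants
    for chrom, grp in v.groupby("chrom", sort=False):
        if np.any(np.diff(grp["pos"].to_numpy()) < 0):
            raise ValueError(
                f"variants on chromosome {chrom} are not position-sorted; "
                "sort before pruning"
            )
    keep = np.ones(G.n_variants, dtype=bool)
    D = G.dosages
    for chrom in v["chrom"].unique():
        idx = np.where((v["chrom"] == chrom).to_numpy())[0]
        start = 0
        while start < len(idx):
            win = idx[start:start + window]
            for a in range(len(win)):
                i = win[a]
                if not keep[i]:
                    continue
                for b in range(a + 1, len(win)):
                    j = win[b]
                    if not keep[j]:
                        continue
                    if _pairwise_r2(D[:, i], D[:, j]) > r2_max:
                        keep[j] = False
            if start + window >= len(idx):
                break
            start += step
    survivors = list(v.loc[keep, "id"])
    logger.info(
        "LD pruning: %d of %d variants survive (r2 <= %g)",
        len(survivors), G.n_variants, r2_max,
    )
    return survivors
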