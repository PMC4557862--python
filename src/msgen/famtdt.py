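"""Trio transmission counting and the transmission disequilibrium test.

The TDT compares, over parents heterozygous for a counted allele, how
often that allele was transmitted (T) versus not transmitted (U) to the
affected proband.  Under the null of no association/linkage, T and U are
exchangeable and (T-U)^2/(T+U) is chi-square with 1 df.  HLA alleles are
handled by collapsing each allele to a biallelic allele-vs-rest dosage
before counting, matching the 0/1/2 recoding used for SNPs.

Mixed-ancestry trios contribute transmissions from both parents.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genio import MISSING

logger = logging.getLogger(__name__)

__all__ = ["TrioSet", "TdtRecord", "count_transmissions", "tdt", "tdt_scan"]


@dataclass
class TrioSet:
    """Father/mother/proband dosage triples plus per-trio metadata.

    Each dosage array has shape (n_trios, n_markers) with values in
    {0, 1, 2, MISSING}.  ``meta`` carries one row per trio with at least
    ``father_population``, ``mother_population`` and the derived
    ``aj_trio`` flag (at least one Ashkenazi parent).
    """

    fathers: np.ndarray
    mothers: np.ndarray
    probands: np.ndarray
    marker_ids: list[str]
    meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.fathers = np.asarray(self.fathers, dtype=np.int8)
        self.mothers = np.asarray(self.mothers, dtype=np.int8)
        self.probands = np.asarray(self.probands, dtype=np.int8)
        if not (self.fathers.shape == self.mothers.shape == self.probands.shape):
            raise ValueError("father/mother/proband dosage shapes differ")
        if self.fathers.shape[1] != len(self.marker_ids):
            raise ValueError("marker_ids length does not match dosage columns")

    @property
    def n_trios(self) -> int:
        return self.fathers.shape[0]

    def subset(self, trio_index: np.ndarray) -> "TrioSet":
        meta = self.meta.iloc[trio_index].reset_index(drop=True) if len(self.meta) else self.meta
        return TrioSet(
            self.fathers[trio_index],
            self.mothers[trio_index],
            self.probands[trio_index],
            list(self.marker_ids),
            meta,
        )


@dataclass
class TdtRecord:
    marker: str
    t_count: int
    u_count: int
    odds_ratio: float
    chi2: float
    p: float
    n_informative: int
    n_mendel_excluded: int = 0


def mendelian_consistent(f: np.ndarray, m: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Elementwise consistency of proband dosage with parental dosages.

    A parent with dosage 0 transmits 0 copies, dosage 2 transmits 1,
    dosage 1 transmits 0 or 1, so the proband must lie in
    [(f==2)+(m==2), (f>0)+(m>0)].  Missing entries are treated as
    consistent (they are excluded from counting separately).
    """
    f, m, c = (np.asarray(x) for x in (f, m, c))
    lo = (f == 2).astype(int) + (m == 2).astype(int)
    hi = (f > 0).astype(int) + (m > 0).astype(int)
    ok = (c >= lo) & (c <= hi)
    any_missing = (f == MISSING) | (m == MISSING) | (c == MISSING)
    return ok | any_missing


def count_transmissions(
    trios: TrioSet, marker: str | int
) -> tuple[int, int, int, int]:
    """Count transmitted (T) and untransmitted (U) alleles at one marker.

    Each heterozygous parent contributes one transmission event; the
    number of counted-allele copies the proband received from its het
    parents is the proband dosage minus the homozygous parents' fixed
    contribution.  Trios with a missing member or a Mendelian
    inconsistency at this marker are excluded (the exclusion count is
    returned and logged).

    Returns (T, U, n_informative_trios, n_mendel_excluded).
    """
    j = trios.marker_ids.index(marker) if isinstance(marker, str) else int(marker)
    f = trios.fathers[:, j].astype(int)
    m = trios.mothers[:, j].astype(int)
    c = trios.probands[:, j].astype(int)

    complete = (f != MISSING) & (m != MISSING) & (c != MISSING)
    consistent = mendelian_consistent(f, m, c)
    n_mendel = int((complete & ~consistent).sum())
    if n_mendel:
        logger.info(
            "marker %s: excluded %d Mendelian-inconsistent trios",
            trios.marker_ids[j], n_mendel,
        )
    use = complete & consistent

    fu, mu, cu = f[use], m[use], c[use]
    n_het = (fu == 1).astype(int) + (mu == 1).astype(int)
    fixed = (fu == 2).astype(int) + (mu == 2).astype(int)
    transmitted = cu - fixed  # copies received from het parents
    T = int(transmitted[n_het > 0].sum())
    U = int((n_het - transmitted)[n_het > 0].sum())
    n_informative = int((n_het > 0).sum())
    if n_informative == 0:
        logger.warning("marker %s: no heterozygous parents", trios.marker_ids[j])
    return T, U, n_informative, n_mendel


def tdt(T: int, U: int, marker: str = "", n_informative: int = 0,
        n_mendel_excluded: int = 0) -> TdtRecord:
    """Classical 1-df TDT from transmission counts (no continuity correction).

    chi2 = (T-U)^2/(T+U); the odds ratio T/U is undefined (NaN) when U=0.
    """
    if T < 0 or U < 0:
        raise ValueError("transmission counts must be nonnegative")
    if T + U == 0:
        raise ValueError("TDT undefined: no informative transmissions (T+U=0)")
    chi2 = (T - U) ** 2 / (T + U)
    p = float(stats.chi2.sf(chi2, df=1))
    orr = T / U if U > 0 else float("nan")
    return TdtRecord(marker, T, U, orr, float(chi2), p,
                     n_informative, n_mendel_excluded)


def tdt_scan(trios: TrioSet, markers: Sequence[str] | None = None) -> list[TdtRecord]:
    """Run the TDT over a set of markers, skipping uninformative ones."""
    if markers is None:
        markers = trios.marker_ids
    records = []
    for marker in markers:
        T, U, n_inf, n_mendel = count_transmissions(trios, marker)
        if T + U == 0:
            logger.info("marker %s skipped: T+U=0", marker)
            continue
        records.append(tdt(T, U, marker, n_inf, n_mendel))
    return records
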