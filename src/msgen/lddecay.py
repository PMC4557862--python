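"""Two-locus linkage disequilibrium and distance-binned decay profiles.

Haplotype frequencies at a pair of unphased biallelic loci are estimated
by EM over the double-heterozygote phase ambiguity (composite-genotype
EM; the source datasets were unphased chips).  From the four haplotype
frequencies the module derives D, D' and r^2, and summarises groups of
samples as median D'/r^2 per inter-locus distance bin — the decay
profile that contrasts a bottlenecked founder population's longer-range
LD with a larger outbred one.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._rng import stream
from .genio import MISSING

__all__ = [
    "HapFreqs",
    "em_hapfreq",
    "hap_freqs_from_phased",
    "ld_stats",
    "decay_profile",
]


@dataclass
class HapFreqs:
    """Two-locus haplotype frequencies (f_AB, f_Ab, f_aB, f_ab), sum 1."""

    f_ab_: np.ndarray  # length-4 vector in the order AB, Ab, aB, ab

    def __post_init__(self) -> None:
        f = np.asarray(self.f_ab_, dtype=float)
        if f.shape != (4,) or np.any(f < -1e-12) or abs(f.sum() - 1) > 1e-9:
            raise ValueError("haplotype frequencies must be 4 nonnegative "
                             "values summing to 1")
        self.f_ab_ = np.clip(f, 0.0, 1.0)

    @property
    def f_AB(self) -> float:
        return float(self.f_ab_[0])

    @property
    def f_Ab(self) -> float:
        return float(self.f_ab_[1])

    @property
    def f_aB(self) -> float:
        return float(self.f_ab_[2])

    @property
    def f_ab(self) -> float:
        return float(self.f_ab_[3])

    @property
    def p_A(self) -> float:
        return float(self.f_ab_[0] + self.f_ab_[1])

    @property
    def p_B(self) -> float:
        return float(self.f_ab_[0] + self.f_ab_[2])


def _genotype_counts(d1: np.ndarray, d2: np.ndarray) -> np.ndarray:
    """3x3 joint genotype counts over pairwise-complete individuals."""
    ok = (d1 != MISSING) & (d2 != MISSING)
    if ok.sum() < 1:
        raise ValueError("no complete two-locus genotypes")
    n = np.zeros((3, 3))
    np.add.at(n, (d1[ok], d2[ok]), 1)
    return n


def em_hapfreq(
    d1: np.ndarray | None = None,
    d2: np.ndarray | None = None,
    counts: np.ndarray | None = None,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> HapFreqs:
    """EM haplotype-frequency estimate for two unphased biallelic loci.

    Input is either two dosage vectors or a 3x3 genotype-count table
    (rows: locus-1 dosage 0/1/2 of allele A; columns: locus-2 dosage of
    allele B).  All haplotype assignments are determined by the
    genotypes except in double heterozygotes, which the E-step splits
    between the AB/ab and Ab/aB phases.  Uniform start; the
    log-likelihood is non-decreasing and iteration stops when the
    frequencies move by less than ``tol``.
    """
    if counts is None:
        if d1 is None or d2 is None:
            raise ValueError("provide dosage vectors or a count table")
        counts = _genotype_counts(np.asarray(d1), np.asarray(d2))
    n = np.asarray(counts, dtype=float)
    if n.shape != (3, 3) or n.sum() < 1:
        raise ValueError("counts must be a populated 3x3 table")
    tot_hap = 2.0 * n.sum()
    # allele A dosage i contributes i copies of A, (2-i) of a
    p_A = (n.sum(axis=1) @ np.array([0, 1, 2])) / tot_hap
    p_B = (n.sum(axis=0) @ np.array([0, 1, 2])) / tot_hap
    if p_A in (0.0, 1.0) or p_B in (0.0, 1.0):
        raise ValueError("LD undefined: a locus is monomorphic")

    # fixed haplotype contributions from phase-unambiguous genotypes;
    # order AB, Ab, aB, ab with index (1-a)*2 + (1-b)
    base = np.zeros(4)
    for i, j in itertools.product(range(3), range(3)):
        c = n[i, j]
        if c == 0 or (i == 1 and j == 1):
            continue
        if i == 1:  # single het at locus 1: both haplotypes carry b = j/2
            haps = [(1, j // 2), (0, j // 2)]
        elif j == 1:
            haps = [(i // 2, 1), (i // 2, 0)]
        else:  # double homozygote
            haps = [(i // 2, j // 2)] * 2
        for a, b in haps:
            base[(1 - a) * 2 + (1 - b)] += c
    n_dh = n[1, 1]  # double heterozygotes

    f = np.full(4, 0.25)
    for _ in range(max_iter):
        # P(phase AB/ab) for a double het
        num = f[0] * f[3]
        den = num + f[1] * f[2]
        q = 0.5 if den == 0 else num / den
        new = base.copy()
        new[0] += n_dh * q
        new[3] += n_dh * q
        new[1] += n_dh * (1 - q)
        new[2] += n_dh * (1 - q)
        new /= tot_hap
        if np.max(np.abs(new - f)) < tol:
            f = new
            break
        f = new
    return HapFreqs(f)


def hap_freqs_from_phased(h1: np.ndarray, h2: np.ndarray) -> HapFreqs:
    """Direct haplotype counting for phased data (no EM needed)."""
    h1 = np.asarray(h1, dtype=int)
    h2 = np.asarray(h2, dtype=int)
    if h1.size != h2.size or h1.size == 0:
        raise ValueError("phased vectors must be nonempty and equal-length")
    f = np.array([
        ((h1 == 1) & (h2 == 1)).sum(),
        ((h1 == 1) & (h2 == 0)).sum(),
        ((h1 == 0) & (h2 == 1)).sum(),
        ((h1 == 0) & (h2 == 0)).sum(),
    ], dtype=float)
    return HapFreqs(f / f.sum())


def ld_stats(h: HapFreqs) -> tuple[float, float, float]:
    """(D, D', r^2) from two-locus haplotype frequencies.

    D = f_AB - p_A p_B; D' = |D| / D_max with D_max = min(p_A(1-p_B),
    (1-p_A)p_B) for D > 0 and min(p_A p_B, (1-p_A)(1-p_B)) for D < 0, so
    D' lies in [0, 1]; r^2 = D^2 / (p_A(1-p_A) p_B(1-p_B)).
    """
    p_A, p_B = h.p_A, h.p_B
    if not (0 < p_A < 1 and 0 < p_B < 1):
        raise ValueError("LD undefined at boundary allele frequencies")
    D = h.f_AB - p_A * p_B
    if D >= 0:
        d_max = min(p_A * (1 - p_B), (1 - p_A) * p_B)
    else:
        d_max = min(p_A * p_B, (1 - p_A) * (1 - p_B))
    dprime = 0.0 if d_max == 0 else abs(D) / d_max
    r2 = D * D / (p_A * (1 - p_A) * p_B * (1 - p_B))
    return float(D), float(min(dprime, 1.0)), float(min(r2, 1.0))


def decay_profile(
    data: np.ndarray,
    positions: np.ndarray,
    groups: Mapping[str, Sequence[int]],
    bins: Sequence[float] | None = None,
    n_subsample: int | None = None,
    max_dist: float = 500_000,
    max_pairs_per_bin: int = 500,
    phased: bool = False,
    seed: int = 0,
) -> pd.DataFrame:
    """Median D' and r^2 per inter-locus distance bin, per sample group.

    ``data`` is individuals x sites dosages (or haplotypes x sites when
    ``phased``); ``groups`` maps a label to row indices (haplotype rows
    2i, 2i+1 per individual when phased).  Groups are subsampled to a
    common ``n_subsample`` (seeded) per the equal-n comparison design;
    site pairs closer than ``max_dist`` are assigned to log-spaced bins
    (default 10 bins to 500 kb) and, beyond ``max_pairs_per_bin``, are
    seeded-subsampled within each bin.  Empty bins are emitted with NaN
    medians.
    """
    positions = np.asarray(positions, dtype=float)
    if np.any(np.diff(positions) <= 0):
        raise ValueError("positions must be strictly increasing")
    if bins is None:
        bins = np.logspace(np.log10(1000), np.log10(max_dist), 11)
        bins = np.concatenate([[0.0], bins])
    bins = np.asarray(bins, dtype=float)

    rng = stream(seed, "ld-subsample")
    sizes = {g: len(idx) for g, idx in groups.items()}
    if n_subsample is None:
        n_subsample = min(sizes.values())
    if any(n_subsample > s for s in sizes.values()):
        raise ValueError("n_subsample exceeds a group size")

    # enumerate pairs once, bin them, and cap per bin
    i_idx, j_idx = np.triu_indices(positions.size, k=1)
    dist = positions[j_idx] - positions[i_idx]
    in_range = dist < max_dist
    i_idx, j_idx, dist = i_idx[in_range], j_idx[in_range], dist[in_range]
    which_bin = np.digitize(dist, bins) - 1
    chosen: list[tuple[int, int, int]] = []
    for b in range(len(bins) - 1):
        members = np.where(which_bin == b)[0]
        if members.size > max_pairs_per_bin:
            members = rng.choice(members, size=max_pairs_per_bin, replace=False)
        chosen.extend((b, int(i_idx[k]), int(j_idx[k])) for k in members)

    rows = []
    for label, idx in groups.items():
        idx = np.asarray(idx)
        sub = rng.choice(idx, size=n_subsample, replace=False)
        X = data[sub]
        per_bin_d: dict[int, list[float]] = {}
        per_bin_r: dict[int, list[float]] = {}
        for b, i, j in chosen:
            try:
                if phased:
                    h = hap_freqs_from_phased(X[:, i], X[:, j])
                else:
                    h = em_hapfreq(X[:, i], X[:, j])
                _, dprime, r2 = ld_stats(h)
            except ValueError:
                continue  # monomorphic in this subsample
            per_bin_d.setdefault(b, []).append(dprime)
            per_bin_r.setdefault(b, []).append(r2)
        for b in range(len(bins) - 1):
            dvals = per_bin_d.get(b, [])
            rows.append(
                {
                    "group": label,
                    "bin_lo": bins[b],
                    "bin_hi": bins[b + 1],
                    "median_dprime": float(np.median(dvals)) if dvals else np.nan,
                    "median_r2": float(np.median(per_bin_r[b])) if dvals else np.nan,
                    "n_pairs": len(dvals),
                }
            )
    return pd.DataFrame(rows)
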