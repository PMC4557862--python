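"""Synthetic case-control cohorts, reference panels, and trios.

The generator emulates the statistical structure the downstream analysis
assumes, so the whole pipeline is testable without any genotype download:

* two diverged European-like subpopulations (an Ashkenazi-like founder
  population "AJ" with a well-characterised reference panel, and a
  northwest-European-like comparison group "EUNW"), with between-
  population divergence controlled by an Fst-style parameter via
  Balding-Nichols beta draws;
* HLA alleles with population-specific haplotype frequencies — the main
  class II risk allele (DRB1*15:01, carried by ~5 % of AJ vs ~15-20 % of
  EUNW) with its tightly linked DQB1*06:02, and a protective class I
  B*38:01–C*12:03 haplotype planted on one simulated chromosome;
* ~110 weak non-HLA risk SNPs (OR 1.2-1.4) feeding a logistic
  case/control assignment with a target marginal prevalence;
* trios with Mendelian transmission, a tunable fraction with exactly one
  non-AJ parent, optionally ascertained on an affected proband;
* optional haplotype-level LD via founder-pool copying with a per-base
  switch probability, so pairwise r^2 decays with distance.

All randomness derives from one global integer seed through keyed
sub-streams (see ``msgen._rng``), so a fixed seed gives bit-identical
cohorts regardless of stage order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from ._rng import stream
from .famtdt import TrioSet
from .genio import (
    MISSING,
    SAMPLE_COLUMNS,
    STATUS_CASE,
    STATUS_CONTROL,
    GenotypeMatrix,
    make_risk_table,
)

__all__ = [
    "HlaAlleleSpec",
    "SimConfig",
    "SimCohort",
    "default_hla_spec",
    "make_ms_risk_table",
    "draw_subpop_freqs",
    "simulate_genotypes",
    "plant_hla_haplotypes",
    "assign_case_status",
    "simulate_trio_cohort",
    "simulate_cohort",
]

POPULATIONS = ("AJ", "EUNW")


@dataclass(frozen=True)
class HlaAlleleSpec:
    """One classical HLA allele to plant.

    freq: haplotype frequency, either a scalar or a per-population mapping.
    odds_ratio: multiplicative per-copy disease odds ratio.
    haplotype: alleles sharing a tag are placed on the same simulated
        chromosome (e.g. the B*38:01–C*12:03 haplotype) and must declare
        identical frequencies.
    """

    name: str
    freq: float | Mapping[str, float]
    odds_ratio: float = 1.0
    haplotype: str | None = None

    @property
    def locus(self) -> str:
        return self.name.split("*")[0]

    def freq_in(self, population: str) -> float:
        if isinstance(self.freq, Mapping):
            return float(self.freq[population])
        return float(self.freq)


def default_hla_spec() -> list[HlaAlleleSpec]:
    """The study-like HLA configuration.

    Haplotype frequencies q solve 1-(1-q)^2 = target carrier frequency:
    DRB1*15:01 carriers ~5 % in AJ and ~17.5 % in EUNW (the middle of the
    15-20 % range quoted for general Europeans).  DQB1*06:02 rides the
    same haplotype.  The protective class I B*38:01–C*12:03 haplotype is
    planted at an AJ-enriched frequency.
    """
    q_drb_aj = 1 - np.sqrt(1 - 0.05)     # ~0.0253
    q_drb_eu = 1 - np.sqrt(1 - 0.175)    # ~0.0917
    drb_freq = {"AJ": q_drb_aj, "EUNW": q_drb_eu}
    b38_freq = {"AJ": 0.06, "EUNW": 0.02}
    return [
        HlaAlleleSpec("DRB1*15:01", drb_freq, odds_ratio=3.0, haplotype="DR15"),
        HlaAlleleSpec("DQB1*06:02", drb_freq, odds_ratio=1.0, haplotype="DR15"),
        HlaAlleleSpec("A*68:02", {"AJ": 0.05, "EUNW": 0.03}, odds_ratio=2.0),
        HlaAlleleSpec("B*38:01", b38_freq, odds_ratio=0.5, haplotype="B38C12"),
        HlaAlleleSpec("C*12:03", b38_freq, odds_ratio=1.0, haplotype="B38C12"),
    ]


def make_ms_risk_table(
    variant_ids: Sequence[str],
    risk_alleles: Sequence[str],
    seed: int,
    or_range: tuple[float, float] = (1.2, 1.4),
) -> pd.DataFrame:
    """Risk-weight table with ORs drawn uniformly in ``or_range``.

    Defaults emulate the catalogue of ~110 confirmed weak non-HLA risk
    SNPs (per-variant OR 1.2-1.4)."""
    rng = stream(seed, "risk-table")
    ors = rng.uniform(*or_range, size=len(variant_ids))
    return make_risk_table(variant_ids, risk_alleles, ors)


@dataclass
class SimConfig:
    """Generator parameters; defaults are the study-like conditions."""

    n_per_pop: int = 200
    m_snps: int = 5000
    fst: float = 0.01
    ld_pool_size: int | None = None
    recomb_per_bp: float | None = None
    risk_table: pd.DataFrame | None = None
    hla_spec: Sequence[HlaAlleleSpec] = field(default_factory=default_hla_spec)
    baseline_prevalence: float = 0.2
    n_trios: int = 0
    fraction_mixed: float = 1 / 3
    ancestral_range: tuple[float, float] = (0.1, 0.9)
    snp_spacing_bp: int = 2000
    n_reference: int = 50
    n_risk_snps: int = 110
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.fst < 1:
            raise ValueError("fst must lie in [0, 1)")
        if not 0 < self.baseline_prevalence < 1:
            raise ValueError("baseline_prevalence must lie in (0, 1)")
        if not 0 <= self.fraction_mixed <= 1:
            raise ValueError("fraction_mixed must lie in [0, 1]")
        lo, hi = self.ancestral_range
        if not (0 < lo <= hi < 1):
            raise ValueError("ancestral_range must lie within (0, 1)")


@dataclass
class SimCohort:
    genotypes: GenotypeMatrix
    samples: pd.DataFrame
    hla_dosages: pd.DataFrame
    risk_table: pd.DataFrame
    haplotypes: np.ndarray | None = None  # (2n, m) phased alleles
    trios: TrioSet | None = None

    @property
    def is_case(self) -> np.ndarray:
        return (self.samples["status"] == STATUS_CASE).to_numpy()

    @property
    def population(self) -> np.ndarray:
        return self.samples["population"].to_numpy()

    @property
    def reference_flags(self) -> np.ndarray:
        return self.samples["reference_panel"].to_numpy()


def draw_subpop_freqs(
    m: int,
    fst: float,
    ancestral_range: tuple[float, float] = (0.1, 0.9),
    seed: int = 0,
    n_pops: int = 2,
) -> np.ndarray:
    """Balding-Nichols subpopulation allele frequencies.

    Each site has an ancestral frequency p ~ Uniform(ancestral_range);
    each population draws its frequency from Beta(p(1-f)/f, (1-p)(1-f)/f),
    which has mean p and variance f·p(1-p) — the Fst-style divergence
    knob.  fst=0 returns the ancestral draw for every population.

    Returns an array of shape (n_pops, m).
    """
    if not 0 <= fst < 1:
        raise ValueError("fst must lie in [0, 1)")
    lo, hi = ancestral_range
    if not (0 < lo <= hi < 1):
        raise ValueError("ancestral_range must lie within (0, 1)")
    rng = stream(seed, "subpop-freqs")
    p = rng.uniform(lo, hi, size=m)
    if fst == 0:
        return np.tile(p, (n_pops, 1))
    a = p * (1 - fst) / fst
    b = (1 - p) * (1 - fst) / fst
    return rng.beta(a, b, size=(n_pops, m))


def _copy_founders(
    pool: np.ndarray,
    n_haplotypes: int,
    positions: np.ndarray,
    recomb_per_bp: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Li–Stephens-style mosaic copying from a founder haplotype pool."""
    k, m = pool.shape
    gaps = np.diff(positions).astype(float)
    # switch probability between adjacent sites
    p_switch = 1.0 - np.exp(-recomb_per_bp * gaps)
    switch = np.empty((n_haplotypes, m), dtype=bool)
    switch[:, 0] = True
    switch[:, 1:] = rng.random((n_haplotypes, m - 1)) < p_switch
    choices = rng.integers(0, k, size=(n_haplotypes, m))
    # forward-fill the founder chosen at the last switch point
    idx = np.where(switch, np.arange(m), 0)
    last = np.maximum.accumulate(idx, axis=1)
    rows = np.arange(n_haplotypes)[:, None]
    founder = choices[rows, last]
    return pool[founder, np.arange(m)]


def simulate_genotypes(
    freqs: np.ndarray,
    n: int,
    ld: tuple[int, float] | None = None,
    positions: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Simulate dosages (and haplotypes when LD is requested) at given freqs.

    Without ``ld`` each site is an independent Binomial(2, p) draw.  With
    ``ld = (pool_size, recomb_per_bp)``, 2n haplotypes are mosaics of a
    founder pool with per-base switch probability ``recomb_per_bp``, so
    pairwise r^2 decays with inter-site distance; dosages are the sums of
    the two haplotypes.

    Returns (dosages of shape (n, m), haplotypes of shape (2n, m) or None).
    Haplotypes are interleaved: rows 2i and 2i+1 belong to individual i.
    """
    freqs = np.asarray(freqs, dtype=float)
    if freqs.ndim != 1:
        raise ValueError("freqs must be a 1-D per-site frequency vector")
    m = freqs.size
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = stream(seed, "genotypes")
    if ld is None:
        dosages = rng.binomial(2, freqs, size=(n, m)).astype(np.int8)
        return dosages, None
    pool_size, recomb_per_bp = ld
    if positions is None:
        raise ValueError("positions are required for LD simulation")
    positions = np.asarray(positions)
    if positions.size != m or np.any(np.diff(positions) <= 0):
        raise ValueError("positions must be strictly increasing and match freqs")
    pool = (rng.random((pool_size, m)) < freqs).astype(np.int8)
    haps = _copy_founders(pool, 2 * n, positions, recomb_per_bp, rng)
    dosages = (haps[0::2] + haps[1::2]).astype(np.int8)
    return dosages, haps


def _hla_blocks(
    spec: Sequence[HlaAlleleSpec],
) -> list[list[tuple[tuple[str, ...], HlaAlleleSpec]]]:
    """Group the spec into independently drawn haplotype blocks.

    Alleles sharing a haplotype tag form one outcome (they co-occur on a
    chromosome); alleles at the same locus are mutually exclusive and so
    share a block.  Returns, per block, a list of
    (allele-name tuple, representative spec) outcomes.
    """
    # outcome = haplotype group or solo allele
    outcomes: dict[str, list[HlaAlleleSpec]] = {}
    for a in spec:
        key = f"tag:{a.haplotype}" if a.haplotype else f"solo:{a.name}"
        outcomes.setdefault(key, []).append(a)
    for key, members in outcomes.items():
        freqs = {tuple(sorted(m.freq.items())) if isinstance(m.freq, Mapping)
                 else m.freq for m in members}
        if len(freqs) > 1:
            raise ValueError(
                f"alleles on one haplotype must share a frequency: {key}"
            )
    # union loci linked by an outcome into blocks
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        while parent.setdefault(x, x) != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: str, y: str) -> None:
        parent[find(x)] = find(y)

    for members in outcomes.values():
        loci = [m.locus for m in members]
        for other in loci[1:]:
            union(loci[0], other)

    blocks: dict[str, list[tuple[tuple[str, ...], HlaAlleleSpec]]] = {}
    for members in outcomes.values():
        root = find(members[0].locus)
        names = tuple(m.name for m in members)
        blocks.setdefault(root, []).append((names, members[0]))
    return list(blocks.values())


def plant_hla_haplotypes(
    hla_spec: Sequence[HlaAlleleSpec],
    n: int,
    seed: int = 0,
    populations: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Draw per-individual HLA allele dosages (0/1/2 per named allele).

    Each individual carries two chromosomes; within a haplotype block one
    outcome (a declared allele/haplotype, or the residual "other"
    allele) is drawn per chromosome, so alleles declared on one haplotype
    co-occur on the same simulated chromosome.  ``populations`` selects
    the per-population frequency for each individual (defaults to a
    single population when frequencies are scalars).
    """
    if populations is None:
        populations = ["AJ"] * n
    populations = np.asarray(populations)
    if populations.size != n:
        raise ValueError("populations must have length n")
    rng = stream(seed, "hla")

    names = [a.name for a in hla_spec]
    dosage = pd.DataFrame(0, index=range(n), columns=names, dtype=np.int8)

    for block in _hla_blocks(hla_spec):
        for pop in np.unique(populations):
            rows = np.where(populations == pop)[0]
            probs = np.array([out[1].freq_in(pop) for out in block])
            if np.any(probs < 0) or probs.sum() > 1 + 1e-12:
                raise ValueError(
                    f"haplotype frequencies in population {pop!r} exceed 1"
                )
            full = np.append(probs, max(0.0, 1.0 - probs.sum()))
            draws = rng.choice(len(full), size=(rows.size, 2), p=full / full.sum())
            for out_idx, (allele_names, _) in enumerate(block):
                copies = (draws == out_idx).sum(axis=1).astype(np.int8)
                for name in allele_names:
                    dosage.loc[rows, name] = copies
    return dosage


def _linear_risk(
    genotypes: GenotypeMatrix | None,
    hla_dosages: pd.DataFrame | None,
    risk_table: pd.DataFrame | None,
    hla_spec: Sequence[HlaAlleleSpec] = (),
) -> np.ndarray:
    """Log-odds contribution sum(w_i * d_i) over SNP and HLA risk terms."""
    parts = []
    if risk_table is not None and genotypes is not None and len(risk_table):
        for _, row in risk_table.iterrows():
            d = genotypes.risk_allele_dosage(row["variant"], row["risk_allele"])
            d = np.where(d == MISSING, 2 * np.clip(d[d != MISSING].mean() / 2, 0, 1)
                         if (d != MISSING).any() else 0.0, d)
            parts.append(row["weight"] * d.astype(float))
    if hla_dosages is not None:
        for a in hla_spec:
            if a.odds_ratio != 1.0 and a.name in hla_dosages.columns:
                parts.append(np.log(a.odds_ratio)
                             * hla_dosages[a.name].to_numpy(dtype=float))
    if not parts:
        n = (genotypes.n_samples if genotypes is not None
             else len(hla_dosages))
        return np.zeros(n)
    return np.sum(parts, axis=0)


def assign_case_status(
    genotypes: GenotypeMatrix | None,
    hla_dosages: pd.DataFrame | None,
    risk_table: pd.DataFrame | None,
    hla_spec: Sequence[HlaAlleleSpec],
    baseline_prevalence: float,
    seed: int = 0,
) -> np.ndarray:
    """Draw case labels under P(case|d) = logistic(alpha + sum w_i d_i).

    The intercept alpha is solved so the cohort's marginal case
    probability equals ``baseline_prevalence``; labels are then drawn
    independently.  Returns a boolean is_case array.
    """
    if not 0 < baseline_prevalence < 1:
        raise ValueError("baseline_prevalence must lie in (0, 1)")
    eta = _linear_risk(genotypes, hla_dosages, risk_table, hla_spec)
    alpha = brentq(
        lambda a: expit(a + eta).mean() - baseline_prevalence, -40.0, 40.0
    )
    rng = stream(seed, "case-status")
    return rng.random(eta.size) < expit(alpha + eta)


def simulate_trio_cohort(
    parent_freqs: Mapping[str, np.ndarray],
    n_trios: int,
    fraction_mixed: float = 0.0,
    risk_weights: np.ndarray | None = None,
    baseline_prevalence: float = 0.2,
    ascertain_cases: bool = False,
    marker_ids: Sequence[str] | None = None,
    seed: int = 0,
) -> TrioSet:
    """Simulate father/mother/proband trios with Mendelian transmission.

    Parents are drawn as phased haplotype pairs from their population's
    allele frequencies (``parent_freqs`` maps population label to a
    per-site frequency vector; the "AJ" entry is mandatory).  A
    ``fraction_mixed`` of trios has exactly one non-AJ ("EUNW") parent.
    Probands inherit one allele per parent per site.  When
    ``ascertain_cases`` is set, trios are rejection-sampled until the
    proband is affected under the logistic risk model given by
    ``risk_weights`` (per-marker log-OR of the counted allele).
    """
    if n_trios < 1:
        raise ValueError("n_trios must be >= 1")
    if "AJ" not in parent_freqs:
        raise ValueError("parent_freqs must include the 'AJ' population")
    if fraction_mixed > 0 and "EUNW" not in parent_freqs:
        raise ValueError("mixed trios require an 'EUNW' parent pool")
    for pop, f in parent_freqs.items():
        if np.asarray(f).size == 0:
            raise ValueError(f"empty parent pool for population {pop!r}")
    m = np.asarray(parent_freqs["AJ"]).size
    if marker_ids is None:
        marker_ids = [f"snp{j:05d}" for j in range(m)]

    rng = stream(seed, "trios")
    n_mixed = int(round(fraction_mixed * n_trios))
    mixed = np.zeros(n_trios, dtype=bool)
    mixed[:n_mixed] = True
    rng.shuffle(mixed)
    # in a mixed trio either parent may be the non-AJ one
    father_is_eunw = mixed & (rng.random(n_trios) < 0.5)
    mother_is_eunw = mixed & ~father_is_eunw

    eta_alpha = None
    if ascertain_cases:
        if risk_weights is None:
            risk_weights = np.zeros(m)
        # intercept from the AJ allele-frequency expectation of the burden
        f_aj = np.asarray(parent_freqs["AJ"], dtype=float)
        mean_eta = float(2 * f_aj @ risk_weights)
        eta_alpha = brentq(
            lambda a: expit(a + mean_eta) - baseline_prevalence, -40.0, 40.0
        )

    def draw_block(count: int, f_pop: np.ndarray) -> np.ndarray:
        return (rng.random((count, 2, m)) < f_pop).astype(np.int8)

    fathers = np.empty((n_trios, 2, m), dtype=np.int8)
    mothers = np.empty((n_trios, 2, m), dtype=np.int8)
    for pop, sel_f, sel_m in (
        ("AJ", ~father_is_eunw, ~mother_is_eunw),
        ("EUNW", father_is_eunw, mother_is_eunw),
    ):
        if pop not in parent_freqs:
            continue
        f_pop = np.asarray(parent_freqs[pop], dtype=float)
        if sel_f.any():
            fathers[sel_f] = draw_block(int(sel_f.sum()), f_pop)
        if sel_m.any():
            mothers[sel_m] = draw_block(int(sel_m.sum()), f_pop)

    def transmit(count: int, fa: np.ndarray, mo: np.ndarray) -> np.ndarray:
        pick_f = rng.integers(0, 2, size=(count, m))
        pick_m = rng.integers(0, 2, size=(count, m))
        rows = np.arange(count)[:, None]
        cols = np.arange(m)[None, :]
        return (fa[rows, pick_f, cols] + mo[rows, pick_m, cols]).astype(np.int8)

    probands = transmit(n_trios, fathers, mothers)
    if ascertain_cases:
        pending = np.arange(n_trios)
        for _ in range(2000):
            eta = probands[pending] @ risk_weights
            p_case = expit(eta_alpha + eta)
            affected = rng.random(pending.size) < p_case
            pending = pending[~affected]
            if pending.size == 0:
                break
            probands[pending] = transmit(
                pending.size, fathers[pending], mothers[pending]
            )
        else:
            raise RuntimeError("proband ascertainment did not converge")

    meta = pd.DataFrame(
        {
            "father_population": np.where(father_is_eunw, "EUNW", "AJ"),
            "mother_population": np.where(mother_is_eunw, "EUNW", "AJ"),
        }
    )
    meta["aj_trio"] = (meta["father_population"] == "AJ") | (
        meta["mother_population"] == "AJ"
    )
    return TrioSet(
        fathers.sum(axis=1),
        mothers.sum(axis=1),
        probands,
        list(marker_ids),
        meta,
    )


def _variant_table(m: int, spacing: int) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [f"snp{j:05d}" for j in range(m)],
            "chrom": "1",
            "pos": np.arange(1, m + 1) * spacing,
            "allele1": "A",
            "allele2": "G",
        }
    )


def simulate_cohort(config: SimConfig) -> SimCohort:
    """Generate the full study-like cohort from one config.

    Produces n_per_pop individuals per population (AJ first), genotypes
    over m_snps (with haplotype-level LD when configured), HLA dosages,
    a risk-weight table (defaulting to the 110-SNP OR 1.2-1.4 catalogue
    on the first risk SNPs), case/control labels at the configured
    prevalence, a flagged AJ reference panel of controls, and optionally
    trios ascertained on affected AJ probands.
    """
    cfg = config
    freqs = draw_subpop_freqs(
        cfg.m_snps, cfg.fst, cfg.ancestral_range, cfg.seed
    )
    variants = _variant_table(cfg.m_snps, cfg.snp_spacing_bp)
    positions = variants["pos"].to_numpy()
    ld = (
        (cfg.ld_pool_size, cfg.recomb_per_bp)
        if cfg.ld_pool_size is not None and cfg.recomb_per_bp is not None
        else None
    )

    dosage_blocks, hap_blocks = [], []
    for p, pop in enumerate(POPULATIONS):
        d, h = simulate_genotypes(
            freqs[p], cfg.n_per_pop, ld=ld, positions=positions,
            seed=cfg.seed + p,
        )
        dosage_blocks.append(d)
        if h is not None:
            hap_blocks.append(h)
    dosages = np.vstack(dosage_blocks)
    haplotypes = np.vstack(hap_blocks) if hap_blocks else None

    n_total = 2 * cfg.n_per_pop
    sample_ids = [f"S{i:05d}" for i in range(n_total)]
    population = np.repeat(POPULATIONS, cfg.n_per_pop)
    G = GenotypeMatrix(dosages, variants, sample_ids)

    hla = plant_hla_haplotypes(
        cfg.hla_spec, n_total, seed=cfg.seed, populations=population
    )
    hla.index = pd.Index(sample_ids, name="sample_id")

    risk_table = cfg.risk_table
    if risk_table is None and cfg.n_risk_snps > 0:
        ids = variants["id"].iloc[: cfg.n_risk_snps]
        risk_table = make_ms_risk_table(ids, ["A"] * len(ids), cfg.seed)

    is_case = assign_case_status(
        G, hla, risk_table, cfg.hla_spec, cfg.baseline_prevalence, cfg.seed
    )

    # reference panel: well-characterised AJ controls
    ref = np.zeros(n_total, dtype=bool)
    aj_controls = np.where((population == "AJ") & ~is_case)[0]
    ref[aj_controls[: cfg.n_reference]] = True

    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "family_id": sample_ids,
            "father_id": "0",
            "mother_id": "0",
            "sex": stream(cfg.seed, "sex").integers(1, 3, size=n_total),
            "age": np.round(
                stream(cfg.seed, "age").normal(40, 12, size=n_total), 1
            ),
            "status": np.where(is_case, STATUS_CASE, STATUS_CONTROL),
            "cohort": "sim",
            "population": population,
            "reference_panel": ref,
        }
    )[SAMPLE_COLUMNS]

    trios = None
    if cfg.n_trios > 0:
        weights = np.zeros(cfg.m_snps)
        if risk_table is not None:
            idx = variants.set_index("id").index.get_indexer(risk_table["variant"])
            weights[idx] = risk_table["weight"].to_numpy()
        trios = simulate_trio_cohort(
            {"AJ": freqs[0], "EUNW": freqs[1]},
            cfg.n_trios,
            fraction_mixed=cfg.fraction_mixed,
            risk_weights=weights,
            baseline_prevalence=cfg.baseline_prevalence,
            ascertain_cases=risk_table is not None,
            marker_ids=list(variants["id"]),
            seed=cfg.seed,
        )

    return SimCohort(G, samples, hla, risk_table, haplotypes, trios)
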