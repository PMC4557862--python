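"""Readers and writers for the text formats the pipeline touches.

Genotypes travel as PLINK-style text PED/MAP; samples, HLA-allele dosages,
risk weights, and result records travel as TSV.  All readers reject
malformed input with located errors and every writer/reader pair is a
lossless round trip.

Dosage coding: each variant is re-coded as 0, 1, or 2 copies of its minor
allele (determined per dataset at load, ties broken toward ``allele1``,
the first allele seen in file order).  Missing genotypes use the sentinel
``MISSING``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING: int = -1

VALID_ALLELES = set("ACGT12")

VARIANT_COLUMNS = ["id", "chrom", "pos", "allele1", "allele2"]

SAMPLE_COLUMNS = [
    "sample_id",
    "family_id",
    "father_id",
    "mother_id",
    "sex",
    "age",
    "status",
    "cohort",
    "population",
    "reference_panel",
]

# PED phenotype column: 1=control, 2=case, 0/-9=missing.
STATUS_CONTROL, STATUS_CASE, STATUS_MISSING = 1, 2, 0


class ParseError(ValueError):
    """Malformed input file; message carries the file and line number."""


class SchemaError(ValueError):
    """A table is missing a mandatory column or violates a domain bound."""


@dataclass
class GenotypeMatrix:
    """Individuals x variants minor-allele dosage matrix with metadata.

    dosages: int8 array of shape (n_samples, n_variants); values in
        {0, 1, 2, MISSING}.
    variants: DataFrame with columns id, chrom, pos, allele1, allele2;
        ``allele1`` is the counted (minor) allele.
    sample_ids: unique ordered identifiers, one per row.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x variants)")
        n, m = self.dosages.shape
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match dosage rows")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample ids must be unique")
        if len(self.variants) != m:
            raise ValueError("variant table length does not match dosage columns")
        missing_cols = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing_cols:
            raise SchemaError(f"variant table missing columns: {missing_cols}")
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosages must be 0, 1, 2 or the missing sentinel")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def take_variants(self, index: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            self.dosages[:, index],
            self.variants.iloc[index].reset_index(drop=True),
            list(self.sample_ids),
        )

    def take_samples(self, index: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            self.dosages[index],
            self.variants.copy(),
            [self.sample_ids[i] for i in index],
        )

    def allele_frequency(self) -> np.ndarray:
        """Per-variant frequency of the counted allele among non-missing calls."""
        d = self.dosages.astype(float)
        d[self.dosages == MISSING] = np.nan
        with np.errstate(invalid="ignore"):
            return np.nanmean(d, axis=0) / 2.0

    def missing_rate(self) -> np.ndarray:
        return (self.dosages == MISSING).mean(axis=0)

    def risk_allele_dosage(self, variant_id: str, risk_allele: str) -> np.ndarray:
        """Dosage of ``risk_allele`` (0/1/2, MISSING preserved) for one variant."""
        idx = self.variants.index[self.variants["id"] == variant_id]
        if len(idx) == 0:
            raise KeyError(f"variant {variant_id!r} not in genotype matrix")
        j = int(idx[0])
        row = self.variants.iloc[j]
        d = self.dosages[:, j].astype(np.int8)
        if risk_allele == row["allele1"]:
            out = d.copy()
        elif risk_allele == row["allele2"]:
            out = np.where(d == MISSING, MISSING, 2 - d).astype(np.int8)
        else:
            raise KeyError(
                f"risk allele {risk_allele!r} not among alleles of {variant_id!r}"
            )
        return out


def _parse_map(map_path: Path) -> pd.DataFrame:
    rows = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) not in (3, 4):
                raise ParseError(f"{map_path}:{lineno}: expected 3 or 4 MAP columns")
            chrom, vid = parts[0], parts[1]
            pos = int(parts[-1])
            if pos <= 0:
                raise ParseError(f"{map_path}:{lineno}: position must be positive")
            rows.append((vid, chrom, pos))
    df = pd.DataFrame(rows, columns=["id", "chrom", "pos"])
    if df.groupby("chrom")["id"].apply(lambda s: s.duplicated().any()).any():
        raise ParseError(f"{map_path}: duplicate variant ids within a chromosome")
    return df


def read_ped_map(ped_path: str | Path, map_path: str | Path) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Read a text PED/MAP pair into a GenotypeMatrix and a sample table.

    Alleles are recoded to minor-allele dosage per variant ("0 0" is
    missing).  The returned sample table carries the six leading PED
    columns under the standard names.
    """
    ped_path, map_path = Path(ped_path), Path(map_path)
    variants = _parse_map(map_path)
    m = len(variants)

    sample_rows = []
    allele_pairs: list[np.ndarray] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise ParseError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * m} fields, got {len(parts)}"
                )
            fam, iid, pat, mat, sex, pheno = parts[:6]
            alleles = parts[6:]
            for a in alleles:
                if a not in VALID_ALLELES and a != "0":
                    raise ParseError(
                        f"{ped_path}:{lineno}: invalid allele {a!r}"
                    )
            sample_rows.append((iid, fam, pat, mat, int(sex), int(pheno)))
            allele_pairs.append(np.array(alleles, dtype="U1").reshape(m, 2))

    if not sample_rows:
        raise ParseError(f"{ped_path}: no samples")
    n = len(sample_rows)
    A = np.stack(allele_pairs)  # (n, m, 2)

    ids = [r[0] for r in sample_rows]
    if len(set(ids)) != n:
        raise ParseError(f"{ped_path}: duplicate sample ids")

    dosages = np.full((n, m), MISSING, dtype=np.int8)
    allele1 = np.empty(m, dtype="U1")
    allele2 = np.empty(m, dtype="U1")
    for j in range(m):
        col = A[:, j, :]
        present = col != "0"
        # "0 0" is missing; a half-called genotype is rejected
        half = present[:, 0] != present[:, 1]
        if half.any():
            raise ParseError(
                f"{ped_path}: half-missing genotype at variant "
                f"{variants['id'].iloc[j]!r}"
            )
        obs = col[present]
        uniq, counts = np.unique(obs, return_counts=True)
        if len(uniq) > 2:
            raise ParseError(
                f"{ped_path}: variant {variants['id'].iloc[j]!r} has >2 alleles"
            )
        if len(uniq) == 0:
            allele1[j], allele2[j] = "0", "0"
            continue
        # first allele seen in file order defines allele1; ties toward it
        first_seen = obs.flat[0]
        if len(uniq) == 1:
            a1, a2 = uniq[0], "0"
            minor = a1  # degenerate: all dosage equals count of sole allele
        else:
            c = dict(zip(uniq, counts))
            other = uniq[0] if uniq[1] == first_seen else uniq[1]
            if c[first_seen] <= c[other]:
                minor, major = first_seen, other
            else:
                minor, major = other, first_seen
            a1, a2 = minor, major
        allele1[j], allele2[j] = a1, a2
        cnt = (col == a1).sum(axis=1).astype(np.int8)
        dosages[:, j] = np.where(present[:, 0], cnt, MISSING)

    variants = variants.assign(allele1=allele1, allele2=allele2)[VARIANT_COLUMNS]

    samples = pd.DataFrame(
        sample_rows,
        columns=["sample_id", "family_id", "father_id", "mother_id", "sex", "status"],
    )
    samples["age"] = np.nan
    samples["cohort"] = ""
    samples["population"] = ""
    samples["reference_panel"] = False
    samples = samples[SAMPLE_COLUMNS]
    return GenotypeMatrix(dosages, variants, ids), samples


def write_ped_map(
    G: GenotypeMatrix,
    samples: pd.DataFrame,
    ped_path: str | Path,
    map_path: str | Path,
) -> None:
    """Write a GenotypeMatrix back to text PED/MAP (inverse of read_ped_map)."""
    v = G.variants
    with open(map_path, "w") as fh:
        for _, row in v.iterrows():
            fh.write(f"{row['chrom']}\t{row['id']}\t0\t{row['pos']}\n")
    samples = samples.set_index("sample_id")
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(G.sample_ids):
            s = samples.loc[sid]
            fields = [
                str(s["family_id"]) or sid,
                sid,
                str(s["father_id"]),
                str(s["mother_id"]),
                str(int(s["sex"])),
                str(int(s["status"])),
            ]
            for j in range(G.n_variants):
                d = G.dosages[i, j]
                a1, a2 = v["allele1"].iloc[j], v["allele2"].iloc[j]
                if d == MISSING:
                    fields += ["0", "0"]
                elif d == 2:
                    fields += [a1, a1]
                elif d == 1:
                    fields += [a1, a2]
                else:
                    fields += [a2, a2]
            fh.write(" ".join(fields) + "\n")


@dataclass(frozen=True)
class ColumnSpec:
    name: str
    dtype: type
    required: bool = True


def read_table(path: str | Path, schema: Sequence[ColumnSpec]) -> pd.DataFrame:
    """Read a TSV against a typed schema; missing markers normalised to NaN."""
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=["", "NA", "-9", "."])
    for spec in schema:
        if spec.name not in df.columns:
            if spec.required:
                raise SchemaError(f"{path}: missing mandatory column {spec.name!r}")
            continue
        if spec.dtype is not str:
            df[spec.name] = df[spec.name].astype(float)
            if spec.dtype is int:
                df[spec.name] = df[spec.name].astype("Int64")
    return df


RISK_TABLE_SCHEMA = [
    ColumnSpec("variant", str),
    ColumnSpec("risk_allele", str),
    ColumnSpec("odds_ratio", float),
]


def read_risk_table(path: str | Path) -> pd.DataFrame:
    """Risk-weight table: variant, risk allele, published OR; adds w = ln(OR)."""
    df = read_table(path, RISK_TABLE_SCHEMA)
    return make_risk_table(df["variant"], df["risk_allele"], df["odds_ratio"])


def make_risk_table(
    variants: Iterable[str], risk_alleles: Iterable[str], odds_ratios: Iterable[float]
) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "variant": list(variants),
            "risk_allele": list(risk_alleles),
            "odds_ratio": np.asarray(list(odds_ratios), dtype=float),
        }
    )
    if (df["odds_ratio"] <= 0).any() or not np.isfinite(df["odds_ratio"]).all():
        bad = df.loc[(df["odds_ratio"] <= 0) | ~np.isfinite(df["odds_ratio"]), "variant"]
        raise SchemaError(f"odds ratios must be positive and finite: {list(bad)}")
    df["weight"] = np.log(df["odds_ratio"])
    return df


def write_risk_table(df: pd.DataFrame, path: str | Path) -> None:
    df[["variant", "risk_allele", "odds_ratio"]].to_csv(path, sep="\t", index=False)


def read_hla_dosages(path: str | Path) -> pd.DataFrame:
    """HLA allele-dosage table: sample_id index, one 0/1/2 column per allele."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise SchemaError(f"{path}: missing mandatory column 'sample_id'")
    return df.set_index("sample_id")


def write_hla_dosages(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=True, index_label="sample_id")


def read_samples(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={c: str for c in
                     ("sample_id", "family_id", "father_id", "mother_id",
                      "cohort", "population")})
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing sample columns {missing}")
    df["reference_panel"] = df["reference_panel"].astype(bool)
    return df[SAMPLE_COLUMNS]


def write_samples(df: pd.DataFrame, path: str | Path) -> None:
    df[SAMPLE_COLUMNS].to_csv(path, sep="\t", index=False)


def write_results(records: Iterable, path: str | Path) -> None:
    """Write a stream of result records (dataclasses, dicts, or a DataFrame)
    to TSV with a deterministic column order.

    An empty stream still produces a header when the schema is known
    (DataFrame input); dataclass streams take their column order from the
    field declaration order of the first record.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        records = list(records)
        if records and dataclasses.is_dataclass(records[0]):
            cols = [f.name for f in dataclasses.fields(records[0])]
            df = pd.DataFrame([dataclasses.asdict(r) for r in records], columns=cols)
        else:
            df = pd.DataFrame(records)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
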