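import numpy as np
import pandas as pd
import pytest

from msgen.genio import GenotypeMatrix


def make_matrix(dosages, sample_prefix="S", allele1="A", allele2="G",
                spacing=1000) -> GenotypeMatrix:
    """GenotypeMatrix from a raw dosage array with synthetic metadata."""
    d = np.asarray(dosages, dtype=np.int8)
    n, m = d.shape
    variants = pd.DataFrame(
        {
            "id": [f"snp{j:05d}" for j in range(m)],
            "chrom": "1",
            "pos": np.arange(1, m + 1) * spacing,
            "allele1": allele1,
            "allele2": allele2,
        }
    )
    return GenotypeMatrix(d, variants, [f"{sample_prefix}{i:05d}" for i in range(n)])


@pytest.fixture
def two_pop_cohort():
    """Small two-population cohort shared by ancestry-level tests."""
    from msgen.simcohort import SimConfig, simulate_cohort

    return simulate_cohort(
        SimConfig(n_per_pop=60, m_snps=1500, fst=0.05, n_risk_snps=20,
                  n_trios=10, seed=42)
    )
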