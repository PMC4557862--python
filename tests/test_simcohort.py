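import numpy as np
import pandas as pd
import pytest

from msgen import simcohort as sc
from msgen.famtdt import mendelian_consistent
from msgen.lddecay import decay_profile


def hudson_fst(p1, p2, n1, n2):
    """Hudson estimator (ratio of averages) from subpopulation frequencies."""
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num.mean() / den.mean()


class TestSubpopFreqs:
    def test_zero_divergence_limit(self):
        f = sc.draw_subpop_freqs(100, 0.0, seed=1)
        assert np.array_equal(f[0], f[1])

    def test_degenerate_ancestral_range(self):
        f = sc.draw_subpop_freqs(50, 1e-9, ancestral_range=(0.5, 0.5), seed=1)
        assert np.allclose(f, 0.5, atol=1e-3)

    def test_fst_recovered_from_genotypes(self):
        # estimate Fst by the variance-components formula on genotype-based
        # frequency estimates; band covers sampling error over seeds
        ests = []
        for seed in range(5):
            f = sc.draw_subpop_freqs(10000, 0.01, seed=seed)
            n = 200
            d1, _ = sc.simulate_genotypes(f[0], n, seed=seed)
            d2, _ = sc.simulate_genotypes(f[1], n, seed=seed + 100)
            ests.append(hudson_fst(d1.mean(0) / 2, d2.mean(0) / 2, 2 * n, 2 * n))
        assert np.mean(ests) == pytest.approx(0.01, abs=0.003)

    def test_invalid_fst_rejected(self):
        with pytest.raises(ValueError):
            sc.draw_subpop_freqs(10, 1.5)


class TestSimulateGenotypes:
    def test_fixed_allele(self):
        d, _ = sc.simulate_genotypes(np.array([1.0, 0.2]), 50, seed=0)
        assert (d[:, 0] == 2).all()

    def test_determinism(self):
        f = sc.draw_subpop_freqs(200, 0.05, seed=3)[0]
        d1, _ = sc.simulate_genotypes(f, 40, seed=9)
        d2, _ = sc.simulate_genotypes(f, 40, seed=9)
        assert d1.tobytes() == d2.tobytes()

    def test_ld_r2_decays_with_distance(self):
        # founder copying: median r^2 in the 0-10 kb bin exceeds the
        # 200-500 kb bin (computed by direct haplotype counting)
        rng = np.random.default_rng(7)
        pos = np.sort(rng.choice(np.arange(1, 1_000_000), 2000, replace=False))
        freqs = rng.uniform(0.1, 0.9, 2000)
        _, haps = sc.simulate_genotypes(
            freqs, 100, ld=(20, 1e-6), positions=pos, seed=7
        )
        prof = decay_profile(
            haps, pos, {"g": np.arange(200)}, phased=True,
            bins=[0, 10_000, 200_000, 500_000], max_pairs_per_bin=500, seed=7,
        )
        med = prof.set_index("bin_lo")["median_r2"]
        assert med[0] > med[200_000]

    def test_dosage_is_haplotype_sum(self):
        f = np.full(100, 0.4)
        d, h = sc.simulate_genotypes(
            f, 30, ld=(10, 1e-6), positions=np.arange(1, 101) * 1000, seed=2
        )
        assert np.array_equal(d, h[0::2] + h[1::2])

    def test_nonincreasing_positions_rejected(self):
        with pytest.raises(ValueError):
            sc.simulate_genotypes(
                np.array([0.5, 0.5]), 5, ld=(5, 1e-6),
                positions=np.array([10, 10]), seed=0,
            )


class TestPlantHla:
    def test_zero_frequency_allele_absent(self):
        spec = [sc.HlaAlleleSpec("A*01:01", 0.0)]
        d = sc.plant_hla_haplotypes(spec, 200, seed=1)
        assert (d["A*01:01"] == 0).all()

    def test_carrier_frequency_five_percent(self):
        # haplotype frequency q solves 1-(1-q)^2 = 0.05
        q = 1 - np.sqrt(0.95)
        spec = [sc.HlaAlleleSpec("DRB1*15:01", q)]
        d = sc.plant_hla_haplotypes(spec, 10000, seed=2)
        carrier = (d["DRB1*15:01"] >= 1).mean()
        assert carrier == pytest.approx(0.05, abs=0.01)

    def test_linked_alleles_cooccur(self):
        spec = [
            sc.HlaAlleleSpec("B*38:01", 0.1, haplotype="H"),
            sc.HlaAlleleSpec("C*12:03", 0.1, haplotype="H"),
        ]
        d = sc.plant_hla_haplotypes(spec, 3000, seed=3)
        r = np.corrcoef(d["B*38:01"], d["C*12:03"])[0, 1]
        assert r > 0.9

    def test_same_locus_alleles_exclusive(self):
        spec = [
            sc.HlaAlleleSpec("DRB1*15:01", 0.4),
            sc.HlaAlleleSpec("DRB1*13:03", 0.4),
        ]
        d = sc.plant_hla_haplotypes(spec, 2000, seed=4)
        assert (d.sum(axis=1) <= 2).all()

    def test_overfull_locus_rejected(self):
        spec = [
            sc.HlaAlleleSpec("DRB1*15:01", 0.7),
            sc.HlaAlleleSpec("DRB1*13:03", 0.7),
        ]
        with pytest.raises(ValueError, match="exceed"):
            sc.plant_hla_haplotypes(spec, 10, seed=0)


class TestCaseStatus:
    def test_null_model_hits_baseline_prevalence(self):
        from conftest import make_matrix

        rng = np.random.default_rng(5)
        G = make_matrix(rng.binomial(2, 0.3, size=(10000, 5)))
        table = sc.make_risk_table(
            list(G.variants["id"]), ["A"] * 5, [1.0] * 5
        )
        is_case = sc.assign_case_status(G, None, table, (), 0.2, seed=5)
        se = np.sqrt(0.2 * 0.8 / 10000)
        assert is_case.mean() == pytest.approx(0.2, abs=4 * se)

    def test_single_variant_or_two_doubles_odds_per_copy(self):
        from conftest import make_matrix

        rng = np.random.default_rng(6)
        G = make_matrix(rng.binomial(2, 0.5, size=(20000, 1)))
        table = sc.make_risk_table(["snp00000"], ["A"], [2.0])
        is_case = sc.assign_case_status(G, None, table, (), 0.3, seed=6)
        d = G.dosages[:, 0]

        def odds(sel):
            p = is_case[sel].mean()
            return p / (1 - p)

        assert odds(d == 2) / odds(d == 0) == pytest.approx(4.0, rel=0.15)

    def test_balanced_null_is_fair_coin(self):
        from conftest import make_matrix

        G = make_matrix(np.zeros((5000, 1), dtype=np.int8))
        is_case = sc.assign_case_status(G, None, None, (), 0.5, seed=7)
        assert is_case.mean() == pytest.approx(0.5, abs=0.02)

    def test_unknown_risk_variant_rejected(self):
        from conftest import make_matrix

        G = make_matrix(np.zeros((10, 2), dtype=np.int8))
        table = sc.make_risk_table(["nope"], ["A"], [1.5])
        with pytest.raises(KeyError):
            sc.assign_case_status(G, None, table, (), 0.2, seed=0)


class TestTrios:
    def test_all_aj_when_not_mixed(self):
        f = sc.draw_subpop_freqs(100, 0.02, seed=8)
        trios = sc.simulate_trio_cohort(
            {"AJ": f[0], "EUNW": f[1]}, 50, fraction_mixed=0.0, seed=8
        )
        assert (trios.meta["father_population"] == "AJ").all()
        assert (trios.meta["mother_population"] == "AJ").all()

    def test_mixed_trios_have_exactly_one_non_aj_parent(self):
        f = sc.draw_subpop_freqs(100, 0.02, seed=9)
        trios = sc.simulate_trio_cohort(
            {"AJ": f[0], "EUNW": f[1]}, 60, fraction_mixed=0.5, seed=9
        )
        n_eunw = ((trios.meta["father_population"] == "EUNW").astype(int)
                  + (trios.meta["mother_population"] == "EUNW").astype(int))
        assert set(n_eunw) <= {0, 1}
        assert (n_eunw == 1).sum() == 30
        assert trios.meta["aj_trio"].all()

    def test_mendelian_consistency_by_construction(self):
        f = sc.draw_subpop_freqs(300, 0.02, seed=10)
        trios = sc.simulate_trio_cohort(
            {"AJ": f[0]}, 100, risk_weights=np.full(300, 0.1),
            ascertain_cases=True, seed=10,
        )
        ok = mendelian_consistent(trios.fathers, trios.mothers, trios.probands)
        assert ok.all()

    def test_empty_parent_pool_rejected(self):
        with pytest.raises(ValueError, match="empty parent pool"):
            sc.simulate_trio_cohort({"AJ": np.array([])}, 5)


class TestFullCohort:
    def test_fixed_seed_bit_identical(self):
        cfg = sc.SimConfig(n_per_pop=40, m_snps=300, n_risk_snps=10,
                           n_trios=8, seed=11)
        a = sc.simulate_cohort(cfg)
        b = sc.simulate_cohort(cfg)
        assert a.genotypes.dosages.tobytes() == b.genotypes.dosages.tobytes()
        assert a.samples.equals(b.samples)
        assert a.hla_dosages.equals(b.hla_dosages)
        assert a.trios.probands.tobytes() == b.trios.probands.tobytes()

    def test_empirical_frequencies_converge(self):
        f = sc.draw_subpop_freqs(500, 0.01, seed=12)[0]
        d, _ = sc.simulate_genotypes(f, 10000, seed=12)
        emp = d.mean(axis=0) / 2
        se = np.sqrt(f * (1 - f) / (2 * 10000))
        # standardised deviations should look like N(0,1): none extreme
        z = (emp - f) / se
        assert np.abs(z).max() < 5
        assert np.abs(z).mean() < 1.2

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            sc.SimConfig(fst=1.2)
        with pytest.raises(ValueError):
            sc.SimConfig(baseline_prevalence=0.0)
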