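import numpy as np
import pandas as pd
import pytest
from scipy import stats

from landgen import genotype as gt
from landgen import synthetic as syn

from conftest import toy_genotypes


def _write_toy_vcf(path, records, samples=("s1", "s2")):
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "##contig=<ID=1>",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    lines += records
    path.write_text("\n".join(lines) + "\n")


class TestReadVcf:
    def test_het_and_missing_codes(self, tmp_path):
        p = tmp_path / "t.vcf"
        _write_toy_vcf(p, [
            "1\t100\t.\tA\tG\t45\tPASS\t.\tGT\t0/1\t1/1",
            "1\t200\t.\tA\tG\t45\tPASS\t.\tGT\t./.\t0/0",
        ])
        gm = gt.read_vcf(p)
        assert gm.dosage[0, 0] == 1 and gm.dosage[1, 0] == 2
        assert gm.dosage[0, 1] == gt.MISSING and gm.dosage[1, 1] == 0

    def test_multiallelic_dropped_with_count(self, tmp_path):
        p = tmp_path / "t.vcf"
        _write_toy_vcf(p, [
            "1\t100\t.\tA\tG,T\t45\tPASS\t.\tGT\t0/1\t1/2",
            "1\t200\t.\tA\tG\t45\tPASS\t.\tGT\t0/1\t0/0",
        ])
        gm = gt.read_vcf(p)
        assert gm.n_loci == 1
        assert gm.attrition["multiallelic_dropped"] == 1

    def test_half_call_becomes_missing(self, tmp_path):
        p = tmp_path / "t.vcf"
        _write_toy_vcf(p, ["1\t100\t.\tA\tG\t45\tPASS\t.\tGT\t./1\t0/0"])
        gm = gt.read_vcf(p)
        assert gm.dosage[0, 0] == gt.MISSING
        assert gm.attrition["half_calls"] == 1

    def test_empty_vcf_fails(self, tmp_path):
        p = tmp_path / "t.vcf"
        _write_toy_vcf(p, [])
        with pytest.raises(ValueError, match="zero biallelic"):
            gt.read_vcf(p)


class TestFilterSnps:
    def test_three_thresholds_applied(self):
        # locus 0: QUAL 20 (fails); locus 1: MAF 0 (fails);
        # locus 2: call rate 0.6 (fails); loci 3-4 pass
        dosage = np.array([
            [1, 0, 1, 1, 2],
            [1, 0, gt.MISSING, 0, 1],
            [0, 0, gt.MISSING, 1, 0],
            [1, 0, 1, 0, 1],
            [0, 0, gt.MISSING, 1, 2],
        ])
        gm = toy_genotypes(dosage, quals=[20, 50, 50, 50, 50])
        out = gt.filter_snps(gm, min_qual=30, min_maf=0.01, min_call_rate=0.7)
        assert out.n_loci == 2
        assert list(out.loci["pos"]) == [4, 5]
        assert out.attrition["fail_qual"] == 1
        assert out.attrition["fail_maf"] == 1
        assert out.attrition["fail_call_rate"] == 1

    def test_monomorphic_removed_by_maf(self):
        gm = toy_genotypes(np.zeros((4, 1)))
        with pytest.raises(ValueError, match="all loci removed"):
            gt.filter_snps(gm)

    def test_zero_thresholds_identity(self):
        rng = np.random.default_rng(0)
        gm = toy_genotypes(rng.integers(0, 3, (6, 20)),
                           quals=rng.uniform(10, 60, 20))
        out = gt.filter_snps(gm, min_qual=0, min_maf=0, min_call_rate=0)
        assert out.n_loci == 20


class TestDiversity:
    def test_monomorphic_population_flags_fis(self):
        gm = toy_genotypes(np.zeros((4, 3)))
        div = gt.population_diversity(gm, {f"ind{i}": "A" for i in range(4)})
        assert div.loc["A", "Ho"] == 0 and div.loc["A", "He"] == 0
        assert np.isnan(div.loc["A", "Fis"])

    def test_all_heterozygous_closed_form(self):
        # 10 individuals all het at one locus: Ho=1, He=(20/19)*0.5,
        # Fis = 1 - 1/He
        gm = toy_genotypes(np.ones((10, 1)))
        div = gt.population_diversity(gm, {f"ind{i}": "A" for i in range(10)})
        he = (20 / 19) * 0.5
        assert div.loc["A", "Ho"] == 1.0
        assert div.loc["A", "He"] == pytest.approx(he, abs=1e-12)
        assert div.loc["A", "Fis"] == pytest.approx(1 - 1 / he, abs=1e-12)

    def test_fis_recovers_generative_inbreeding(self):
        cfg = syn.SyntheticConfig(
            n_pops=2, n_ind_per_pop=30, n_loci=5000, grid_shape=(25, 25),
            inbreeding_f=0.3, missing_rate=0.0, seed=9,
        )
        env, suit = syn.generate_env_rasters(cfg)
        pops = syn.place_populations(cfg, suit)
        ev = syn.extract_env_values(pops, env)
        truth = syn.simulate_allele_frequencies(pops, ev, cfg)
        gm = syn.simulate_genotypes(truth, cfg)
        div = gt.population_diversity(gm, syn.population_assignment(truth, cfg))
        assert div["Fis"].mean() == pytest.approx(0.3, abs=0.03)

    def test_bounds_hold_across_seeds(self):
        for seed in range(10):
            cfg = syn.SyntheticConfig(
                n_pops=4, n_ind_per_pop=4, n_loci=150, grid_shape=(20, 20),
                seed=seed,
            )
            env, suit = syn.generate_env_rasters(cfg)
            pops = syn.place_populations(cfg, suit)
            ev = syn.extract_env_values(pops, env)
            truth = syn.simulate_allele_frequencies(pops, ev, cfg)
            gm = syn.simulate_genotypes(truth, cfg)
            div = gt.population_diversity(gm, syn.population_assignment(truth, cfg))
            assert div["Ho"].between(0, 1).all()
            assert div["He"].between(0, 1).all()
            assert div["Fis"].dropna().between(-1, 1).all()


class TestHoHeChi2:
    def test_hardy_weinberg_proportions_give_near_zero(self):
        # 25 AA, 50 Aa, 25 aa: naive HW proportions at p=0.5. The unbiased
        # expectation carries the 2n/(2n-1) small-sample factor, so the
        # statistic is ~0 (0.0025 here), not exactly 0.
        dosage = np.array([[0]] * 25 + [[1]] * 50 + [[2]] * 25)
        gm = toy_genotypes(dosage)
        out = gt.ho_he_chi2(gm, {f"ind{i}": "A" for i in range(100)})
        assert out.loc["A", "chi2"] == pytest.approx(0.0, abs=0.01)
        assert out.loc["A", "p"] > 0.9

    def test_hand_computed_statistic(self):
        # hand case: 100 pooled calls, 20 het observed vs 50 expected:
        # chi2 = (20-50)^2/50 + (80-50)^2/50 = 36
        obs_het, exp_het, n = 20.0, 50.0, 100.0
        chi2 = (obs_het - exp_het) ** 2 / exp_het + (
            (n - obs_het) - (n - exp_het)
        ) ** 2 / (n - exp_het)
        assert chi2 == pytest.approx(36.0)
        # the implementation reproduces the same two-cell formula on data
        # engineered to that configuration is hard to construct exactly;
        # instead verify the formula path on a simple polymorphic sample
        dosage = np.array([[0]] * 6 + [[1]] * 2 + [[2]] * 2)
        gm = toy_genotypes(dosage)
        out = gt.ho_he_chi2(gm, {f"ind{i}": "A" for i in range(10)})
        p_hat = 6 / 20
        e_het = 2 * p_hat * (1 - p_hat) * 10 * (20 / 19)   # unbiased expectation
        expected = (2 - e_het) ** 2 / e_het + (8 - (10 - e_het)) ** 2 / (10 - e_het)
        assert out.loc["A", "chi2"] == pytest.approx(expected, abs=1e-12)

    def test_null_calibration_rejection_rate(self):
        # F=0 data: the pooled test should reject at ~alpha, certainly <=15%
        rejections = 0
        n_rep = 20
        for seed in range(n_rep):
            cfg = syn.SyntheticConfig(
                n_pops=1, n_ind_per_pop=30, n_loci=400, grid_shape=(20, 20),
                inbreeding_f=0.0, missing_rate=0.0, seed=seed,
            )
            env, suit = syn.generate_env_rasters(cfg)
            pops = syn.place_populations(cfg, suit)
            ev = syn.extract_env_values(pops, env)
            truth = syn.simulate_allele_frequencies(pops, ev, cfg)
            gm = syn.simulate_genotypes(truth, cfg)
            out = gt.ho_he_chi2(gm, syn.population_assignment(truth, cfg))
            if out["p"].iloc[0] < 0.05:
                rejections += 1
        assert rejections <= 0.15 * n_rep


def brute_force_wc(dosA, dosB):
    """Independent scalar transcription of the two-population W&C formulas."""
    out = []
    for l in range(dosA.shape[1]):
        ga = [d for d in dosA[:, l] if d >= 0]
        gb = [d for d in dosB[:, l] if d >= 0]
        n1, n2 = len(ga), len(gb)
        if n1 < 1 or n2 < 1 or n1 + n2 <= 2:
            out.append((np.nan, np.nan, np.nan, False))
            continue
        p1 = sum(ga) / (2 * n1)
        p2 = sum(gb) / (2 * n2)
        h1 = sum(1 for d in ga if d == 1) / n1
        h2 = sum(1 for d in gb if d == 1) / n2
        r = 2
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2
            - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        out.append((a, b, c, True))
    return out


class TestWcFst:
    def _pair(self, dosA, dosB):
        dosage = np.vstack([dosA, dosB]).astype(np.int8)
        gm = toy_genotypes(dosage)
        assign = {f"ind{i}": ("A" if i < len(dosA) else "B")
                  for i in range(len(dosage))}
        return gm, assign

    def test_fixed_difference_theta_one(self):
        gm, assign = self._pair(np.zeros((10, 1)), np.full((10, 1), 2))
        comp = gt.wc_fst_pair(gm, assign, "A", "B")
        assert comp.theta_weighted == pytest.approx(1.0, abs=1e-12)

    def test_symmetric_counts_hand_evaluated(self):
        # both pops: 5 hom-ref, 0 het, 5 hom-alt
        block = np.array([[0]] * 5 + [[2]] * 5)
        gm, assign = self._pair(block, block)
        comp = gt.wc_fst_pair(gm, assign, "A", "B")
        # hand evaluation: n1=n2=10, p=0.5 both, h=0 => s2=0, pbar=0.5
        # a = -(0.25 - 0)/9 = -1/36; b = (10/9)*0.25 = 5/18; c = 0
        a, b, c = -1 / 36, 5 / 18, 0.0
        assert comp.a[0] == pytest.approx(a, abs=1e-12)
        assert comp.b[0] == pytest.approx(b, abs=1e-12)
        assert comp.c[0] == pytest.approx(c, abs=1e-12)
        assert comp.theta_weighted == pytest.approx(a / (a + b + c), abs=1e-12)

    def test_components_match_brute_force(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            n1, n2 = rng.integers(2, 9, 2)
            nl = int(rng.integers(1, 6))
            dosA = rng.integers(-1, 3, (n1, nl))
            dosB = rng.integers(-1, 3, (n2, nl))
            a_, b_, c_, valid = gt._wc_components(dosA, dosB)
            oracle = brute_force_wc(dosA, dosB)
            for l, (ao, bo, co, ok) in enumerate(oracle):
                assert valid[l] == ok
                if ok:
                    assert abs(a_[l] - ao) < 1e-12
                    assert abs(b_[l] - bo) < 1e-12
                    assert abs(c_[l] - co) < 1e-12

    def test_theta_invariant_to_pop_swap_and_allele_flip(self):
        rng = np.random.default_rng(3)
        dosA = rng.integers(0, 3, (8, 50))
        dosB = rng.integers(0, 3, (6, 50))
        gm, assign = self._pair(dosA, dosB)
        t_ab = gt.wc_fst_pair(gm, assign, "A", "B").theta_weighted
        t_ba = gt.wc_fst_pair(gm, assign, "B", "A").theta_weighted
        assert t_ab == pytest.approx(t_ba, abs=1e-12)
        gm_flip, assign_f = self._pair(2 - dosA, 2 - dosB)
        t_flip = gt.wc_fst_pair(gm_flip, assign_f, "A", "B").theta_weighted
        assert t_ab == pytest.approx(t_flip, abs=1e-12)

    def test_no_shared_loci_fails(self):
        gm, assign = self._pair(
            np.full((3, 1), gt.MISSING), np.array([[1]] * 3)
        )
        with pytest.raises(ValueError, match="informative"):
            gt.wc_fst_pair(gm, assign, "A", "B")


class TestFstMatrix:
    def test_two_populations_single_value(self, small_dataset):
        gm = small_dataset["genotypes"]
        assign = small_dataset["assignment"]
        two = {k: v for k, v in assign.items() if v in ("P01", "P02")}
        sub_rows = [i for i, ind in enumerate(gm.individuals) if ind in two]
        sub = gt.GenotypeMatrix(
            individuals=[gm.individuals[i] for i in sub_rows],
            loci=gm.loci, dosage=gm.dosage[sub_rows],
        )
        pm = gt.fst_matrix(sub, two)
        comp = gt.wc_fst_pair(sub, two, "P01", "P02")
        assert pm.values[0, 1] == pytest.approx(comp.theta_weighted, abs=1e-15)

    def test_matrix_finite_and_symmetric(self, small_fst):
        assert np.isfinite(small_fst.values).all()
        n = small_fst.n
        assert len(small_fst.condensed()) == n * (n - 1) // 2


class TestDiversityEnvCorrelation:
    def test_t_from_r_closed_form(self):
        # published Pearson rows at df = 19: r = -0.473 -> t = 2.338 and
        # r = 0.604 -> t = 3.300 (to their printed rounding). r = 0.603 gives
        # t = 3.295 by the formula — nowhere near the 10.871 printed for
        # that row, an internal inconsistency of the source table.
        for r, expected_t in [(-0.473, 2.338), (0.604, 3.300)]:
            t = abs(r) * np.sqrt(19 / (1 - r ** 2))
            assert t == pytest.approx(expected_t, abs=5e-3)
        assert 0.603 * np.sqrt(19 / (1 - 0.603 ** 2)) == pytest.approx(3.295, abs=5e-3)

    def test_correlation_table_on_constructed_data(self):
        rng = np.random.default_rng(4)
        n = 21
        x = rng.normal(size=n)
        div = pd.DataFrame({"Ho": 0.3 * x + rng.normal(scale=0.5, size=n)},
                           index=[f"P{i}" for i in range(n)])
        env = pd.DataFrame({"Bio5": x}, index=div.index)
        out = gt.diversity_env_correlation(div, env)
        row = out.iloc[0]
        r_ref, p_ref = stats.pearsonr(env["Bio5"], div["Ho"])
        assert row["r"] == pytest.approx(r_ref, abs=1e-12)
        assert row["p"] == pytest.approx(p_ref, abs=1e-9)
        assert row["t"] == pytest.approx(
            abs(row["r"]) * np.sqrt((n - 2) / (1 - row["r"] ** 2)), abs=1e-12
        )

    def test_collinear_vectors(self):
        idx = [f"P{i}" for i in range(5)]
        div = pd.DataFrame({"Ho": [1.0, 2, 3, 4, 5]}, index=idx)
        env = pd.DataFrame({"V": [2.0, 4, 6, 8, 10]}, index=idx)
        out = gt.diversity_env_correlation(div, env)
        assert out.iloc[0]["r"] == pytest.approx(1.0)
        assert out.iloc[0]["p"] == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_flagged(self):
        idx = [f"P{i}" for i in range(5)]
        div = pd.DataFrame({"Ho": [1.0, 2, 3, 4, 5]}, index=idx)
        env = pd.DataFrame({"V": [1.0] * 5}, index=idx)
        out = gt.diversity_env_correlation(div, env)
        assert out.iloc[0]["flag"] == "degenerate"
        assert np.isnan(out.iloc[0]["r"])
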