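"""QC, PCA, association tests, inflation and meta-analysis."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from grspipe import assoc_qc
from grspipe.errors import ComputationError, ConfigError
from grspipe.geno_io import ASSOC_COLUMNS, MISSING

from conftest import make_dataset


def make_assoc(betas, ses, snps=None, a1="A", a2="G", chrom="1", pos=None):
    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    m = len(betas)
    z = betas / ses
    return pd.DataFrame({
        "snp": snps if snps is not None else [f"rs{j + 1}" for j in range(m)],
        "chrom": chrom, "pos": pos if pos is not None else (np.arange(m) + 1) * 1000,
        "a1": a1, "a2": a2, "beta": betas, "se": ses, "z": z,
        "p": 2 * stats.norm.sf(np.abs(z)), "n": 100.0, "info": np.nan,
        "eaf": 0.3,
    })[ASSOC_COLUMNS]


class TestVariantQC:
    def test_mhc_region_snp_removed(self):
        ds = make_dataset([[0, 1], [1, 2]], chrom="6",
                          pos=[30_000_000, 40_000_000])
        out, report = assoc_qc.variant_qc(
            ds, exclude_regions=[assoc_qc.MHC_EXTENDED_REGION])
        assert list(out.variants["snp"]) == ["rs2"]
        assert report.removed_region == 1

    def test_maf_threshold_is_closed_lower_bound(self):
        # freqs: 1/8 (= threshold, retained) and 0/8 (below, removed)
        ds = make_dataset([[1, 0], [0, 0], [0, 0], [0, 0]])
        out, report = assoc_qc.variant_qc(ds, maf_min=0.125)
        assert list(out.variants["snp"]) == ["rs1"]
        assert report.removed_maf == 1

    def test_overlapping_rules_counted_per_rule(self):
        """10 SNPs: 3 fail MAF, 2 fail INFO (1 overlap) -> 6 retained."""
        dosages = np.ones((4, 10), dtype=np.int8)
        dosages[:, :3] = 0      # SNPs 1-3 monomorphic -> MAF 0
        ds = make_dataset(dosages)
        info = np.array([1, 1, 0.5, 0.6, 1, 1, 1, 1, 1, 1.0])   # 3,4 fail INFO
        out, report = assoc_qc.variant_qc(ds, maf_min=0.05, info_min=0.7,
                                          info=info)
        assert report.removed_maf == 3
        assert report.removed_info == 2
        assert report.n_retained == 6
        assert report.n_input == 10

    def test_idempotent(self):
        ds = make_dataset(np.array([[0, 1, 2], [1, 1, 0], [2, 1, 0],
                                    [0, 0, 0]], dtype=np.int8))
        once, _ = assoc_qc.variant_qc(ds, maf_min=0.2)
        twice, rep = assoc_qc.variant_qc(once, maf_min=0.2)
        assert list(once.variants["snp"]) == list(twice.variants["snp"])
        assert rep.n_input == rep.n_retained


class TestRelatedness:
    def test_duplicate_sample_detected_and_one_removed(self, rng):
        g = rng.binomial(2, 0.3, size=(10, 1500)).astype(np.int8)
        g[1] = g[0]     # duplicate pair
        ds = make_dataset(g)
        kept, pairs = assoc_qc.relatedness_filter(ds, pihat_max=0.125)
        dup = pairs[(pairs["iid_a"] == "S1") & (pairs["iid_b"] == "S2")]
        assert dup["pihat"].iloc[0] > 0.9
        assert "S2" not in set(kept.samples["iid"])
        assert "S1" in set(kept.samples["iid"])

    def test_unrelated_samples_have_near_zero_pihat(self, rng):
        g = rng.binomial(2, rng.uniform(0.1, 0.5, 5000),
                         size=(30, 5000)).astype(np.int8)
        ds = make_dataset(g)
        kept, pairs = assoc_qc.relatedness_filter(ds, pihat_max=0.125)
        assert len(pairs) == 0      # nobody crosses the relatedness threshold
        # full distribution: nulls concentrate near zero
        _, allp = assoc_qc.relatedness_filter(ds, pihat_max=0.0)
        v = np.zeros(30 * 29 // 2)
        v[:len(allp)] = allp["pihat"].to_numpy()
        assert np.quantile(v, 0.9) < 0.05
        assert v.mean() < 0.03

    def test_parent_offspring_pihat_near_half(self, rng):
        p = rng.uniform(0.2, 0.5, 2000)
        m = len(p)
        father = (rng.random((1, m)) < p).astype(np.int8) \
            + (rng.random((1, m)) < p).astype(np.int8)
        mother = (rng.random((1, m)) < p).astype(np.int8) \
            + (rng.random((1, m)) < p).astype(np.int8)
        # child: one allele transmitted from each parent
        pat = np.where(father == 1, rng.random((1, m)) < 0.5, father == 2)
        mat = np.where(mother == 1, rng.random((1, m)) < 0.5, mother == 2)
        child = pat.astype(np.int8) + mat.astype(np.int8)
        others = rng.binomial(2, p, size=(6, m)).astype(np.int8)
        ds = make_dataset(np.vstack([father, child, others]))
        _, pairs = assoc_qc.relatedness_filter(ds, pihat_max=0.3)
        po = pairs[(pairs["iid_a"] == "S1") & (pairs["iid_b"] == "S2")]
        assert po["pihat"].iloc[0] == pytest.approx(0.5, abs=0.08)


class TestPCA:
    def _two_pops(self, rng, fst, n_per=200, m=400):
        p = rng.uniform(0.2, 0.5, m)
        scale = (1 - fst) / fst if fst > 0 else None
        p1 = rng.beta(p * scale, (1 - p) * scale) if fst else p
        p2 = rng.beta(p * scale, (1 - p) * scale) if fst else p
        g = np.vstack([rng.binomial(2, p1, size=(n_per, m)),
                       rng.binomial(2, p2, size=(n_per, m))]).astype(np.int8)
        labels = np.r_[np.zeros(n_per), np.ones(n_per)]
        return make_dataset(g), labels

    def test_pc1_separates_drifted_populations(self, rng):
        ds, labels = self._two_pops(rng, fst=0.1)
        pcs = assoc_qc.compute_pcs(ds, 2)
        r = np.corrcoef(pcs["PC1"], labels)[0, 1]
        assert abs(r) > 0.9

    def test_no_structure_no_separation(self, rng):
        ds, labels = self._two_pops(rng, fst=0.0, n_per=1000, m=300)
        pcs = assoc_qc.compute_pcs(ds, 2)
        for col in pcs:
            assert abs(np.corrcoef(pcs[col], labels)[0, 1]) < 0.1

    def test_duplicate_rows_get_identical_coordinates(self, rng):
        g = rng.binomial(2, 0.4, size=(20, 50)).astype(np.int8)
        g[3] = g[7]
        pcs = assoc_qc.compute_pcs(make_dataset(g), 3)
        np.testing.assert_allclose(pcs.iloc[3], pcs.iloc[7], atol=1e-9)

    def test_k_beyond_rank_rejected(self, rng):
        g = rng.binomial(2, 0.4, size=(5, 50)).astype(np.int8)
        with pytest.raises(ConfigError, match="k must"):
            assoc_qc.compute_pcs(make_dataset(g), 6)


class TestSnpAssociation:
    def test_allelic_chisq_matches_hand_2x2(self):
        """Cases 30/70 vs controls 20/80 alleles: OR 1.714, Pearson chi-sq."""
        # 50 cases: 30 het, 20 ref-hom ; 50 controls: 20 het, 30 ref-hom
        dosage = np.r_[np.repeat([1], 30), np.repeat([0], 20),
                       np.repeat([1], 20), np.repeat([0], 30)][:, None]
        y = np.r_[np.ones(50), np.zeros(50)]
        ds = make_dataset(dosage.astype(np.int8))
        res = assoc_qc.snp_association(ds, y, test="allelic_chisq")
        or_expected = (30 / 70) / (20 / 80)
        assert np.exp(res["beta"][0]) == pytest.approx(or_expected, rel=1e-9)
        chi2, p, _, _ = stats.chi2_contingency(
            [[30, 70], [20, 80]], correction=False)
        assert res["p"][0] == pytest.approx(p, rel=1e-9)

    def test_logistic_equals_allelic_or_on_binary_coding(self):
        """With 0/1 dosages the logistic beta is exactly the table log OR."""
        dosage = np.r_[np.ones(35), np.zeros(25), np.ones(15), np.zeros(45)]
        y = np.r_[np.ones(60), np.zeros(60)]
        ds = make_dataset(dosage[:, None].astype(np.int8))
        res = assoc_qc.snp_association(ds, y)
        ln_or = np.log((35 / 25) / (15 / 45))
        assert res["beta"][0] == pytest.approx(ln_or, abs=1e-3)

    def test_matches_statsmodels_with_covariates_and_missing(self, rng):
        n, m = 400, 12
        g = rng.binomial(2, 0.3, size=(n, m)).astype(np.int8)
        g[rng.random((n, m)) < 0.06] = MISSING
        cov = rng.standard_normal((n, 2))
        logit = -0.3 + 0.4 * cov[:, 0] + 0.5 * np.where(g[:, 0] > 0, g[:, 0], 0)
        y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(float)
        ds = make_dataset(g)
        res = assoc_qc.snp_association(ds, y, covariates=cov)
        for j in range(m):
            ok = g[:, j] != MISSING
            X = sm.add_constant(np.column_stack([cov[ok], g[ok, j]]))
            fit = sm.Logit(y[ok], X).fit(disp=0)
            assert res["beta"][j] == pytest.approx(fit.params[-1], abs=1e-6)
            assert res["se"][j] == pytest.approx(fit.bse[-1], abs=1e-6)

    def test_null_p_values_uniform(self, rng):
        n, m = 600, 1000
        g = rng.binomial(2, rng.uniform(0.1, 0.5, m), size=(n, m)).astype(np.int8)
        y = rng.binomial(1, 0.4, n).astype(float)
        ds = make_dataset(g)
        res = assoc_qc.snp_association(ds, y)
        ks = stats.kstest(res["p"].dropna(), "uniform")
        assert ks.pvalue > 0.01

    def test_monomorphic_flagged_not_tested(self):
        ds = make_dataset(np.array([[2, 1], [2, 0], [2, 1]], dtype=np.int8))
        res = assoc_qc.snp_association(ds, np.array([1.0, 0.0, 1.0]))
        assert res["status"][0] == "monomorphic"
        assert np.isnan(res["beta"][0])


class TestGenomicInflation:
    def test_lambda_definition(self):
        z = np.full(100, np.sqrt(0.4549364))
        assoc = make_assoc(z * 0.1, np.full(100, 0.1))
        lam = assoc_qc.genomic_inflation(assoc).lambda_gc
        assert lam == pytest.approx(1.0, abs=1e-6)

    def test_doubling_z_quadruples_lambda(self, rng):
        z = rng.standard_normal(5000)
        a1 = make_assoc(z * 0.1, np.full(5000, 0.1))
        a2 = make_assoc(2 * z * 0.1, np.full(5000, 0.1))
        l1 = assoc_qc.genomic_inflation(a1).lambda_gc
        l2 = assoc_qc.genomic_inflation(a2).lambda_gc
        assert l2 == pytest.approx(4 * l1, rel=1e-9)

    def test_null_chi_square_draws_give_unit_lambda(self, rng):
        z = rng.standard_normal(100_000)
        assoc = make_assoc(z * 0.1, np.full(100_000, 0.1))
        lam = assoc_qc.genomic_inflation(assoc).lambda_gc
        assert lam == pytest.approx(1.0, abs=0.02)


class TestMetaAnalysis:
    def test_equal_studies_halve_the_variance(self):
        a = make_assoc([0.2], [0.1])
        b = make_assoc([0.2], [0.1])
        out = assoc_qc.meta_fixed_effects(a, b)
        assert out["beta"][0] == pytest.approx(0.2, abs=1e-12)
        assert out["se"][0] == pytest.approx(0.1 / np.sqrt(2), abs=1e-6)

    def test_equal_weights_average_betas(self):
        out = assoc_qc.meta_fixed_effects(make_assoc([0.1], [0.1]),
                                          make_assoc([0.3], [0.1]))
        assert out["beta"][0] == pytest.approx(0.2, abs=1e-12)

    def test_single_table_is_identity(self):
        a = make_assoc([0.1, -0.2], [0.1, 0.2])
        out = assoc_qc.meta_fixed_effects(a)
        np.testing.assert_allclose(out["beta"], a["beta"])
        assert out["single_study"].all()

    def test_swapped_alleles_flip_sign_before_combining(self):
        a = make_assoc([0.2], [0.1], a1="A", a2="G")
        b = make_assoc([-0.2], [0.1], a1="G", a2="A")
        out = assoc_qc.meta_fixed_effects(a, b)
        assert out["beta"][0] == pytest.approx(0.2, abs=1e-12)
        assert out["n_studies"][0] == 2

    def test_strand_ambiguous_mismatch_dropped(self):
        a = make_assoc([0.2], [0.1], a1="A", a2="T")
        b = make_assoc([0.2], [0.1], a1="T", a2="A")
        out = assoc_qc.meta_fixed_effects(a, b)
        # swapped-direct match applies; but a complement-only match would drop:
        c = make_assoc([0.2], [0.1], a1="C", a2="G")
        d = make_assoc([0.2], [0.1], a1="A", a2="G")
        out2 = assoc_qc.meta_fixed_effects(c, d)
        assert out2["n_studies"][0] == 1 and out2["single_study"][0]

    def test_meta_se_below_every_input_se(self, rng):
        a = make_assoc(rng.normal(0, 0.1, 20), rng.uniform(0.05, 0.2, 20))
        b = make_assoc(rng.normal(0, 0.1, 20), rng.uniform(0.05, 0.2, 20))
        out = assoc_qc.meta_fixed_effects(a, b)
        multi = out[out["n_studies"] == 2]
        for i, row in multi.iterrows():
            assert row["se"] < min(a["se"][a["snp"] == row["snp"]].iloc[0],
                                   b["se"][b["snp"] == row["snp"]].iloc[0])
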