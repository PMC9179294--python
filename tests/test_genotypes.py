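"""Genotype tools: PRS computation, Hardy-Weinberg exact test, QC filters
and principal components, each checked against an independent oracle."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import mammotwin as mt
from mammotwin.genotypes import SNP_META_COLUMNS


def make_panel(dosages, effect=None, other=None):
    dosages = np.asarray(dosages, dtype=float)
    m = dosages.shape[1]
    meta = pd.DataFrame({
        "snp_id": [f"s{i}" for i in range(m)],
        "chrom": "1", "pos": np.arange(m) + 1,
        "effect_allele": effect if effect is not None else ["A"] * m,
        "other_allele": other if other is not None else ["G"] * m,
    })
    ids = np.array([f"i{j}" for j in range(dosages.shape[0])])
    return mt.GenotypePanel(dosages, meta, ids)


def make_weights(panel, betas):
    tab = panel.snp_meta[SNP_META_COLUMNS].copy()
    betas = np.asarray(betas, dtype=float)
    for col in ("beta_overall", "beta_erneg", "beta_erpos"):
        tab[col] = betas
    return mt.WeightSet(tab)


class TestPrs:
    def test_zero_dosages_give_zero_score(self):
        panel = make_panel(np.zeros((4, 3)))
        w = make_weights(panel, [0.5, -0.2, 1.0])
        assert (mt.compute_prs(panel, w).to_numpy() == 0).all()

    def test_single_snp_arithmetic(self):
        panel = make_panel([[2.0]])
        w = make_weights(panel, [0.5])
        assert mt.compute_prs(panel, w).iloc[0] == pytest.approx(1.0)

    def test_matches_explicit_loop_oracle(self):
        rng = np.random.default_rng(0)
        dos = rng.integers(0, 3, size=(100, 313)).astype(float)
        panel = make_panel(dos)
        betas = rng.normal(0, 0.1, 313)
        w = make_weights(panel, betas)
        score = mt.compute_prs(panel, w, "overall").to_numpy()
        for j in range(100):
            oracle = 0.0
            for i in range(313):
                oracle += betas[i] * dos[j, i]
            assert score[j] == pytest.approx(oracle, abs=1e-12)

    def test_allele_flip_recovers_same_score(self):
        """A panel counting the other allele (dosage 2-X) yields the same
        PRS once orientations are resolved."""
        rng = np.random.default_rng(1)
        dos = rng.integers(0, 3, size=(20, 5)).astype(float)
        panel = make_panel(dos, effect=["A"] * 5, other=["G"] * 5)
        w = make_weights(panel, rng.normal(size=5))
        flipped = make_panel(2.0 - dos, effect=["G"] * 5, other=["A"] * 5)
        np.testing.assert_allclose(
            mt.compute_prs(panel, w).to_numpy(),
            mt.compute_prs(flipped, w).to_numpy(), atol=1e-12)

    def test_flip_and_negate_shifts_by_constant(self):
        """Swapping every weight's allele orientation and negating the
        weights changes the PRS by exactly -2 * sum(beta)."""
        rng = np.random.default_rng(2)
        dos = rng.integers(0, 3, size=(15, 4)).astype(float)
        panel = make_panel(dos, effect=["A"] * 4, other=["G"] * 4)
        betas = rng.normal(size=4)
        base = mt.compute_prs(panel, make_weights(panel, betas)).to_numpy()
        flipped = make_weights(panel, -betas)
        flipped.table["effect_allele"], flipped.table["other_allele"] = (
            flipped.table["other_allele"].copy(),
            flipped.table["effect_allele"].copy())
        shifted = mt.compute_prs(panel, flipped).to_numpy()
        np.testing.assert_allclose(shifted, base - 2 * betas.sum(),
                                   atol=1e-12)

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(seed=st.integers(0, 2 ** 16))
    def test_linearity_in_weights(self, seed):
        rng = np.random.default_rng(seed)
        dos = rng.integers(0, 3, size=(10, 6)).astype(float)
        panel = make_panel(dos)
        b1, b2 = rng.normal(size=6), rng.normal(size=6)
        s1 = mt.compute_prs(panel, make_weights(panel, b1)).to_numpy()
        s2 = mt.compute_prs(panel, make_weights(panel, b2)).to_numpy()
        s12 = mt.compute_prs(panel, make_weights(panel, b1 + b2)).to_numpy()
        np.testing.assert_allclose(s12, s1 + s2, atol=1e-10)

    def test_missing_dosage_imputed_to_twice_frequency(self):
        dos = np.array([[0.0], [2.0], [np.nan], [2.0]])
        panel = make_panel(dos)
        w = make_weights(panel, [1.0])
        score = mt.compute_prs(panel, w).to_numpy()
        assert score[2] == pytest.approx(2 * (4.0 / 6.0))

    def test_unknown_weight_snp_raises(self):
        panel = make_panel(np.zeros((2, 1)))
        w = make_weights(panel, [1.0])
        w.table.loc[0, "snp_id"] = "rs_missing"
        with pytest.raises(KeyError, match="rs_missing"):
            mt.compute_prs(panel, w)


def hwe_enumeration_oracle(n_hom_ref, n_het, n_hom_alt):
    """Exact-rational enumeration of the conditional heterozygote-count
    distribution given allele counts, independent of the implementation."""
    n = n_hom_ref + n_het + n_hom_alt
    n_a = 2 * n_hom_ref + n_het
    n_b = 2 * n_hom_alt + n_het
    n_minor = min(n_a, n_b)
    if n_minor == 0:
        return 1.0
    weights = {}
    for het in range(n_minor % 2, n_minor + 1, 2):
        hom_minor = (n_minor - het) // 2
        hom_major = n - het - hom_minor
        w = (Fraction(math.factorial(n),
                      math.factorial(hom_major) * math.factorial(het)
                      * math.factorial(hom_minor)) * Fraction(2) ** het)
        weights[het] = w
    total = sum(weights.values())
    p_obs = weights[n_het]
    return float(sum(w for w in weights.values() if w <= p_obs) / total)


class TestHweExact:
    def test_monomorphic_site_is_uninformative(self):
        assert mt.hwe_exact_test(100, 0, 0) == 1.0
        assert mt.hwe_exact_test(0, 0, 7) == 1.0

    def test_balanced_counts_match_enumeration(self):
        assert mt.hwe_exact_test(25, 50, 25) == pytest.approx(
            hwe_enumeration_oracle(25, 50, 25), abs=1e-12)

    def test_extreme_het_excess_fails_qc_threshold(self):
        p = mt.hwe_exact_test(0, 100, 0)
        assert p == pytest.approx(hwe_enumeration_oracle(0, 100, 0), rel=1e-9)
        assert p < 1e-7

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(n_rr=st.integers(0, 60), n_het=st.integers(0, 60),
           n_aa=st.integers(0, 60))
    def test_agrees_with_enumeration_oracle(self, n_rr, n_het, n_aa):
        if n_rr + n_het + n_aa == 0:
            return
        assert mt.hwe_exact_test(n_rr, n_het, n_aa) == pytest.approx(
            hwe_enumeration_oracle(n_rr, n_het, n_aa), abs=1e-12)

    def test_pvalues_uniform_under_null_at_large_n(self):
        """At n = 10,000 the exact test is asymptotically chi-square
        calibrated: null p-values are uniform."""
        rng = np.random.default_rng(10)
        ps = np.empty(2000)
        for i in range(2000):
            g = rng.binomial(1, 0.3, size=(10000, 2)).sum(axis=1)
            ps[i] = mt.hwe_exact_test(int((g == 0).sum()),
                                      int((g == 1).sum()),
                                      int((g == 2).sum()))
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestQcFilter:
    def test_clean_panel_removes_nothing(self):
        cohort = mt.simulate_pedigrees(0, 0, 300, seed=20)
        panel = mt.simulate_genotypes(cohort, 50, seed=20)
        out, report = mt.qc_filter(panel)
        assert out.n_samples == panel.n_samples
        assert out.n_snps == panel.n_snps
        assert report.snps_call_rate == report.snps_hwe == report.snps_maf == 0

    def test_low_call_rate_snp_removed(self):
        # 50 SNPs so the nulled samples keep a 98% call rate and survive
        cohort = mt.simulate_pedigrees(0, 0, 200, seed=21)
        panel = mt.simulate_genotypes(cohort, 50, seed=21)
        dos = panel.dosages.copy()
        dos[:20, 3] = np.nan  # 10% missing at one SNP
        panel = mt.GenotypePanel(dos, panel.snp_meta, panel.sample_ids)
        out, report = mt.qc_filter(panel)
        assert report.samples_call_rate == 0
        assert report.snps_call_rate == 1
        assert "snp00004" not in out.snp_meta.snp_id.tolist()
        assert out.n_snps == 49

    def test_rare_snp_removed_unless_exempt(self):
        rng = np.random.default_rng(22)
        dos = rng.binomial(2, 0.3, size=(400, 3)).astype(float)
        dos[:, 1] = rng.binomial(2, 0.002, size=400)  # MAF << 0.01
        panel = make_panel(dos)
        out, report = mt.qc_filter(panel)
        assert report.snps_maf == 1 and out.n_snps == 2
        out2, report2 = mt.qc_filter(panel, exempt_snp_ids=["s1"])
        assert out2.n_snps == 3 and report2.exempt_snps == ["s1"]

    def test_filter_is_idempotent(self):
        cohort = mt.simulate_pedigrees(0, 0, 300, seed=23)
        panel = mt.simulate_genotypes(cohort, 30, seed=23, missing_rate=0.02)
        once, _ = mt.qc_filter(panel)
        twice, report = mt.qc_filter(once)
        assert twice.n_snps == once.n_snps
        assert twice.n_samples == once.n_samples
        assert report.samples_call_rate == 0 and report.snps_call_rate == 0

    def test_all_samples_removed_raises(self):
        dos = np.full((5, 4), np.nan)
        dos[:, 0] = 1.0  # 25% call rate everywhere
        panel = make_panel(dos)
        with pytest.raises(ValueError, match="all samples removed"):
            mt.qc_filter(panel)


class TestPca:
    def test_identical_columns_put_all_variance_on_pc1(self):
        rng = np.random.default_rng(30)
        col = rng.normal(size=50)
        dos = np.clip(np.tile(col[:, None], (1, 8)), 0, 2)
        panel = make_panel(dos)
        scores = mt.compute_pcs(panel, k=3)
        total = (scores ** 2).sum()
        assert (scores[:, 0] ** 2).sum() / total == pytest.approx(1.0)

    def test_scores_match_dense_eigendecomposition(self):
        cohort = mt.simulate_pedigrees(0, 0, 120, seed=31)
        panel = mt.simulate_genotypes(cohort, 60, seed=31)
        scores = mt.compute_pcs(panel, k=5)
        # independent oracle: eigendecomposition of the covariance of the
        # standardized dosage matrix
        X = panel.dosages - panel.dosages.mean(axis=0)
        X /= X.std(axis=0)
        evals, evecs = np.linalg.eigh(X.T @ X / 1.0)
        order = np.argsort(evals)[::-1]
        oracle = X @ evecs[:, order[:5]]
        for j in range(5):
            dot = scores[:, j] @ oracle[:, j]
            np.testing.assert_allclose(scores[:, j],
                                       np.sign(dot) * oracle[:, j],
                                       atol=1e-8)
        # zero mean, diagonal Gram matrix
        np.testing.assert_allclose(scores.mean(axis=0), 0, atol=1e-10)
        gram = scores.T @ scores
        np.testing.assert_allclose(gram - np.diag(np.diag(gram)), 0,
                                   atol=1e-8)

    def test_pc1_separates_two_subpopulations(self):
        rng = np.random.default_rng(32)
        n, m = 200, 80
        group = np.repeat([0, 1], n // 2)
        maf = np.where(group[:, None] == 0,
                       rng.uniform(0.1, 0.2, size=(1, m)),
                       rng.uniform(0.35, 0.45, size=(1, m)))
        dos = rng.binomial(2, maf).astype(float)
        panel = make_panel(dos)
        scores = mt.compute_pcs(panel, k=2)
        r = np.corrcoef(scores[:, 0], group)[0, 1]
        assert abs(r) > 0.9

    def test_k_too_large_rejected(self):
        panel = make_panel(np.random.default_rng(33).integers(
            0, 3, size=(10, 5)).astype(float))
        with pytest.raises(ValueError):
            mt.compute_pcs(panel, k=5)


class TestIo:
    VCF = (
        "##fileformat=VCFv4.2\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n'
        "##contig=<ID=1>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3\n"
        "1\t100\trs1\tA\tG\t.\tPASS\t.\tGT:DS\t0/0:0.1\t0/1:1.0\t1/1:1.9\n"
        "1\t200\trs2\tC\tT\t.\tPASS\t.\tGT:DS\t0/1:0.9\t./.:.\t0/0:0.0\n"
    )

    def test_vcf_dosage_reader(self, tmp_path):
        cyvcf2 = pytest.importorskip("cyvcf2")  # noqa: F841
        path = tmp_path / "t.vcf"
        path.write_text(self.VCF)
        panel = mt.GenotypePanel.from_vcf(path)
        assert list(panel.sample_ids) == ["S1", "S2", "S3"]
        np.testing.assert_allclose(panel.dosages[:, 0], [0.1, 1.0, 1.9],
                                   atol=1e-6)
        assert np.isnan(panel.dosages[1, 1])  # missing DS
        # ALT is the counted (effect) allele
        assert panel.snp_meta.effect_allele.tolist() == ["G", "T"]
        assert panel.snp_meta.other_allele.tolist() == ["A", "C"]

    def test_plink_raw_reader(self, tmp_path):
        raw = ("FID IID PAT MAT SEX PHENOTYPE rs1_A rs2_C\n"
               "f1 i1 0 0 2 -9 0 2\n"
               "f1 i2 0 0 2 -9 1 NA\n")
        path = tmp_path / "t.raw"
        path.write_text(raw)
        panel = mt.GenotypePanel.from_plink_raw(path)
        assert list(panel.sample_ids) == ["i1", "i2"]
        assert panel.snp_meta.snp_id.tolist() == ["rs1", "rs2"]
        assert panel.snp_meta.effect_allele.tolist() == ["A", "C"]
        np.testing.assert_allclose(panel.dosages[:, 0], [0.0, 1.0])
        assert np.isnan(panel.dosages[1, 1])

    def test_tsv_roundtrip(self, tmp_path):
        cohort = mt.simulate_pedigrees(2, 2, 3, seed=70)
        panel = mt.simulate_genotypes(cohort, 6, seed=70, missing_rate=0.1)
        panel.to_tsv(tmp_path / "d.tsv", tmp_path / "m.tsv")
        back = mt.GenotypePanel.from_tsv(tmp_path / "d.tsv",
                                         tmp_path / "m.tsv")
        np.testing.assert_allclose(back.dosages, panel.dosages,
                                   equal_nan=True)
        assert list(back.sample_ids) == list(panel.sample_ids)


class TestHeterozygosityAndStrand:
    def test_extreme_heterozygosity_sample_removed(self):
        cohort = mt.simulate_pedigrees(0, 0, 300, seed=24)
        panel = mt.simulate_genotypes(cohort, 60, seed=24)
        dos = panel.dosages.copy()
        dos[0, :] = 1.0  # fully heterozygous outlier
        panel = mt.GenotypePanel(dos, panel.snp_meta, panel.sample_ids)
        out, report = mt.qc_filter(panel)
        assert report.samples_heterozygosity == 1
        assert panel.sample_ids[0] not in out.sample_ids

    def test_ambiguous_strand_snp_warned_and_droppable(self, caplog):
        dos = np.array([[0.0, 2.0], [1.0, 1.0]])
        panel = make_panel(dos, effect=["A", "A"], other=["T", "G"])
        w = make_weights(panel, [1.0, 1.0])
        import logging
        with caplog.at_level(logging.WARNING, logger="mammotwin.genotypes"):
            kept = mt.compute_prs(panel, w)
        assert "ambiguous" in caplog.text
        dropped = mt.compute_prs(panel, w, drop_ambiguous=True)
        # with the A/T SNP dropped, only the second SNP contributes
        np.testing.assert_allclose(dropped.to_numpy(), dos[:, 1])
        np.testing.assert_allclose(kept.to_numpy(), dos.sum(axis=1))
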