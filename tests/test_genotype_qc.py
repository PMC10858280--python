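"""Genotype loading, exact HWE test, variant filters, standardization."""

import numpy as np
import pytest
from scipy.special import gammaln

from rarity.genotype_qc import (GenotypeMatrix, hwe_exact_p,
                                impute_and_standardize, load_genotypes,
                                qc_filter)
from rarity.io import write_dosage_tsv

from conftest import make_matrix

VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS0\tS1\tS2
"""


def write_vcf(tmp_path, body):
    path = tmp_path / "toy.vcf"
    path.write_text(VCF_HEADER + body)
    return path


class TestVcfLoading:
    def test_biallelic_dosages_count_alt_alleles(self, tmp_path):
        path = write_vcf(tmp_path,
                         "1\t100\trs1\tA\tC\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n")
        g = load_genotypes(path)
        assert g.samples == ["S0", "S1", "S2"]
        np.testing.assert_array_equal(g.dosages[:, 0], [0, 1, 2])

    def test_multiallelic_collapses_to_presence_absence(self, tmp_path):
        # 1/2 carries two different alts -> one collapsed rare genotype
        path = write_vcf(tmp_path,
                         "1\t100\trs1\tA\tC,G\t.\tPASS\t.\tGT\t1/2\t0/2\t0/0\n")
        g = load_genotypes(path)
        np.testing.assert_array_equal(g.dosages[:, 0], [1, 1, 0])

    def test_missing_genotype_stays_missing_in_raw_state(self, tmp_path):
        path = write_vcf(tmp_path,
                         "1\t100\trs1\tA\tC\t.\tPASS\t.\tGT\t./.\t0/1\t0/0\n")
        g = load_genotypes(path)
        assert np.isnan(g.dosages[0, 0])
        assert g.state == "raw"

    def test_variants_sorted_by_position(self, tmp_path):
        body = ("1\t500\trs2\tA\tC\t.\tPASS\t.\tGT\t0/1\t0/0\t0/0\n"
                "1\t100\trs1\tA\tC\t.\tPASS\t.\tGT\t0/0\t0/1\t0/0\n")
        g = load_genotypes(write_vcf(tmp_path, body))
        assert [v.pos for v in g.variants] == [100, 500]


class TestTsvLoading:
    def test_roundtrip(self, tmp_path, rng):
        g = make_matrix(rng.integers(0, 3, size=(5, 4)).astype(float))
        g.dosages[0, 0] = np.nan
        path = tmp_path / "d.tsv"
        write_dosage_tsv(g, path, meta_path=tmp_path / "d.variants.tsv")
        g2 = load_genotypes(path, format="tsv")
        np.testing.assert_array_equal(g.dosages, g2.dosages)
        assert g2.samples == g.samples
        assert [v.vid for v in g2.variants] == [v.vid for v in g.variants]

    def test_ragged_row_names_offender(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("sample_id\tv0\tv1\nS0\t0\t1\nS1\t2\n")
        with pytest.raises(ValueError, match="line 3"):
            load_genotypes(path, format="tsv")

    def test_unreadable_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_genotypes(tmp_path / "nope.tsv")


def hwe_oracle(het, hom_r, hom_c):
    """Direct enumeration of the exact HWE null via log-factorials."""
    n = het + hom_r + hom_c
    rare = 2 * hom_r + het
    if rare > n:
        rare = 2 * n - rare

    def logprob(h):
        nr = (rare - h) // 2
        nc = n - nr - h
        return (gammaln(n + 1) - gammaln(nr + 1) - gammaln(h + 1)
                - gammaln(nc + 1) + h * np.log(2)
                + gammaln(rare + 1) + gammaln(2 * n - rare + 1)
                - gammaln(2 * n + 1))

    hs = [h for h in range(rare % 2, min(rare, 2 * n - rare) + 1, 2)]
    probs = np.exp([logprob(h) for h in hs])
    probs /= probs.sum()
    obs = probs[hs.index(min(het, min(rare, 2 * n - rare)))]
    return probs[probs <= obs * (1 + 1e-12)].sum()


class TestHweExact:
    @pytest.mark.parametrize("het,hom_r,hom_c", [
        (0, 0, 50), (1, 0, 49), (2, 1, 47), (10, 5, 35),
        (20, 0, 30), (3, 10, 37), (0, 25, 25), (12, 2, 36),
    ])
    def test_matches_enumeration_oracle(self, het, hom_r, hom_c):
        assert hwe_exact_p(het, hom_r, hom_c) == pytest.approx(
            hwe_oracle(het, hom_r, hom_c), rel=1e-9)

    def test_perfect_equilibrium_is_not_significant(self):
        assert hwe_exact_p(50, 25, 25) > 0.05

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_p(-1, 0, 10)


class TestQcFilter:
    def test_monomorphic_removed_and_counted(self):
        g = make_matrix(np.column_stack([
            np.zeros(100),
            np.r_[np.ones(30), np.zeros(70)],
        ]))
        out, report = qc_filter(g, maf_max=0.5)
        assert report.n_monomorphic_removed == 1
        assert out.n_variants == 1

    def test_missingness_over_10_percent_removed(self):
        col = np.r_[np.ones(5), np.zeros(95)]
        col[50:61] = np.nan  # 11% missing at n=100, still polymorphic
        ok = np.r_[np.ones(5), np.zeros(95)]
        g = make_matrix(np.column_stack([col, ok]))
        out, report = qc_filter(g, maf_max=0.5)
        assert report.n_missingness_removed == 1
        assert out.vids() == ["v1"]

    def test_extreme_hwe_departure_removed(self):
        # 25 hom-rare, 0 het, 75 hom-common: exact p far below 5e-6
        col = np.r_[np.full(25, 2.0), np.zeros(75)]
        g = make_matrix(col[:, None])
        out, report = qc_filter(g, maf_max=0.5)
        assert hwe_exact_p(0, 25, 75) < 5e-6
        assert report.n_hwe_removed == 1
        assert out.n_variants == 0

    def test_mac_and_maf_filters(self):
        n = 200
        mac2 = np.r_[np.ones(2), np.zeros(n - 2)]       # MAC 2 (= floor) -> out
        mac3 = np.r_[np.ones(3), np.zeros(n - 3)]       # MAC 3, MAF 0.0075 -> in
        # MAF 0.25 in good HWE (expected het 75): removed by the MAF ceiling
        common = np.r_[np.full(12, 2.0), np.ones(76), np.zeros(n - 88)]
        g = make_matrix(np.column_stack([mac2, mac3, common]))
        out, report = qc_filter(g, maf_max=0.01)
        assert report.n_mac_removed == 1
        assert report.n_maf_removed == 1
        assert out.vids() == ["v1"]
        assert out.variants[0].mac == 3
        assert out.variants[0].maf_local == pytest.approx(3 / 400)

    def test_population_maf_ceiling(self):
        n = 200
        col = np.r_[np.ones(3), np.zeros(n - 3)]
        g = make_matrix(np.column_stack([col, col.copy()]))
        g.variants[0].maf_pops = {"nfe": 0.02}   # above ceiling in one pop
        g.variants[1].maf_pops = {"nfe": 0.001}
        out, report = qc_filter(g, maf_max=0.01, pop_maf_ceiling=True)
        assert out.vids() == ["v1"]
        assert report.n_maf_removed == 1

    def test_report_reconciles_and_filter_is_idempotent(self, rng):
        g = make_matrix(rng.binomial(2, 0.05, size=(120, 30)).astype(float))
        g.dosages[rng.random(size=g.dosages.shape) < 0.05] = np.nan
        out, report = qc_filter(g, maf_max=0.2)
        assert report.removed_total() == report.n_input - report.n_retained
        again, report2 = qc_filter(out, maf_max=0.2)
        assert again.vids() == out.vids()
        assert report2.removed_total() == 0

    def test_rejects_non_raw_state(self):
        g = make_matrix(np.zeros((4, 1)), state="standardized")
        with pytest.raises(ValueError, match="raw"):
            qc_filter(g)


class TestImputeAndStandardize:
    def test_mean_imputation_then_unit_scale(self):
        g = make_matrix(np.array([[0.0], [1.0], [np.nan], [1.0]]))
        out = impute_and_standardize(g)
        # imputed value is the observed mean 2/3; column then standardized
        col = np.array([0, 1, 2 / 3, 1], dtype=float)
        expect = (col - col.mean()) / col.std()
        np.testing.assert_allclose(out.dosages[:, 0], expect, atol=1e-12)
        assert out.state == "standardized"

    def test_columns_have_mean_zero_var_one(self, rng):
        g = make_matrix(rng.binomial(2, 0.1, size=(50, 8)).astype(float))
        out = impute_and_standardize(g)
        np.testing.assert_allclose(out.dosages.mean(axis=0), 0, atol=1e-8)
        np.testing.assert_allclose(out.dosages.var(axis=0), 1, atol=1e-8)

    def test_complete_column_unchanged_by_imputation(self):
        col = np.array([0.0, 0.0, 2.0])
        g = make_matrix(col[:, None])
        out = impute_and_standardize(g)
        np.testing.assert_allclose(out.dosages[:, 0],
                                   (col - col.mean()) / col.std(), atol=1e-12)

    def test_zero_variance_column_names_variant(self):
        g = make_matrix(np.zeros((5, 1)))
        with pytest.raises(ValueError, match="v0"):
            impute_and_standardize(g)
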