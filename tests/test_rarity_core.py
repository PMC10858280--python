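"""Per-block OLS estimates, variance formulas, block-sum heritability."""

import numpy as np
import pytest
from scipy import stats

from rarity.blocks import make_exome_blocks
from rarity.genotype_qc import impute_and_standardize
from rarity.rarity_core import (adjusted_r2, compare_estimates, estimate_h2,
                                fit_block, gene_significance,
                                r2_sampling_variance)
from rarity.simulate import SimConfig, generate_genotypes, simulate_phenotype

from conftest import make_matrix


def standardize(x):
    return (x - x.mean(axis=0)) / x.std(axis=0)


def random_design(rng, n, p):
    return standardize(rng.normal(size=(n, p)))


class TestFitBlock:
    def test_perfect_fit_has_unit_r2_and_zero_variance(self, rng):
        g = random_design(rng, 50, 1)
        est = fit_block(g, g[:, 0])
        assert est.r2 == pytest.approx(1.0)
        assert est.var_r2 == pytest.approx(0.0)
        assert est.p_value == 0.0

    def test_null_adjusted_r2_closed_form(self):
        # r2 = 0, n = 100, p = 10: adj = 1 - 99/89
        assert adjusted_r2(0.0, 100, 10) == pytest.approx(1 - 99 / 89)
        assert adjusted_r2(0.0, 100, 10) == pytest.approx(-0.11236, abs=5e-6)

    def test_variance_formula_closed_form(self):
        # 4*0.5*0.25*90^2 / ((101^2-1)*104) = 4050/1060800
        assert r2_sampling_variance(0.5, 101, 10) == pytest.approx(
            4050 / 1_060_800)
        assert r2_sampling_variance(0.5, 101, 10) == pytest.approx(
            3.818e-3, rel=1e-3)

    def test_variance_vanishes_at_extremes_and_peaks_inside(self):
        grid = np.linspace(0, 1, 101)
        v = np.array([r2_sampling_variance(r, 200, 5) for r in grid])
        assert v[0] == 0 and v[-1] == 0
        assert 0 < np.argmax(v) < 100

    def test_matches_normal_equations_oracle(self, rng):
        # independent route: explicit (G'G)^{-1} G'y solve
        G = random_design(rng, 120, 6)
        y = standardize(G @ rng.normal(size=6) + rng.normal(size=120))
        beta = np.linalg.solve(G.T @ G, G.T @ y)
        yhat = G @ beta
        r2_oracle = float(yhat @ yhat / (y @ y))
        est = fit_block(G, y)
        assert est.r2 == pytest.approx(r2_oracle, abs=1e-10)
        n, p = 120, 6
        f_oracle = (r2_oracle / p) / ((1 - r2_oracle) / (n - p - 1))
        assert est.f_stat == pytest.approx(f_oracle, abs=1e-8)
        assert est.p_value == pytest.approx(stats.f.sf(f_oracle, p, n - p - 1))

    def test_matches_statsmodels_r2(self, rng):
        import statsmodels.api as sm

        G = random_design(rng, 80, 4)
        y = standardize(G @ rng.normal(size=4) + rng.normal(size=80))
        fit = sm.OLS(y, sm.add_constant(G)).fit()
        est = fit_block(G, y)
        assert est.r2 == pytest.approx(fit.rsquared, abs=1e-8)

    def test_ci_symmetric_about_adjusted_r2(self, rng):
        G = random_design(rng, 200, 8)
        y = standardize(rng.normal(size=200))
        est = fit_block(G, y)
        lo, hi = est.ci95
        assert (lo + hi) / 2 == pytest.approx(est.adj_r2, abs=1e-12)
        assert est.adj_r2 <= est.r2

    def test_rank_deficient_design_drops_columns(self, rng, caplog):
        col = random_design(rng, 100, 1)
        G = np.column_stack([col, col])  # duplicated predictor
        with caplog.at_level("WARNING"):
            est = fit_block(G, standardize(rng.normal(size=100)))
        assert est.p_k == 1
        assert "rank-deficient" in caplog.text

    def test_too_many_predictors_rejected(self, rng):
        G = rng.normal(size=(10, 9))
        with pytest.raises(ValueError, match="p_k"):
            fit_block(G, rng.normal(size=10))


class TestEstimateH2:
    def test_additivity_is_exact(self, rng):
        cfg = SimConfig(n=500, m=60, n_genes=6, maf_range=(0.01, 0.1),
                        true_h2=0.2, seed=4)
        g = impute_and_standardize(generate_genotypes(cfg))
        y, _ = simulate_phenotype(g, cfg)
        bs = make_exome_blocks(g, target_size=20)
        res = estimate_h2(bs, y)
        assert res.h2 == sum(e.adj_r2 for e in res.blocks)  # bit-for-bit
        assert res.var_h2 == sum(e.var_adj_r2 for e in res.blocks)
        lo, hi = res.ci95
        assert hi - res.h2 == pytest.approx(1.96 * np.sqrt(res.var_h2))

    def test_result_independent_of_block_order(self, rng):
        cfg = SimConfig(n=400, m=40, n_genes=4, maf_range=(0.01, 0.1), seed=5)
        g = impute_and_standardize(generate_genotypes(cfg))
        y, _ = simulate_phenotype(g, cfg)
        bs = make_exome_blocks(g, target_size=10)
        fwd = estimate_h2(bs, y)
        bs.blocks = list(reversed(bs.blocks))
        rev = estimate_h2(bs, y)
        assert fwd.h2 == pytest.approx(rev.h2, abs=1e-14)

    def test_negative_adjusted_r2_retained(self, rng):
        # pure-noise trait: most blocks land below zero and must stay there
        d = rng.binomial(2, 0.2, size=(300, 30)).astype(float)
        d[0, :] = 1
        bs = make_exome_blocks(impute_and_standardize(make_matrix(d)),
                               target_size=3)
        res = estimate_h2(bs, standardize(rng.normal(size=300)))
        assert any(e.adj_r2 < 0 for e in res.blocks)
        assert res.h2 == pytest.approx(sum(e.adj_r2 for e in res.blocks))

    def test_error_carries_block_label(self, rng):
        cfg = SimConfig(n=100, m=20, n_genes=2, maf_range=(0.02, 0.1), seed=6)
        g = impute_and_standardize(generate_genotypes(cfg))
        bs = make_exome_blocks(g, target_size=10)
        with pytest.raises(ValueError, match="chr1_block1"):
            estimate_h2(bs, np.zeros(99))


class TestGeneSignificance:
    def _est(self, label, p):
        from rarity.rarity_core import BlockEstimate

        return BlockEstimate(label=label, p_k=3, r2=0.01, adj_r2=0.005,
                             var_r2=1e-6, var_adj_r2=1e-6, ci95=(0, 0.01),
                             f_stat=1.0, p_value=p)

    def test_bonferroni_threshold_at_18214_genes(self):
        tab = gene_significance([self._est("A", 1e-7)], n_genes=18214)
        assert tab.attrs["threshold"] == pytest.approx(2.75e-6, rel=1e-3)
        assert bool(tab["significant"][0])

    def test_boundary_p_equal_threshold_not_significant(self):
        thr = 0.05 / 10
        tab = gene_significance([self._est("A", thr)], n_genes=10)
        assert not tab["significant"].any()

    def test_single_gene_threshold_is_alpha(self):
        tab = gene_significance([self._est("A", 0.04)], n_genes=1)
        assert tab.attrs["threshold"] == pytest.approx(0.05)
        assert bool(tab["significant"][0])

    def test_nonpositive_gene_count_rejected(self):
        with pytest.raises(ValueError):
            gene_significance([self._est("A", 0.5)], n_genes=0)


class TestCompareEstimates:
    def _result(self, h2, var, samples=None):
        from rarity.rarity_core import HeritabilityResult

        return HeritabilityResult(h2=h2, var_h2=var, ci95=(0, 0), n=100, K=1,
                                  blocks=[], samples=samples)

    def test_identical_estimates_give_z0_p1(self):
        z, p = compare_estimates(self._result(0.1, 1e-4),
                                 self._result(0.1, 1e-4))
        assert z == 0.0 and p == pytest.approx(1.0)

    def test_1_96_sigma_difference_gives_p_05(self):
        var = 1e-4
        delta = 1.96 * np.sqrt(2 * var)
        z, p = compare_estimates(self._result(0.1 + delta, var),
                                 self._result(0.1, var))
        assert p == pytest.approx(0.05, abs=1e-3)

    def test_overlapping_strata_rejected(self):
        a = self._result(0.1, 1e-4, samples=["S1", "S2"])
        b = self._result(0.2, 1e-4, samples=["S2", "S3"])
        with pytest.raises(ValueError, match="disjoint"):
            compare_estimates(a, b)
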