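"""Null-model fit, score tests, SPA and candidate-gene windows."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2

from ordgen.io_formats import GeneRecord
from ordgen.ordinal_gwas import (
    _score_all,
    candidate_gene_window,
    fit_null,
    genome_scan,
    genomic_control_lambda,
    score_test,
)


@pytest.fixture(scope="module")
def ordinal_data():
    rng = np.random.default_rng(42)
    n = 400
    x = rng.normal(size=n)
    g = rng.binomial(2, 0.3, n).astype(float)
    eta = 0.5 * x + 0.8 * g
    lat = eta + rng.logistic(size=n)
    y = np.searchsorted([-1.0, 0.5, 2.0], lat) + 1
    return y.astype(float), x, g


class TestFitNull:
    def test_intercept_only_closed_form(self):
        """Cut-points of the covariate-free fit are logit cumulative frequencies."""
        y = np.repeat([1, 2, 3], [30, 50, 20]).astype(float)
        null = fit_null(y, None)
        cum = np.array([0.3, 0.8])
        np.testing.assert_allclose(null.cutpoints, np.log(cum / (1 - cum)), atol=1e-10)
        # fitted class probabilities match the empirical frequencies
        np.testing.assert_allclose(null.probs[0], [0.3, 0.5, 0.2], atol=1e-10)

    def test_null_covariates_near_zero(self):
        rng = np.random.default_rng(3)
        n = 500
        y = rng.integers(1, 5, n).astype(float)
        x = rng.normal(size=(n, 2))
        null = fit_null(y, x)
        # independent covariates: coefficients within ~3 s.e. (se ~ 1/sqrt(n W))
        assert np.all(np.abs(null.beta) < 3.5 / np.sqrt(n * null.weights.mean()))

    def test_rank_deficient_covariates_rejected(self):
        y = np.tile([1.0, 2.0], 20)
        x = np.ones((40, 2))
        with pytest.raises(ValueError, match="rank"):
            fit_null(y, x)

    def test_single_category_rejected(self):
        with pytest.raises(ValueError, match="single category"):
            fit_null(np.ones(30), None)


class TestScoreTest:
    def test_matches_likelihood_ratio_oracle(self, ordinal_data):
        """Score p agrees asymptotically with a brute-force LRT refit."""
        from statsmodels.miscmodels.ordinal_model import OrderedModel

        y, x, g = ordinal_data
        null = fit_null(y, x[:, None])
        res = score_test(null, g, spa_threshold=np.inf)
        codes = np.unique(y, return_inverse=True)[1]
        m1 = OrderedModel(codes, np.column_stack([x, g]), distr="logit").fit(
            method="bfgs", disp=False
        )
        m0 = OrderedModel(codes, x[:, None], distr="logit").fit(method="bfgs", disp=False)
        p_lrt = chi2.sf(2 * (m1.llf - m0.llf), 1)
        assert np.log10(res.p_normal) == pytest.approx(np.log10(p_lrt), abs=0.5)

    def test_binary_trait_reduces_to_logistic_score(self):
        """C=2 case agrees with the logistic-regression LRT."""
        import statsmodels.api as sm

        rng = np.random.default_rng(8)
        n = 300
        x = rng.normal(size=n)
        g = rng.binomial(2, 0.4, n).astype(float)
        p = 1 / (1 + np.exp(-(0.3 * x + 0.6 * g - 0.5)))
        y = (rng.random(n) < p) + 1.0
        null = fit_null(y, x[:, None])
        res = score_test(null, g, spa_threshold=np.inf)
        X1 = sm.add_constant(np.column_stack([x, g]))
        X0 = sm.add_constant(x[:, None])
        m1 = sm.GLM(y - 1, X1, family=sm.families.Binomial()).fit()
        m0 = sm.GLM(y - 1, X0, family=sm.families.Binomial()).fit()
        p_lrt = chi2.sf(2 * (m1.llf - m0.llf), 1)
        assert np.log10(res.p_normal) == pytest.approx(np.log10(p_lrt), abs=0.5)

    def test_monomorphic_snp_flagged(self, ordinal_data):
        y, x, _ = ordinal_data
        null = fit_null(y, x[:, None])
        res = score_test(null, np.ones(len(y)))
        assert res.reason == "monomorphic"
        assert np.isnan(res.p_normal)
        assert not res.significant

    def test_allele_flip_invariance(self, ordinal_data):
        y, x, g = ordinal_data
        null = fit_null(y, x[:, None])
        a = score_test(null, g, spa_threshold=np.inf)
        b = score_test(null, 2.0 - g, spa_threshold=np.inf)
        assert a.p_normal == pytest.approx(b.p_normal, rel=1e-6)
        assert a.sign == -b.sign

    def test_spa_agrees_with_normal_in_bulk(self, ordinal_data):
        y, x, _ = ordinal_data
        rng = np.random.default_rng(5)
        null = fit_null(y, x[:, None])
        snps = rng.binomial(2, 0.3, size=(len(y), 300)).astype(float)
        tab = _score_all(null, snps, spa_threshold=0.0)
        z = (tab["score"] / np.sqrt(tab["variance"])).to_numpy()
        bulk = np.abs(z) < 1
        assert bulk.sum() > 50
        assert np.nanmax(np.abs(tab["p_spa"] - tab["p_normal"])[bulk]) < 0.01

    def test_spa_improves_tail_calibration_rare_variant(self):
        """For a rare variant the SPA p differs from (and exceeds fidelity of)
        the normal p in the extreme tail; sanity-check it stays a probability."""
        rng = np.random.default_rng(13)
        n = 300
        y = rng.integers(1, 4, n).astype(float)
        null = fit_null(y, None)
        g = np.zeros(n)
        g[:5] = 1.0
        tab = _score_all(null, g, spa_threshold=0.0)
        assert 0 < tab["p_spa"].iloc[0] <= 1


class TestGenomeScan:
    def test_scan_sorted_and_null_calibrated(self, unstructured_panel):
        """Across phenotype draws the null scan is calibrated on average;
        single-draw lambda is noisy on small correlated SNP sets, so a
        multi-draw mean is what the contract can promise at this scale."""
        from ordgen.popgen import maf_filter

        panel = maf_filter(unstructured_panel, 0.05)
        lams, type1 = [], []
        scan = None
        for s in range(8):
            rng = np.random.default_rng(100 + s)
            y = rng.integers(1, 10, panel.n_individuals).astype(float)
            null = fit_null(y, panel.sex_indicator()[:, None])
            scan = genome_scan(panel, null)
            p = scan["p"].dropna()
            lams.append(genomic_control_lambda(p))
            type1.append((p < 0.05).mean())
            assert scan["significant"].sum() == 0  # null data, 1e-6 threshold
        assert list(scan.columns[:3]) == ["chrom", "pos", "id"]
        for _, sub in scan.groupby("chrom"):
            assert np.all(np.diff(sub["pos"]) > 0)
        assert 0.85 < np.mean(lams) < 1.2
        assert 0.02 < np.mean(type1) < 0.09

    def test_pql_mode_runs_and_calibrates(self, filtered_panel, small_grm):
        rng = np.random.default_rng(6)
        y = rng.integers(1, 6, filtered_panel.n_individuals).astype(float)
        null = fit_null(y, filtered_panel.sex_indicator()[:, None], G=small_grm)
        assert null.mode == "pql"
        assert null.tau >= 0
        scan = genome_scan(filtered_panel, null)
        p = scan["p"].dropna()
        assert (p < 0.05).mean() < 0.12  # roughly uniform null p-values
        assert scan["significant"].sum() == 0


GENES = [
    GeneRecord("chr01", 1_000, 5_000, "+", "gA"),
    GeneRecord("chr01", 40_000, 45_000, "-", "gB"),
    GeneRecord("chr01", 80_000, 81_000, "+", "gC"),
    GeneRecord("chr01", 130_000, 140_000, "+", "gD"),
    GeneRecord("chr02", 50_000, 60_000, "+", "gE"),
]


class TestCandidateGeneWindow:
    def _hits(self, pos, chrom="chr01"):
        return pd.DataFrame({"chrom": [chrom], "pos": [pos], "id": ["snp1"]})

    def test_brute_force_interval_oracle(self):
        pos, flank = 50_000, 30_000
        # oracle: brute-force interval intersection over the gene list
        expected = {
            g.gene_id
            for g in GENES
            if g.chrom == "chr01" and g.end >= pos - flank and g.start <= pos + flank
        }
        out = candidate_gene_window(self._hits(pos), GENES, flank)
        assert set(out["gene_id"]) == expected == {"gB", "gC"}

    def test_containment_distance_zero(self):
        out = candidate_gene_window(self._hits(42_000), GENES, 30_000)
        row = out[out["gene_id"] == "gB"].iloc[0]
        assert row["distance"] == 0

    def test_inclusive_boundary(self):
        # gene gD starts exactly at pos + flank
        out = candidate_gene_window(self._hits(100_000), GENES, 30_000)
        assert "gD" in set(out["gene_id"])
        row = out[out["gene_id"] == "gD"].iloc[0]
        assert row["distance"] == 30_000

    def test_unknown_chromosome_warns_and_skips(self):
        with pytest.warns(UserWarning, match="absent"):
            out = candidate_gene_window(self._hits(10, chrom="chrZZ"), GENES, 30_000)
        assert len(out) == 0
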