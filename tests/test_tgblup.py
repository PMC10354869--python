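"""Threshold-GBLUP sampler, prediction, Brier score and LOO machinery."""

import numpy as np
import pytest

from ordgen.popgen import maf_filter, vanraden_grm
from ordgen.synthetic_data import SimulationConfig, TraitModel, simulate_genotypes, simulate_ordinal_phenotypes
from ordgen.tgblup import (
    BrierReport,
    CategoryProbabilities,
    McmcSettings,
    brier_score,
    fit_tgblup,
    loo_cv,
    predict_probs,
)

FAST = McmcSettings(n_iter=600, burn_in=200, thin=2, seed=3)


@pytest.fixture(scope="module")
def fitted(filtered_panel, small_grm):
    table, truth = simulate_ordinal_phenotypes(filtered_panel, TraitModel(var_g=1.0), seed=17)
    y = table.scores("trait")
    sex = filtered_panel.individuals["sex"].to_numpy()
    fit = fit_tgblup(y, sex, small_grm, McmcSettings(n_iter=1200, burn_in=400, thin=2, seed=5))
    return fit, y, sex, truth


class TestBrierScore:
    def test_perfect_one_hot_is_zero(self):
        probs = np.eye(9)[[0, 4, 8]]
        cp = CategoryProbabilities(ids=list("abc"), probs=probs, observed=np.array([1, 5, 9]))
        assert brier_score(cp).score == 0.0

    def test_confident_wrong_is_one(self):
        probs = np.eye(9)[[1, 1]]
        cp = CategoryProbabilities(ids=list("ab"), probs=probs, observed=np.array([5.0, 9.0]))
        assert brier_score(cp).score == 1.0

    def test_uniform_nine_classes_closed_form(self):
        probs = np.full((4, 9), 1 / 9)
        cp = CategoryProbabilities(ids=list("abcd"), probs=probs, observed=np.array([1, 3, 5, 9]))
        assert brier_score(cp).score == pytest.approx(4 / 9, abs=1e-12)

    def test_rejects_unnormalized(self):
        cp = CategoryProbabilities(ids=["a"], probs=np.full((1, 9), 0.2), observed=np.array([1.0]))
        with pytest.raises(ValueError, match="sum to 1"):
            brier_score(cp)


class TestFit:
    def test_threshold_count_and_monotonicity(self, fitted):
        fit, *_ = fitted
        assert fit.thresholds_mean.shape == (8,)  # C-1 = 8 for C=9
        gam = fit.samples["gamma"]
        assert np.all(np.diff(gam, axis=1) > 0)

    def test_recovers_signal(self, fitted):
        fit, y, sex, truth = fitted
        assert 0.4 < fit.sigma2_g_mean < 3.0
        assert np.corrcoef(fit.g_mean, truth["g_true"])[0, 1] > 0.4

    def test_pure_noise_posterior_below_signal_posterior(self, filtered_panel, small_grm):
        """Genetic variance is weakly identified from ordinal data alone, so
        under pure noise the posterior shrinks toward the prior; it must sit
        clearly below the posterior under strong simulated signal."""
        rng = np.random.default_rng(1)
        sex = filtered_panel.individuals["sex"].to_numpy()
        y_noise = rng.integers(1, 10, filtered_panel.n_individuals).astype(float)
        fit_noise = fit_tgblup(y_noise, sex, small_grm, McmcSettings(n_iter=1200, burn_in=400, seed=2))
        table, _ = simulate_ordinal_phenotypes(filtered_panel, TraitModel(var_g=3.0), seed=41)
        fit_sig = fit_tgblup(table.scores("trait"), sex, small_grm,
                             McmcSettings(n_iter=1200, burn_in=400, seed=2))
        assert fit_noise.sigma2_g_mean < 0.5 * fit_sig.sigma2_g_mean
        assert fit_noise.sigma2_g_mean < 1.0

    def test_non_psd_grm_rejected(self):
        n = 20
        bad = -np.eye(n)
        y = np.tile([1.0, 2.0], n // 2)
        with pytest.raises(ValueError, match="ridge"):
            fit_tgblup(y, np.zeros(n), bad, FAST, n_categories=2)

    def test_missing_phenotypes_allowed(self, filtered_panel, small_grm):
        table, _ = simulate_ordinal_phenotypes(filtered_panel, TraitModel(), seed=19, missing_rate=0.3)
        y = table.scores("trait")
        fit = fit_tgblup(y, filtered_panel.individuals["sex"].to_numpy(), small_grm, FAST)
        assert np.isfinite(fit.sigma2_g_mean)

    def test_absent_category_warns(self, filtered_panel, small_grm):
        y = np.full(filtered_panel.n_individuals, 2.0)
        y[: y.size // 2] = 5.0
        with pytest.warns(UserWarning, match="absent"):
            fit_tgblup(y, filtered_panel.individuals["sex"].to_numpy(), small_grm, FAST)


class TestPredict:
    def test_probabilities_sum_to_one(self, fitted):
        fit, *_ = fitted
        cp = predict_probs(fit)
        np.testing.assert_allclose(cp.probs.sum(axis=1), 1.0, atol=1e-10)
        assert np.all(cp.probs >= 0)

    def test_symmetric_thresholds_symmetric_probs(self):
        """eta = 0 with thresholds symmetric about 0 gives a symmetric vector."""
        from scipy.special import ndtr

        gam = np.array([-1.5, -0.5, 0.5, 1.5])
        edges = np.concatenate([[-np.inf], gam, [np.inf]])
        probs = np.diff(ndtr(edges - 0.0))
        np.testing.assert_allclose(probs, probs[::-1], atol=1e-12)

    def test_extreme_eta_concentrates_top_class(self, fitted):
        from scipy.special import ndtr

        fit, *_ = fitted
        edges = np.concatenate([[-np.inf], fit.thresholds_mean, [np.inf]])
        probs = np.diff(ndtr(edges - 50.0))
        assert probs[-1] == pytest.approx(1.0)

    def test_unknown_id_raises(self, fitted):
        fit, *_ = fitted
        with pytest.raises(KeyError, match="unknown individual"):
            predict_probs(fit, ["nobody"])


class TestLooCv:
    def test_toy_audit_counts_refits(self):
        cfg = SimulationConfig(
            n_individuals=12, n_chromosomes=1, n_snps_per_chrom=60,
            n_subpops=1, fst=0.0, seed=23,
        )
        panel = maf_filter(simulate_genotypes(cfg), 0.05)
        G = vanraden_grm(panel)
        table, _ = simulate_ordinal_phenotypes(panel, TraitModel(n_categories=3), seed=1)
        rep = loo_cv(table.scores("trait"), panel.individuals["sex"].to_numpy(), G,
                     FAST, n_categories=3)
        assert rep.n_refits == 12
        assert rep.scheme == "loo"
        assert 0.0 <= rep.score <= 1.0

    def test_small_n_rejected(self):
        with pytest.raises(ValueError, match="n >= 10"):
            loo_cv(np.tile([1.0, 2.0], 3), np.zeros(6), np.eye(6), FAST, n_categories=2)

    def test_informative_beats_marginal_predictor(self, filtered_panel, small_grm):
        """On strongly heritable data the model beats class-frequency guessing."""
        table, _ = simulate_ordinal_phenotypes(
            filtered_panel, TraitModel(var_g=2.0), seed=29
        )
        y = table.scores("trait")
        sex = filtered_panel.individuals["sex"].to_numpy()
        rep = loo_cv(y, sex, small_grm, FAST)
        freq = np.bincount(y.astype(int), minlength=10)[1:] / len(y)
        marginal = CategoryProbabilities(
            ids=list(filtered_panel.individuals["id"]),
            probs=np.tile(freq, (len(y), 1)),
            observed=y,
        )
        assert rep.score < brier_score(marginal).score
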