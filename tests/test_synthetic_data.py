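"""Generative contracts of the synthetic panel and liability-trait simulators."""

import numpy as np
import pytest
from scipy.special import ndtr

from ordgen.popgen import pca
from ordgen.synthetic_data import (
    SimulationConfig,
    TraitModel,
    simulate_genotypes,
    simulate_ordinal_phenotypes,
    simulate_trait_table,
)


def test_same_seed_bit_identical():
    cfg = SimulationConfig(n_individuals=50, n_chromosomes=2, n_snps_per_chrom=40, seed=3)
    a = simulate_genotypes(cfg)
    b = simulate_genotypes(cfg)
    np.testing.assert_array_equal(a.dosages, b.dosages)
    assert a.snp_map.equals(b.snp_map)
    assert a.individuals.equals(b.individuals)


def test_config_validation():
    with pytest.raises(ValueError, match="fst"):
        SimulationConfig(fst=1.0)
    with pytest.raises(ValueError, match="maf_floor"):
        SimulationConfig(maf_floor=0.6)
    with pytest.raises(ValueError, match="n_individuals"):
        SimulationConfig(n_individuals=0)


def test_independent_loci_mean_r2_near_reciprocal_n():
    """fst=0 and per-locus switching: mean off-diagonal r2 ~ 1/n."""
    cfg = SimulationConfig(
        n_individuals=100,
        n_chromosomes=1,
        n_snps_per_chrom=150,
        chromosome_length_bp=10_000_000,
        n_subpops=1,
        fst=0.0,
        copy_switch_rate=5.0,
        seed=21,
    )
    panel = simulate_genotypes(cfg)
    X = panel.dosages
    sd = X.std(axis=0)
    keep = sd > 0
    C = np.corrcoef(X[:, keep], rowvar=False) ** 2
    iu = np.triu_indices_from(C, k=1)
    vals = C[iu]
    se = vals.std() / np.sqrt(len(vals))
    assert abs(vals.mean() - 1.0 / 100) < 3 * se + 0.003


def test_pc1_separates_subpopulations(two_pop_panel):
    res = pca(two_pop_panel, n_components=2)
    labels = (two_pop_panel.individuals["group"] == "pop2").to_numpy(dtype=float)
    pc1 = res.scores[:, 0]
    # silhouette on PC1 must be positive: clusters are separated along it
    within = np.array([np.abs(pc1[labels == g] - pc1[labels == g].mean()).mean() for g in (0, 1)])
    between = abs(pc1[labels == 0].mean() - pc1[labels == 1].mean())
    assert between > within.max()


def test_positions_strictly_increasing_and_groups_labelled(two_pop_panel):
    for _, sub in two_pop_panel.snp_map.groupby("chrom"):
        assert np.all(np.diff(sub["pos"]) > 0)
    assert set(two_pop_panel.individuals["group"]) == {"pop1", "pop2"}


def test_maf_floor_infeasible_raises():
    with pytest.raises(ValueError, match="maf_floor"):
        simulate_genotypes(
            SimulationConfig(
                n_individuals=20,
                n_chromosomes=1,
                n_snps_per_chrom=30,
                n_subpops=1,
                fst=0.0,
                maf_floor=0.4,
                n_founder_haplotypes=3,  # pool freqs in {0,1/3,2/3,1}: floor 0.4 unreachable
                seed=0,
            )
        )


class TestOrdinalPhenotypes:
    def test_no_genetics_class_frequencies_match_normal_cdf(self, unstructured_panel):
        """With var_g=0 the class frequencies are differences of normal CDFs."""
        model = TraitModel(n_categories=9, var_g=0.0, sex_effect=0.0, n_causal=1)
        thr = model.resolved_thresholds()
        table, _ = simulate_ordinal_phenotypes(unstructured_panel, model, seed=8)
        counts = table.category_counts("trait")
        n = counts.sum()
        edges = np.concatenate([[-np.inf], thr, [np.inf]])
        expected = np.diff(ndtr(edges))
        se = np.sqrt(expected * (1 - expected) / n)
        assert np.all(np.abs(counts / n - expected) < 3 * se + 0.01)

    def test_binary_symmetric_split(self, unstructured_panel):
        model = TraitModel(
            n_categories=2, thresholds=np.array([0.0]), var_g=0.0, sex_effect=0.0, n_causal=1
        )
        table, _ = simulate_ordinal_phenotypes(unstructured_panel, model, seed=9)
        freq = table.category_counts("trait") / unstructured_panel.n_individuals
        assert np.all(np.abs(freq - 0.5) < 0.12)

    def test_liability_variance_partition(self):
        """corr(g, liability) ~ sqrt(var_g / (var_g + 1)) at var_g=1."""
        cfg = SimulationConfig(
            n_individuals=2000, n_chromosomes=1, n_snps_per_chrom=200,
            n_subpops=1, fst=0.0, seed=13,
        )
        panel = simulate_genotypes(cfg)
        table, truth = simulate_ordinal_phenotypes(panel, TraitModel(var_g=1.0), seed=14)
        r = np.corrcoef(truth["g_true"], truth["liability"])[0, 1]
        assert abs(r - np.sqrt(0.5)) < 0.05

    def test_non_increasing_thresholds_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            TraitModel(n_categories=3, thresholds=np.array([1.0, 0.5]))

    def test_categories_in_range_and_masking(self, unstructured_panel):
        table, _ = simulate_ordinal_phenotypes(
            unstructured_panel, TraitModel(), seed=2, missing_rate=0.2
        )
        v = table.scores("trait")
        obs = v[~np.isnan(v)]
        assert obs.min() >= 1 and obs.max() <= 9
        assert 0.05 < np.isnan(v).mean() < 0.4

    def test_separation_monotone_in_var_g(self, unstructured_panel):
        """Larger var_g weakly increases between-class separation of true g."""
        spreads = []
        for vg in (0.25, 4.0):
            model = TraitModel(var_g=vg, sex_effect=0.0)
            table, truth = simulate_ordinal_phenotypes(unstructured_panel, model, seed=31)
            y = table.scores("trait")
            means = [truth["g_true"][y == c].mean() for c in np.unique(y)]
            spreads.append(np.ptp(means))
        assert spreads[1] >= spreads[0]

    def test_trait_table_has_all_nine_traits(self, unstructured_panel):
        table, truths = simulate_trait_table(unstructured_panel, seed=5)
        assert len(table.trait_names) == 9
        assert set(truths) == set(table.trait_names)
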