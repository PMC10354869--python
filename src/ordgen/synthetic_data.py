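"""Synthetic diploid panels with population structure, LD decay and ordinal traits.

Genotypes: per-SNP subpopulation allele frequencies follow a Balding–Nichols
beta around an ancestral frequency (divergence ``fst``); haplotypes are built
by Markov copying from a finite founder pool per subpopulation, with a per-bp
switch rate that makes genotype r² decay with physical distance.

Phenotypes: a liability-threshold model.  The latent liability of individual
*j* with sex *k* is ``l_jk = S_k + g_j + eps_jk`` with ``eps ~ N(0,1)``; the
polygenic value ``g_j`` is a centered marker-effect sum rescaled to variance
``var_g``; the liability is binned into C ordered categories by C-1 strictly
increasing thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtri

from ordgen.io_formats import GenotypePanel, OrdinalPhenotypeTable, SNP_MAP_COLUMNS

#: Trait names mirroring a nine-trait spear-quality / vigor scoring panel.
NINE_TRAITS = [
    "spear_emergence",
    "anthocyanin_intensity",
    "spear_diameter",
    "head_firmness",
    "bract_opening",
    "phylloclade_density",
    "stem_number",
    "stem_length",
    "flowering_time",
]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic genotype panel.

    Defaults emulate a germplasm collection of a few hundred diploid
    genotypes in distinct germplasm clusters over ten chromosomes; marker
    density is desk-scale, not sequencing-scale.
    """

    n_individuals: int = 378
    n_chromosomes: int = 10
    chromosome_length_bp: int = 10_000_000
    n_snps_per_chrom: int = 200
    n_subpops: int = 3
    fst: float = 0.2
    copy_switch_rate: float = 1e-5
    maf_floor: float = 0.05
    n_founder_haplotypes: int = 20
    sib_family_size: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_individuals",
            "n_chromosomes",
            "chromosome_length_bp",
            "n_snps_per_chrom",
            "n_subpops",
            "n_founder_haplotypes",
            "sib_family_size",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        if not 0.0 <= self.fst < 1.0:
            raise ValueError(f"fst must be in [0, 1), got {self.fst}")
        if not 0.0 < self.maf_floor < 0.5:
            raise ValueError(f"maf_floor must be in (0, 0.5), got {self.maf_floor}")
        if self.copy_switch_rate < 0:
            raise ValueError("copy_switch_rate must be non-negative")
        if self.n_snps_per_chrom >= self.chromosome_length_bp:
            raise ValueError("more SNPs than base pairs on a chromosome")


@dataclass
class TraitModel:
    """Liability-threshold generative model for one ordinal trait.

    ``thresholds=None`` selects equal-probability cut points
    ``sqrt(1+var_g) * Phi^{-1}(c/C) + sex_effect/2`` so classes are roughly
    balanced in a half-male panel.  Residual variance is fixed at 1, so the
    liability variance is ``var_g + 1``.
    """

    n_categories: int = 9
    thresholds: np.ndarray | None = None
    sex_effect: float = 0.3
    var_g: float = 1.0
    n_causal: int = 50
    causal_effects: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_categories < 2:
            raise ValueError("need at least 2 categories")
        if self.var_g < 0:
            raise ValueError("var_g must be non-negative")
        if self.n_causal < 1:
            raise ValueError("n_causal must be >= 1")
        if self.thresholds is not None:
            self.thresholds = np.asarray(self.thresholds, dtype=float)
            if self.thresholds.shape != (self.n_categories - 1,):
                raise ValueError(
                    f"expected {self.n_categories - 1} thresholds, got {self.thresholds.shape}"
                )
            if np.any(np.diff(self.thresholds) <= 0):
                raise ValueError("thresholds must be strictly increasing")
        if self.causal_effects is not None:
            self.causal_effects = np.asarray(self.causal_effects, dtype=float)
            if self.causal_effects.shape != (self.n_causal,):
                raise ValueError("causal_effects must have length n_causal")

    def resolved_thresholds(self) -> np.ndarray:
        if self.thresholds is not None:
            return self.thresholds
        c = np.arange(1, self.n_categories) / self.n_categories
        return np.sqrt(1.0 + self.var_g) * ndtri(c) + 0.5 * self.sex_effect


def _chromosome_positions(rng, length_bp: int, n_snps: int) -> np.ndarray:
    # sorted draws plus an index offset guarantee strictly increasing positions
    raw = np.sort(rng.integers(1, length_bp - n_snps + 1, size=n_snps))
    return raw + np.arange(n_snps)


def _draw_site_frequencies(rng, n_sites: int, cfg: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """Ancestral and per-subpop allele frequencies for ``n_sites`` SNPs."""
    p_anc = rng.uniform(cfg.maf_floor, 1.0 - cfg.maf_floor, size=n_sites)
    if cfg.fst == 0.0:
        sub = np.tile(p_anc, (cfg.n_subpops, 1))
    else:
        shape = (1.0 - cfg.fst) / cfg.fst
        sub = rng.beta(p_anc * shape, (1.0 - p_anc) * shape, size=(cfg.n_subpops, n_sites))
    return p_anc, sub


def simulate_genotypes(config: SimulationConfig) -> GenotypePanel:
    """Simulate a structured diploid SNP panel.

    Returns a :class:`GenotypePanel` whose ``individuals.group`` column holds
    the subpopulation index label and whose dosage columns carry LD decaying
    with distance at rate ``copy_switch_rate``.

    Raises
    ------
    ValueError
        If, after 100 redraws, a SNP's pooled founder allele frequency cannot
        be placed inside ``[maf_floor, 1 - maf_floor]``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    p = cfg.n_chromosomes * cfg.n_snps_per_chrom
    n = cfg.n_individuals
    K = cfg.n_founder_haplotypes

    positions = np.concatenate(
        [
            _chromosome_positions(rng, cfg.chromosome_length_bp, cfg.n_snps_per_chrom)
            for _ in range(cfg.n_chromosomes)
        ]
    )
    chroms = np.repeat(
        [f"chr{c + 1:02d}" for c in range(cfg.n_chromosomes)], cfg.n_snps_per_chrom
    )

    # subpopulation assignment: near-equal consecutive blocks
    sizes = np.full(cfg.n_subpops, n // cfg.n_subpops)
    sizes[: n % cfg.n_subpops] += 1
    subpop_of = np.repeat(np.arange(cfg.n_subpops), sizes)

    _, sub_freq = _draw_site_frequencies(rng, p, cfg)
    founders = rng.random((cfg.n_subpops, K, p)) < sub_freq[:, None, :]

    # enforce the MAF floor on pooled founder-pool frequencies
    weights = sizes / n
    pooled = np.einsum("s,skj->j", weights, founders.astype(float)) / K
    bad = (pooled < cfg.maf_floor) | (pooled > 1.0 - cfg.maf_floor)
    for _ in range(100):
        if not bad.any():
            break
        idx = np.flatnonzero(bad)
        _, redraw = _draw_site_frequencies(rng, len(idx), cfg)
        founders[:, :, idx] = (
            rng.random((cfg.n_subpops, K, len(idx))) < redraw[:, None, :]
        )
        pooled[idx] = np.einsum("s,skj->j", weights, founders[:, :, idx].astype(float)) / K
        bad = (pooled < cfg.maf_floor) | (pooled > 1.0 - cfg.maf_floor)
    if bad.any():
        raise ValueError(
            f"{int(bad.sum())} SNPs could not satisfy maf_floor={cfg.maf_floor} "
            f"after 100 redraws; relax the floor or enlarge the founder pool"
        )

    # per-site haplotype-switch probability: forced at chromosome starts
    gaps = np.diff(positions).astype(float)
    new_chrom = chroms[1:] != chroms[:-1]
    with np.errstate(over="ignore"):
        switch_prob = 1.0 - np.exp(-cfg.copy_switch_rate * gaps)
    switch_prob[new_chrom] = 1.0
    switch_prob = np.concatenate([[1.0], switch_prob])

    dosages = np.empty((n, p))
    col_idx = np.arange(p)
    for s in range(cfg.n_subpops):
        n_s = int(sizes[s])
        H = 2 * n_s
        switch = rng.random((H, p)) < switch_prob
        switch[:, 0] = True
        if cfg.sib_family_size > 1:
            # full-sib blocks copy from a family-specific pool of 4 founder haplotypes
            n_fam = -(-n_s // cfg.sib_family_size)
            fam_pools = rng.integers(0, K, size=(n_fam, 4))
            fam_of_hap = np.repeat(np.arange(n_fam), 2 * cfg.sib_family_size)[:H]
            raw = rng.integers(0, 4, size=(H, p))
            draws = fam_pools[fam_of_hap[:, None], raw]
        else:
            draws = rng.integers(0, K, size=(H, p))
        last = np.maximum.accumulate(np.where(switch, col_idx[None, :], 0), axis=1)
        founder_path = np.take_along_axis(draws, last, axis=1)
        alleles = founders[s][founder_path, col_idx[None, :]]
        dosages[subpop_of == s] = (
            alleles[0::2].astype(float) + alleles[1::2].astype(float)
        )

    sex = np.where(rng.random(n) < 0.5, "M", "F")
    individuals = pd.DataFrame(
        {
            "id": [f"ind{i + 1:04d}" for i in range(n)],
            "sex": sex,
            "group": [f"pop{s + 1}" for s in subpop_of],
        }
    )
    snp_map = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": positions,
            "id": [f"{c}_{pos}" for c, pos in zip(chroms, positions)],
            "ref": "A",
            "alt": "G",
        },
        columns=SNP_MAP_COLUMNS,
    )
    return GenotypePanel(dosages=dosages, snp_map=snp_map, individuals=individuals)


def simulate_ordinal_phenotypes(
    panel: GenotypePanel,
    model: TraitModel,
    seed: int,
    trait_name: str = "trait",
    missing_rate: float = 0.0,
) -> tuple[OrdinalPhenotypeTable, pd.DataFrame]:
    """Draw one ordinal trait from the liability model on a genotype panel.

    Returns the phenotype table and a truth table (``id``, ``g_true``,
    ``liability``) for recovery tests; causal indices and effects are stored
    in ``truth.attrs``.
    """
    thresholds = model.resolved_thresholds()
    if np.any(np.diff(thresholds) <= 0):
        raise ValueError("thresholds must be strictly increasing")
    if model.n_causal > panel.n_snps:
        raise ValueError(
            f"n_causal={model.n_causal} exceeds panel SNP count {panel.n_snps}"
        )
    if np.isnan(panel.dosages).any():
        raise ValueError("panel has missing dosages; impute before simulating traits")

    rng = np.random.default_rng(seed)
    causal_idx = np.sort(rng.choice(panel.n_snps, size=model.n_causal, replace=False))
    effects = (
        model.causal_effects
        if model.causal_effects is not None
        else rng.normal(size=model.n_causal)
    )
    X = panel.dosages[:, causal_idx]
    # scale effects so the additive genetic variance sum(2 p q b^2) equals
    # var_g -- the same metric as sigma_g^2 in g ~ N(0, G sigma_g^2), so the
    # generative truth matches the GBLUP variance parameter by construction
    p = X.mean(axis=0) / 2.0
    add_var = float(np.sum(2.0 * p * (1.0 - p) * effects**2))
    if model.var_g > 0 and add_var > 0:
        b = effects * np.sqrt(model.var_g / add_var)
        g = (X - 2.0 * p) @ b
    else:
        g = np.zeros(panel.n_individuals)

    male = panel.sex_indicator()
    liability = model.sex_effect * male + g + rng.normal(size=panel.n_individuals)
    # category c iff gamma_{c-1} < l <= gamma_c (gamma_0=-inf, gamma_C=+inf)
    category = np.searchsorted(thresholds, liability, side="left") + 1

    scores = category.astype(float)
    if missing_rate > 0:
        scores[rng.random(panel.n_individuals) < missing_rate] = np.nan

    table = OrdinalPhenotypeTable(
        data=pd.DataFrame(
            {
                "id": panel.individuals["id"],
                "sex": panel.individuals["sex"],
                trait_name: scores,
            }
        ),
        n_categories=model.n_categories,
    )
    truth = pd.DataFrame(
        {"id": panel.individuals["id"], "g_true": g, "liability": liability}
    )
    truth.attrs["causal_index"] = causal_idx
    truth.attrs["causal_effects"] = np.asarray(effects, dtype=float)
    truth.attrs["thresholds"] = thresholds
    return table, truth


def simulate_trait_table(
    panel: GenotypePanel,
    seed: int,
    trait_names: list[str] | None = None,
    model: TraitModel | None = None,
) -> tuple[OrdinalPhenotypeTable, dict[str, pd.DataFrame]]:
    """Convenience: draw a multi-trait table (default: the nine spear/vigor traits)."""
    names = trait_names if trait_names is not None else NINE_TRAITS
    base = model if model is not None else TraitModel()
    frames = []
    truths: dict[str, pd.DataFrame] = {}
    ss = np.random.SeedSequence(seed)
    for child, name in zip(ss.spawn(len(names)), names):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        tab, truth = simulate_ordinal_phenotypes(panel, base, sub_seed, trait_name=name)
        frames.append(tab.data[name])
        truths[name] = truth
    data = pd.concat(
        [panel.individuals[["id", "sex"]].reset_index(drop=True)] + frames, axis=1
    )
    return OrdinalPhenotypeTable(data=data, n_categories=base.n_categories), truths
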