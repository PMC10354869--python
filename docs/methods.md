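# Methods

This note documents the models implemented in `ordgen`, the defaults and
why they were chosen, the numerical decisions that matter, and what the
synthetic-data experiments do and do not demonstrate.

## Synthetic panels

`synthetic_data.simulate_genotypes` builds diploid biallelic panels in three
layers:

1. **Allele frequencies.** Each SNP has an ancestral frequency drawn
   uniformly inside `[maf_floor, 1 − maf_floor]`; subpopulation frequencies
   follow the Balding–Nichols beta with divergence parameter `fst`
   (`fst = 0` collapses to the ancestral frequency).
2. **Founder pools.** Each subpopulation carries `n_founder_haplotypes`
   founder haplotypes (default 20) drawn site-wise from its frequencies.
   The small pool is deliberate: it emulates a narrow breeding pool in
   which panel members are related through few ancestors.
3. **Markov copying.** Each sample haplotype copies founders along the
   chromosome, switching to a random founder with probability
   `1 − exp(−copy_switch_rate · gap_bp)` between adjacent SNPs. Genotype r²
   therefore decays with physical distance at a tunable rate
   (`copy_switch_rate = 1e-5`/bp ⇒ decay constant ~100 kb); an optional
   `sib_family_size` restricts consecutive individuals to family-specific
   pools of four founder haplotypes, creating full-sib blocks.

Defaults (378 individuals, 10 chromosomes, 3 clusters, F_ST = 0.2, 200
SNPs per 10-Mb chromosome) emulate a germplasm collection with distinct
clusters and adjacent markers in LD. The chromosome length is desk-scale:
what is preserved is the *ratio* of marker spacing to LD range (~50 kb
spacing against a ~100 kb decay constant), which is what the downstream
analyses are sensitive to, not physical genome size. The `maf_floor` is
enforced on pooled founder-pool frequencies (100 redraws per failing SNP,
then an error); the realized sample MAF can still dip slightly below it.

**Ordinal traits.** The liability of individual *j* with sex *k* is
`l_jk = S_k + g_j + e_jk`, `e ~ N(0,1)`; `g` is a centered marker-effect sum
over `n_causal` randomly placed SNPs. Effects are rescaled so the **additive
genetic variance** `Σ 2p(1−p)b²` equals `var_g` — the same metric as `σ²_g`
in `g ~ N(0, G σ²_g)` (and the metric of VanRaden's denominator), so the
generative truth equals the model parameter even in related panels, where
the realized sample variance of `g` differs from `σ²_g` by the mean
self-relationship (≈1.25 in full-sib panels). Scores are
`y = c  iff  γ_{c−1} < l ≤ γ_c`; default thresholds are the
equal-probability cut points `sqrt(1+var_g)·Φ⁻¹(c/C) + S/2`. Defaults:
`C = 9`, `var_g = 1`, `sex_effect = 0.3` (mild dimorphism), `n_causal = 50`
for the general trait table; recovery experiments use a polygenic
architecture (400 causal markers) matching GBLUP's infinitesimal
assumption.

What the generator does **not** emulate: tetraploid genotypes, coalescent
site-frequency spectra, genotyping error and missingness mechanisms of
reduced-representation sequencing, real pedigrees, and
genotype-by-environment structure. Passing tests demonstrate internal
statistical correctness of the methods under the stated generative model,
not performance on any particular real panel.

## Population genetics

* **MAF filter**: SNPs kept iff minor allele frequency `> threshold`
  (default 0.05), frequencies computed on non-missing calls.
* **PCA**: full SVD of the mean-centered dosage matrix; centering-only (no
  unit-variance scaling) keeps the PCA view consistent with the GRM; a
  `scale` flag enables correlation-PCA. PVE is the eigenvalue share.
* **GRM**: VanRaden method 1 with panel-estimated frequencies. Monomorphic
  SNPs are an error (filter first). A `with_ridge` helper adds a small
  diagonal (logged) for mixed-model use on rank-deficient panels.
* **Imputation**: per-SNP mode with ties broken toward the lower dosage —
  a deliberately simple, documented placeholder appropriate for panels
  with controlled missingness; haplotype-based imputation is out of scope.

## LD

r² is the squared Pearson correlation of 0/1/2 dosages on
pairwise-complete observations ("composite genotypic r²"), within
chromosomes, restricted to pairs ≤ 1 Mb apart by default (means beyond that
are flat). Thinning is greedy left-to-right with the vcftools `--thin`
rule. Decay curves average r² in contiguous distance bins (default 10 kb;
100-kb bins are the coarser view used for whole-chromosome summaries —
both widths are supported).

## Polychoric correlation

Two-step estimator: thresholds are `Φ⁻¹` of the marginal cumulative
proportions; ρ maximizes the bivariate-normal rectangle-probability
likelihood (bounded Brent search in `|ρ| ≤ 0.999`). Rectangle probabilities
use a closed-form bivariate normal CDF via Owen's T function, unit-checked
against quadrature. The p-value is a χ²₁ likelihood-ratio test against
ρ = 0. Unobserved categories are dropped before tabulation — this leaves
the likelihood unchanged (zero-count, zero-width cells) and makes ρ̂
exactly invariant under merging of empty categories. A `full_ml` flag
re-optimizes thresholds jointly. Trait-pair matrices report raw p-values
flagged at 0.05 with no multiplicity correction (matching the convention of
reporting each pair on its own evidence).

## Ordinal GWAS

Stage 1 fits the cumulative-logit null `P(y ≤ c) = expit(α_c − Xβ)` with
covariates (sex + top PCs; no intercept — the cut-points absorb location).
The fit is polished by Newton steps on the exact score until the gradient
vanishes at ~1e-9, which makes score-test identities (Σ residuals = 0,
hence allele-flip invariance) hold numerically. With a GRM supplied, a
polygenic variance τ is estimated by penalized quasi-likelihood: iterate
working response `z = η + s/W`, REML (bounded Brent) for τ in the working
LMM `z = Xβ + u + e`, `u ~ N(0, τG)`, and mixed-model updates of `η`.

Stage 2 scores each SNP: `U = gᵀs` with the null score residuals `s`.
In the fixed-effects mode the variance is the exact efficient-score
variance, projecting out **both** covariates and cut-points via the full
expected-information matrix (multinomial identity
`I_tu = Σᵢ Σ_c ∂π_c/∂t · ∂π_c/∂u / π_c`); in the mixed mode it is `gᵀPg`
with the REML projection `P`. Normal p-values come from `U²/Var`.

**Saddlepoint approximation.** Under the null, `U` is a sum of independent
per-individual contributions `g̃ᵢ·s_i(c)` with multinomial class `c`
(`g̃` = covariate-residualized genotype). The CGF
`K(t) = Σᵢ log Σ_c π_ic exp(t g̃ᵢ s_ic)` is solved by Newton with a
bracketing (Brent) fallback; tails use the Barndorff-Nielsen formula, the
lower tail by negating the contributions. A variance-ratio rescaling keeps
SPA and normal p-values consistent in the bulk. SPA replaces the normal
p-value when `|z|` exceeds the switch threshold (default 2).

Candidate-gene windows report genes overlapping `[pos − flank, pos + flank]`
(1-based inclusive, default ±30 kb) with the distance to the nearest gene
edge.

## Threshold-GBLUP

Identification follows the probit-ordinal convention: residual variance
fixed at 1, no intercept, all C−1 thresholds free. The Gibbs sampler uses
Albert–Chib augmentation (truncated-normal liabilities; missing phenotypes
sampled unconstrained, which is how cross-validation masks individuals),
a flat prior on the sex contrast, breeding values sampled in the
eigenbasis of G (decomposed once), and a scaled-inverse-χ² conditional for
`σ²_g`.

**Priors.** `σ²_g ~ scaled-inv-χ²(df = 5, ν·s² = Var(l̃)·R²·(df+2))` with
`R² = 0.5` and `l̃` the inverse-normal score proxy of the observed classes
— the standard Bayesian-GBLUP default convention (prior mode at
`R²·Var(l̃)`). Thresholds carry the **induced uniform-Dirichlet prior** on
the marginal class probabilities of the liability at its current scale,
whose density per cut-point is `N(0, 1 + σ²_g)`.

The threshold prior matters more than usual here. With a flat threshold
prior the posterior contains a *scale-inflation ridge*: because the outer
categories are half-open and `g` is a flexible individual-level effect,
liabilities, thresholds, breeding values and `σ²_g` can inflate jointly at
almost no likelihood cost, and chains drift to `σ²_g` an order of magnitude
above any plausible value. Two diagnostics isolate this (and were used to
verify the sampler): an independent ensemble sampler on the marginal
posterior of a small instance reproduces the Gibbs posterior exactly, and
fixing thresholds at their generative values restores tight recovery. The
induced-Dirichlet prior removes the ridge while remaining scale-coherent
(it does not fight the model's own liability scale). Two Metropolis
ingredients keep the chain exact and well mixed: the `σ²_g` draw is
corrected for the threshold prior's scale dependence, and a group move
proposes rescaling the entire latent configuration
`(l, γ, β, g, σ²_g) → (cl, cγ, cβ, cg, c²σ²_g)` with the appropriate
Jacobian, traversing the scale direction directly.

**Defaults**: 6,000 iterations, 1,000 burn-in, thin 2; a split-chain
diagnostic on `σ²_g` warns above 1.1. **Prediction**:
`π̂_c = Φ(γ_c − η) − Φ(γ_{c−1} − η)` averaged over retained samples.
**LOO CV** masks one phenotype per fold and refits; all folds run as
parallel chains of one batched sampler sharing the eigendecomposition, so
a 300-fold LOO costs seconds rather than hours, and an audit counter
records the number of refits. Cross-validation chains are shorter (700
iterations, 250 burn-in) — Brier scores are posterior-mean functionals
that stabilize far faster than variance components.

**Known limitations.** `σ²_g` is weakly identified from ordinal data at a
few hundred individuals: the likelihood pins heritability-like ratios well
but the liability scale only weakly, so the posterior for `σ²_g` is wide
and prior-sensitive; recovery experiments use family-structured panels
(full-sib blocks of 5) and polygenic traits, where the within/between
family contrast carries most of the information. Degenerate inputs:
non-PSD G raises with a ridge suggestion; categories absent from training
keep prior-driven boundaries (warned); a constant sex column is dropped
with a warning.

## Pipeline

`pipeline.run_pipeline` executes simulate/load → impute → MAF filter → PCA
→ GRM → LD → trait correlations → GWAS (with optional candidate-gene scan)
→ TGBLUP LOO CV from one YAML config, writing TSV outputs plus a manifest
with SHA-256 checksums, parameters and per-stage summaries. One global seed
is fanned out per stage through fixed `SeedSequence` spawn keys, so
enabling or disabling one stage never perturbs another stage's stream;
stages communicate only through files. Problem sizes in the test-suite and
acceptance runs (n = 300, 2,000 SNPs, 20-seed repetitions, reduced CV
chains) are the package's chosen desk-scale study conditions; the methods
scale to larger panels linearly in SNPs and cubically in individuals (one
eigendecomposition of G per trait).
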