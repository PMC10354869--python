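"""MAF filtering, genotype PCA and the VanRaden genomic relationship matrix."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA as _SkPCA

from ordgen.io_formats import GenotypePanel

logger = logging.getLogger(__name__)


@dataclass
class PcaResult:
    """Principal-component scores of the centered dosage matrix.

    ``pve`` is the proportion of total genotypic variance explained by each
    retained component (non-increasing; sums to 1 at full rank).
    """

    scores: np.ndarray
    pve: np.ndarray

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


@dataclass
class GenomicRelationshipMatrix:
    """VanRaden (method 1) genomic relationship matrix over panel individuals."""

    matrix: np.ndarray
    allele_freqs: np.ndarray
    ids: list[str]

    def __post_init__(self) -> None:
        G = np.asarray(self.matrix, dtype=float)
        if not np.allclose(G, G.T, atol=1e-10):
            raise ValueError("G must be symmetric")
        if not np.isfinite(G).all():
            raise ValueError("G contains non-finite entries")
        self.matrix = (G + G.T) / 2.0

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.matrix)[0])

    def with_ridge(self, eps: float = 1e-6) -> "GenomicRelationshipMatrix":
        """Copy of G with ``eps`` added on the diagonal (logged)."""
        logger.info("adding ridge %.1e to G diagonal", eps)
        return GenomicRelationshipMatrix(
            matrix=self.matrix + eps * np.eye(len(self.matrix)),
            allele_freqs=self.allele_freqs,
            ids=list(self.ids),
        )


def maf_filter(panel: GenotypePanel, threshold: float = 0.05) -> GenotypePanel:
    """Drop SNPs whose minor allele frequency is <= ``threshold``.

    Frequencies are computed on non-missing calls, so the filter can run
    before imputation.
    """
    freq = panel.allele_frequencies()
    maf = np.minimum(freq, 1.0 - freq)
    keep = np.flatnonzero(maf > threshold)
    if keep.size == 0:
        raise ValueError(
            f"no SNPs pass MAF > {threshold}; lower the threshold or check the input"
        )
    logger.info("MAF filter: kept %d of %d SNPs", keep.size, panel.n_snps)
    return panel.take_snps(keep)


def pca(panel: GenotypePanel, n_components: int = 10, scale: bool = False) -> PcaResult:
    """PCA of the dosage matrix (mean-centered columns; no pruning or clumping).

    Centering-only is the default so the PCA view stays consistent with the
    GRM construction; set ``scale=True`` for unit-variance columns.
    """
    if np.isnan(panel.dosages).any():
        raise ValueError("PCA requires complete dosages; impute missing calls first")
    X = panel.dosages - panel.dosages.mean(axis=0)
    if scale:
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = X / sd
    rank = min(X.shape) if X.shape[0] > 1 else 1
    if n_components > rank:
        warnings.warn(
            f"n_components={n_components} exceeds rank {rank}; truncating",
            stacklevel=2,
        )
        n_components = rank
    fit = _SkPCA(n_components=rank, svd_solver="full").fit(X)
    scores = fit.transform(X)[:, :n_components]
    pve = fit.explained_variance_ratio_[:n_components]
    return PcaResult(scores=scores, pve=pve)


def vanraden_grm(panel: GenotypePanel) -> GenomicRelationshipMatrix:
    """VanRaden method-1 G: ``W W' / (2 * sum p(1-p))`` with ``W = X - 2p``.

    Allele frequencies are computed from the panel itself.  Monomorphic SNPs
    must be filtered first (they contribute nothing and signal an unfiltered
    panel).
    """
    if np.isnan(panel.dosages).any():
        raise ValueError("GRM requires complete dosages; impute missing calls first")
    p = panel.allele_frequencies()
    if np.any((p == 0.0) | (p == 1.0)):
        raise ValueError("monomorphic SNPs present; apply maf_filter first")
    W = panel.dosages - 2.0 * p
    denom = 2.0 * np.sum(p * (1.0 - p))
    G = (W @ W.T) / denom
    return GenomicRelationshipMatrix(
        matrix=G, allele_freqs=p, ids=list(panel.individuals["id"])
    )
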