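"""SNP thinning, pairwise genotype r² and binned LD-decay curves.

r² is the squared Pearson correlation of 0/1/2 dosages within a chromosome
(the "composite genotypic r²" of vcftools ``--geno-r2``), computed on
pairwise-complete observations; no haplotype phasing or EM is involved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ordgen.io_formats import GenotypePanel

logger = logging.getLogger(__name__)

#: Columns of the pair table returned by :func:`pairwise_r2`.
LD_PAIR_COLUMNS = ["chrom", "pos_a", "pos_b", "distance", "r2", "n"]


@dataclass
class LdDecayCurve:
    """Mean r² per physical-distance bin for one chromosome.

    ``bin_edges`` has length ``len(mean_r2) + 1``; bins are contiguous and
    left-closed; empty bins carry NaN means and zero counts.
    """

    chrom: str
    bin_edges: np.ndarray
    mean_r2: np.ndarray
    pair_counts: np.ndarray


def thin_snps(panel: GenotypePanel, window_bp: int = 50_000) -> GenotypePanel:
    """Greedy left-to-right thinning: keep a SNP iff it lies >= ``window_bp``
    after the last kept SNP on the same chromosome (vcftools ``--thin``)."""
    if window_bp <= 0:
        return panel
    keep: list[int] = []
    for _, sub in panel.snp_map.groupby("chrom", sort=False):
        last = -np.inf
        for idx, pos in zip(sub.index, sub["pos"].to_numpy()):
            if pos - last >= window_bp:
                keep.append(idx)
                last = pos
    logger.info("thinning: kept %d of %d SNPs at window %d bp", len(keep), panel.n_snps, window_bp)
    return panel.take_snps(np.sort(keep))


def _pair_r2_block(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs r² and pairwise-complete n for a dosage block (no missing fast path)."""
    if not np.isnan(X).any():
        sd = X.std(axis=0)
        n = np.full((X.shape[1], X.shape[1]), X.shape[0])
        with np.errstate(invalid="ignore", divide="ignore"):
            C = np.corrcoef(X, rowvar=False)
        r2 = C**2
        r2[sd == 0, :] = np.nan
        r2[:, sd == 0] = np.nan
        return r2, n
    p = X.shape[1]
    r2 = np.full((p, p), np.nan)
    n = np.zeros((p, p), dtype=int)
    for a in range(p):
        for b in range(a, p):
            mask = ~np.isnan(X[:, a]) & ~np.isnan(X[:, b])
            m = int(mask.sum())
            n[a, b] = n[b, a] = m
            if m < 2:
                continue
            xa, xb = X[mask, a], X[mask, b]
            if xa.std() == 0 or xb.std() == 0:
                continue
            r = np.corrcoef(xa, xb)[0, 1]
            r2[a, b] = r2[b, a] = r * r
    return r2, n


def pairwise_r2(panel: GenotypePanel, max_dist_bp: int = 1_000_000) -> pd.DataFrame:
    """Intra-chromosome pairwise r² for SNP pairs at distance <= ``max_dist_bp``.

    Returns a table with columns ``chrom, pos_a, pos_b, distance, r2, n``
    (``pos_a < pos_b``).  Pairs involving an in-sample monomorphic SNP, or
    with fewer than two shared calls, are skipped and counted in the log.
    """
    frames = []
    skipped = 0
    for chrom, sub in panel.snp_map.groupby("chrom", sort=False):
        cols = sub.index.to_numpy()
        pos = sub["pos"].to_numpy()
        if len(cols) < 2:
            continue
        r2, n = _pair_r2_block(panel.dosages[:, cols])
        a_idx, b_idx = np.triu_indices(len(cols), k=1)
        dist = pos[b_idx] - pos[a_idx]
        within = dist <= max_dist_bp
        a_idx, b_idx, dist = a_idx[within], b_idx[within], dist[within]
        vals = r2[a_idx, b_idx]
        ok = ~np.isnan(vals) & (n[a_idx, b_idx] >= 2)
        skipped += int((~ok).sum())
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos_a": pos[a_idx[ok]],
                    "pos_b": pos[b_idx[ok]],
                    "distance": dist[ok],
                    "r2": vals[ok],
                    "n": n[a_idx[ok], b_idx[ok]],
                }
            )
        )
    if skipped:
        logger.info("pairwise_r2: skipped %d monomorphic/undersized pairs", skipped)
    if not frames:
        return pd.DataFrame(columns=LD_PAIR_COLUMNS)
    return pd.concat(frames, ignore_index=True)[LD_PAIR_COLUMNS]


def ld_decay(pairs: pd.DataFrame, bin_bp: int = 10_000) -> LdDecayCurve:
    """Bin one chromosome's pair table by distance and average r² per bin."""
    if len(pairs) == 0:
        return LdDecayCurve(
            chrom="", bin_edges=np.array([0.0]), mean_r2=np.array([]), pair_counts=np.array([], dtype=int)
        )
    chroms = pairs["chrom"].unique()
    if len(chroms) != 1:
        raise ValueError(f"ld_decay expects pairs from one chromosome, got {list(chroms)}")
    dist = pairs["distance"].to_numpy()
    n_bins = int(np.ceil(dist.max() / bin_bp)) or 1
    edges = np.arange(n_bins + 1) * float(bin_bp)
    which = np.minimum((dist // bin_bp).astype(int), n_bins - 1)
    counts = np.bincount(which, minlength=n_bins)
    sums = np.bincount(which, weights=pairs["r2"].to_numpy(), minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return LdDecayCurve(chrom=str(chroms[0]), bin_edges=edges, mean_r2=means, pair_counts=counts)
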