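"""Polychoric correlation between ordinal traits.

Two-step estimator: thresholds come from the inverse-normal of the marginal
cumulative proportions; the latent correlation rho then maximizes the
bivariate-normal cell-probability likelihood over the contingency table.
Significance is a likelihood-ratio test of rho = 0 (chi-square, 1 df).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar
from scipy.special import ndtr, ndtri, owens_t
from scipy.stats import chi2

from ordgen.io_formats import OrdinalPhenotypeTable

RHO_BOUND = 0.999
_TINY = 1e-12


@dataclass
class PolychoricResult:
    """Latent bivariate-normal correlation inferred from a cross-tabulation."""

    rho: float
    row_thresholds: np.ndarray
    col_thresholds: np.ndarray
    loglik: float
    p_value: float


@dataclass
class CorrelationMatrixResult:
    """All pairwise polychoric correlations of a trait table."""

    rho: pd.DataFrame
    p_value: pd.DataFrame
    significant: pd.DataFrame

    def to_long(self, alpha: float = 0.05) -> pd.DataFrame:
        rows = []
        traits = list(self.rho.columns)
        for i, a in enumerate(traits):
            for b in traits[i + 1 :]:
                rows.append(
                    {
                        "trait_a": a,
                        "trait_b": b,
                        "rho": self.rho.loc[a, b],
                        "p": self.p_value.loc[a, b],
                        "significant": bool(self.p_value.loc[a, b] < alpha),
                    }
                )
        return pd.DataFrame(rows)


def bvn_cdf(h, k, rho: float) -> np.ndarray:
    """Standard bivariate normal CDF P(X <= h, Y <= k; rho) via Owen's T."""
    h = np.clip(np.asarray(h, dtype=float), -8.5, 8.5)
    k = np.clip(np.asarray(k, dtype=float), -8.5, 8.5)
    h, k = np.broadcast_arrays(h, k)
    if rho >= 1.0 - 1e-12:
        return ndtr(np.minimum(h, k))
    if rho <= -1.0 + 1e-12:
        return np.maximum(ndtr(h) + ndtr(k) - 1.0, 0.0)
    # nudge exact zeros so the Owen's T arguments stay finite
    h = np.where(np.abs(h) < _TINY, _TINY, h)
    k = np.where(np.abs(k) < _TINY, _TINY, k)
    s = np.sqrt(1.0 - rho * rho)
    ah = (k - rho * h) / (h * s)
    ak = (h - rho * k) / (k * s)
    delta = np.where(h * k < 0, 0.5, 0.0)
    out = 0.5 * (ndtr(h) + ndtr(k)) - owens_t(h, ah) - owens_t(k, ak) - delta
    return np.clip(out, 0.0, 1.0)


def _cell_probs(a: np.ndarray, b: np.ndarray, rho: float) -> np.ndarray:
    """Rectangle probabilities for threshold grids ``a`` (rows), ``b`` (cols)."""
    A = np.concatenate([[-np.inf], a, [np.inf]])
    B = np.concatenate([[-np.inf], b, [np.inf]])
    Z = bvn_cdf(A[:, None], B[None, :], rho)
    P = Z[1:, 1:] - Z[:-1, 1:] - Z[1:, :-1] + Z[:-1, :-1]
    return np.clip(P, _TINY, 1.0)


def _marginal_thresholds(margin: np.ndarray) -> np.ndarray:
    cum = np.cumsum(margin)[:-1] / margin.sum()
    return ndtri(cum)


def _table_loglik(counts: np.ndarray, a: np.ndarray, b: np.ndarray, rho: float) -> float:
    return float(np.sum(counts * np.log(_cell_probs(a, b, rho))))


def polychoric(x, y, full_ml: bool = False) -> PolychoricResult:
    """Polychoric correlation of two ordinal vectors (NaN treated as missing).

    Unobserved categories are dropped before tabulation, which leaves the
    likelihood unchanged (their cells have zero counts and zero width).
    ``full_ml=True`` re-optimizes thresholds jointly with rho.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = ~np.isnan(x) & ~np.isnan(y)
    if mask.sum() < 10:
        raise ValueError(f"need >= 10 complete pairs, got {int(mask.sum())}")
    x, y = x[mask].astype(int), y[mask].astype(int)
    x_levels, xi = np.unique(x, return_inverse=True)
    y_levels, yi = np.unique(y, return_inverse=True)
    if len(x_levels) < 2 or len(y_levels) < 2:
        raise ValueError("each variable needs at least 2 observed categories")
    counts = np.zeros((len(x_levels), len(y_levels)))
    np.add.at(counts, (xi, yi), 1.0)

    a = _marginal_thresholds(counts.sum(axis=1))
    b = _marginal_thresholds(counts.sum(axis=0))

    res = minimize_scalar(
        lambda r: -_table_loglik(counts, a, b, r),
        bounds=(-RHO_BOUND, RHO_BOUND),
        method="bounded",
        options={"xatol": 1e-6},
    )
    rho_hat = float(np.clip(res.x, -RHO_BOUND, RHO_BOUND))
    ll1 = -float(res.fun)

    if full_ml:
        # parametrize thresholds as (first, log-increments) to keep them ordered
        def pack(t):
            return np.concatenate([[t[0]], np.log(np.diff(t))])

        def unpack(z, m):
            return np.concatenate([[z[0]], z[0] + np.cumsum(np.exp(z[1 : m]))])

        na, nb = len(a), len(b)
        z0 = np.concatenate([[np.arctanh(rho_hat)], pack(a), pack(b)])

        def nll(z):
            r = np.tanh(z[0]) * RHO_BOUND
            aa = unpack(z[1 : 1 + na], na)
            bb = unpack(z[1 + na :], nb)
            return -_table_loglik(counts, aa, bb, r)

        opt = minimize(nll, z0, method="Nelder-Mead", options={"maxiter": 4000, "fatol": 1e-8})
        rho_hat = float(np.tanh(opt.x[0]) * RHO_BOUND)
        a = unpack(opt.x[1 : 1 + na], na)
        b = unpack(opt.x[1 + na :], nb)
        ll1 = -float(opt.fun)

    ll0 = _table_loglik(counts, a, b, 0.0)
    lrt = max(2.0 * (ll1 - ll0), 0.0)
    p = float(chi2.sf(lrt, df=1))
    return PolychoricResult(
        rho=rho_hat, row_thresholds=a, col_thresholds=b, loglik=ll1, p_value=p
    )


def correlation_matrix(
    table: OrdinalPhenotypeTable, alpha: float = 0.05
) -> CorrelationMatrixResult:
    """All pairwise polychoric correlations with LRT p-values.

    Raw p-values are flagged at ``alpha`` with no multiplicity correction;
    pairs failing the polychoric preconditions are set missing with a warning.
    """
    traits = table.trait_names
    if len(traits) < 2:
        raise ValueError("need at least two traits for a correlation matrix")
    m = len(traits)
    rho = np.eye(m)
    pval = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            try:
                res = polychoric(table.scores(traits[i]), table.scores(traits[j]))
                rho[i, j] = rho[j, i] = res.rho
                pval[i, j] = pval[j, i] = res.p_value
            except ValueError as exc:
                warnings.warn(
                    f"polychoric failed for ({traits[i]}, {traits[j]}): {exc}",
                    stacklevel=2,
                )
                rho[i, j] = rho[j, i] = np.nan
                pval[i, j] = pval[j, i] = np.nan
    rho_df = pd.DataFrame(rho, index=traits, columns=traits)
    p_df = pd.DataFrame(pval, index=traits, columns=traits)
    return CorrelationMatrixResult(
        rho=rho_df, p_value=p_df, significant=p_df < alpha
    )
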