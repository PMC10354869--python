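"""Proportional-odds logistic mixed-model GWAS for ordinal (and binary) traits.

Two-stage design: a null cumulative-logit model is fitted once with fixed
covariates (typically sex and leading principal components) and, optionally,
a polygenic random effect with a dense genomic relationship matrix (estimated
by penalized quasi-likelihood with a REML variance step).  Each SNP is then
screened by a score test; tail p-values use a saddlepoint approximation of
the score's null cumulant generating function (a sum of independent
per-individual multinomial contributions), switched on when the standardized
score exceeds a threshold.

This is a methodological re-implementation of the dense-GRM null /
score-test / saddlepoint design of proportional-odds mixed-model GWAS, not a
numerical clone of any particular package.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize_scalar
from scipy.special import expit, logsumexp, ndtr
from scipy.stats import chi2

from ordgen.io_formats import GenotypePanel, GeneRecord
from ordgen.popgen import GenomicRelationshipMatrix

logger = logging.getLogger(__name__)

SPA_SWITCH_DEFAULT = 2.0


@dataclass
class NullModel:
    """Stage-one null fit shared by all per-SNP score tests."""

    cutpoints: np.ndarray          # C-1 strictly increasing intercepts
    beta: np.ndarray               # covariate coefficients
    tau: float                     # polygenic variance of the GRM random effect
    probs: np.ndarray              # (n, C) fitted category probabilities
    score_residuals: np.ndarray    # (n,) d loglik / d eta at the null fit
    weights: np.ndarray            # (n,) per-individual Fisher information for eta
    s_cat: np.ndarray              # (n, C) score residual had individual i been in class c
    X: np.ndarray                  # (n, q) covariates
    levels: np.ndarray             # observed ordinal levels, ascending
    # exact efficient-score machinery (fixed-effects mode)
    cross_info: np.ndarray | None = None   # (n, n_theta) per-individual cross information
    info_theta: np.ndarray | None = None   # (n_theta, n_theta)
    # PQL machinery (mixed mode)
    P: np.ndarray | None = None            # REML projection matrix
    working_residual: np.ndarray | None = None  # P @ working response

    @property
    def mode(self) -> str:
        return "pql" if self.P is not None else "fixed"

    @property
    def n_categories(self) -> int:
        return len(self.levels)


@dataclass
class ScoreTestResult:
    """Score-test outcome for one SNP."""

    snp_id: str
    chrom: str
    pos: int
    score: float
    variance: float
    p_normal: float
    p_spa: float
    sign: int
    significant: bool
    reason: str = ""


def _logistic_pieces(eta: np.ndarray, cutpoints: np.ndarray):
    """CDF at the category edges, cell probabilities, score and weight arrays."""
    n = len(eta)
    C = len(cutpoints) + 1
    E = np.empty((n, C + 1))
    E[:, 0], E[:, C] = 0.0, 1.0
    E[:, 1:C] = expit(cutpoints[None, :] - eta[:, None])
    f = E * (1.0 - E)                       # logistic density at the edges
    probs = np.clip(np.diff(E, axis=1), 1e-12, 1.0)
    u = f[:, :-1] - f[:, 1:]                # d pi_c / d eta  (negated)
    s_cat = u / probs
    W = np.sum(u * u / probs, axis=1)
    return E, f, probs, u, s_cat, W


def _intercept_only_cutpoints(codes: np.ndarray, C: int) -> np.ndarray:
    """Closed-form MLE: cut-points are the logits of cumulative frequencies."""
    counts = np.bincount(codes, minlength=C)
    cum = np.cumsum(counts)[:-1] / counts.sum()
    cum = np.clip(cum, 1e-10, 1 - 1e-10)
    return np.log(cum / (1.0 - cum))


def fit_null(
    y,
    covariates=None,
    G: GenomicRelationshipMatrix | np.ndarray | None = None,
    max_iter: int = 100,
) -> NullModel:
    """Fit the covariates-only (plus optional polygenic) null model.

    ``y`` is an ordinal vector (any integer coding; observed levels are used
    in ascending order); ``covariates`` an (n, q) matrix without an intercept
    column (the cut-points absorb location).  With ``G`` supplied, a polygenic
    random effect variance ``tau`` is estimated by iterating a working linear
    mixed model (REML step for ``tau``); otherwise ``tau = 0``.
    """
    y = np.asarray(y, dtype=float)
    if np.isnan(y).any():
        raise ValueError("null model requires complete phenotypes")
    levels, codes = np.unique(y, return_inverse=True)
    C = len(levels)
    if C < 2:
        raise ValueError("phenotype has a single category")
    n = len(y)

    if covariates is None:
        X = np.empty((n, 0))
    else:
        X = np.atleast_2d(np.asarray(covariates, dtype=float))
        if X.shape[0] != n:
            X = X.T
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("covariate matrix is rank deficient")
    q = X.shape[1]

    if q == 0:
        cutpoints = _intercept_only_cutpoints(codes, C)
        beta = np.zeros(0)
    else:
        from statsmodels.miscmodels.ordinal_model import OrderedModel

        model = OrderedModel(codes, X, distr="logit")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(method="bfgs", maxiter=max_iter, disp=False)
        if not res.mle_retvals.get("converged", True):
            raise RuntimeError(
                f"null cumulative-logit fit did not converge in {max_iter} iterations "
                f"(possible separation); final |grad| = "
                f"{np.abs(res.mle_retvals.get('gopt', np.nan)).max():.2e}"
            )
        beta = np.asarray(res.params[:q])
        cutpoints = np.asarray(model.transform_threshold_params(res.params))[1:-1]
        # polish to high precision so score identities (e.g. sum of residuals
        # = 0, hence allele-flip invariance) hold numerically
        cutpoints, beta = _newton_polish(codes, X, cutpoints, beta)

    eta = X @ beta if q else np.zeros(n)
    tau = 0.0
    P = None
    rtilde = None

    if G is not None:
        Gm = G.matrix if isinstance(G, GenomicRelationshipMatrix) else np.asarray(G, float)
        tau, eta, P, rtilde, Xw = _pql_fit(codes + 0, cutpoints, X, Gm, eta, max_iter)
        X_for_proj = Xw
    else:
        X_for_proj = X

    # exact efficient-score information, projecting out cut-points and covariates
    # multinomial identity: I_tu = sum_i sum_c (dpi_c/dt)(dpi_c/du) / pi_c
    probs, u, s_cat, W, Dalpha, Dfull = _theta_tensors(eta, cutpoints, X)
    s = s_cat[np.arange(n), codes]
    info_theta = np.einsum("ncm,ncl->ml", Dfull / probs[:, :, None], Dfull)
    Valpha = np.einsum("nc,ncm->nm", s_cat, Dalpha)
    cross = np.concatenate([Valpha, X * W[:, None]], axis=1)

    return NullModel(
        cutpoints=cutpoints,
        beta=beta,
        tau=tau,
        probs=probs,
        score_residuals=s if P is None else rtilde,
        weights=W,
        s_cat=s_cat,
        X=X_for_proj,
        levels=levels,
        cross_info=cross if P is None else None,
        info_theta=info_theta if P is None else None,
        P=P,
        working_residual=rtilde,
    )


def _theta_tensors(eta, cutpoints, X):
    """Per-individual derivative tensors of the cell probabilities w.r.t.
    (cut-points, covariate coefficients)."""
    n = len(eta)
    C = len(cutpoints) + 1
    E, f, probs, u, s_cat, W = _logistic_pieces(eta, cutpoints)
    f_free = f[:, 1:C]
    Dalpha = np.zeros((n, C, C - 1))
    for m_ in range(C - 1):
        Dalpha[:, m_, m_] += f_free[:, m_]
        Dalpha[:, m_ + 1, m_] -= f_free[:, m_]
    Dbeta = u[:, :, None] * X[:, None, :]
    Dfull = np.concatenate([Dalpha, Dbeta], axis=2)
    return probs, u, s_cat, W, Dalpha, Dfull


def _newton_polish(codes, X, cutpoints, beta, tol=1e-9, max_iter=40):
    """Drive the (cut-points, beta) score vector to ~0 by Newton steps."""
    n = len(codes)
    rows = np.arange(n)
    for _ in range(max_iter):
        eta = X @ beta if X.shape[1] else np.zeros(n)
        probs, _, _, _, _, Dfull = _theta_tensors(eta, cutpoints, X)
        score_vec = (Dfull[rows, codes, :] / probs[rows, codes, None]).sum(axis=0)
        if np.max(np.abs(score_vec)) < tol * n:
            break
        info = np.einsum("ncm,ncl->ml", Dfull / probs[:, :, None], Dfull)
        try:
            delta = np.linalg.solve(info, score_vec)
        except np.linalg.LinAlgError:
            break
        step = 1.0
        C1 = len(cutpoints)
        for _ in range(20):
            new_cut = cutpoints + step * delta[:C1]
            if np.all(np.diff(new_cut) > 0):
                break
            step /= 2.0
        else:
            break
        cutpoints = cutpoints + step * delta[:C1]
        beta = beta + step * delta[C1:]
    return cutpoints, beta


def _pql_fit(codes, cutpoints, X, Gm, eta0, max_iter):
    """Penalized quasi-likelihood loop with a REML step for tau.

    The working model carries an intercept (absorbing cut-point location), so
    score statistics stay invariant to allele relabeling.
    """
    n = len(codes)
    Xw = np.column_stack([np.ones(n), X])
    eta = eta0.copy()
    tau = 0.1
    I = np.eye(n)
    for _ in range(max_iter):
        _, _, _, _, s_cat, W = _logistic_pieces(eta, cutpoints)
        s = s_cat[np.arange(n), codes]
        W = np.clip(W, 1e-8, None)
        z = eta + s / W
        Dinv = np.diag(1.0 / W)

        def neg_reml(log_tau):
            t = np.exp(log_tau)
            Sigma = Dinv + t * Gm
            try:
                L = np.linalg.cholesky(Sigma)
            except np.linalg.LinAlgError:
                return 1e12
            logdet = 2.0 * np.log(np.diag(L)).sum()
            Si = np.linalg.inv(Sigma)
            XtSiX = Xw.T @ Si @ Xw
            sign, logdet_x = np.linalg.slogdet(XtSiX)
            if sign <= 0:
                return 1e12
            Pm = Si - Si @ Xw @ np.linalg.solve(XtSiX, Xw.T @ Si)
            return 0.5 * (logdet + logdet_x + z @ Pm @ z)

        opt = minimize_scalar(neg_reml, bounds=(np.log(1e-6), np.log(50.0)), method="bounded")
        tau_new = float(np.exp(opt.x))
        Sigma = Dinv + tau_new * Gm
        Si = np.linalg.inv(Sigma)
        XtSiX = Xw.T @ Si @ Xw
        beta_w = np.linalg.solve(XtSiX, Xw.T @ Si @ z)
        u_hat = tau_new * Gm @ Si @ (z - Xw @ beta_w)
        eta_new = Xw @ beta_w + u_hat
        if np.max(np.abs(eta_new - eta)) < 1e-4 and abs(tau_new - tau) < 1e-4:
            eta, tau = eta_new, tau_new
            break
        eta, tau = eta_new, tau_new
    Pm = Si - Si @ Xw @ np.linalg.solve(XtSiX, Xw.T @ Si)
    rtilde = Pm @ z
    return tau, eta, Pm, rtilde, Xw


def _saddlepoint_p(zeta: np.ndarray, probs: np.ndarray, u_obs: float) -> float:
    """Tail probability P(sum_i xi_i >= u_obs) by Barndorff-Nielsen's formula.

    ``zeta[i, c]`` is the value individual *i* contributes when its class is
    *c*; classes are multinomial with probabilities ``probs[i, c]``.
    """
    log_p = np.log(probs)

    def K(t):
        return float(np.sum(logsumexp(log_p + t * zeta, axis=1)))

    def K1K2(t):
        a = log_p + t * zeta
        mx = a.max(axis=1, keepdims=True)
        w = np.exp(a - mx)
        w /= w.sum(axis=1, keepdims=True)
        m1 = np.sum(w * zeta, axis=1)
        m2 = np.sum(w * zeta * zeta, axis=1)
        return float(m1.sum()), float(np.sum(m2 - m1 * m1))

    var0 = K1K2(0.0)[1]
    if var0 <= 0:
        return np.nan
    t = u_obs / var0
    ok = False
    for _ in range(60):
        k1, k2 = K1K2(t)
        diff = k1 - u_obs
        if abs(diff) < 1e-9 * max(1.0, abs(u_obs)):
            ok = True
            break
        if k2 <= 0:
            break
        t -= diff / k2
    if not ok:
        try:
            lo, hi = (0.0, 200.0) if u_obs > 0 else (-200.0, 0.0)
            t = brentq(lambda tt: K1K2(tt)[0] - u_obs, lo, hi, maxiter=200)
        except ValueError:
            return np.nan
    _, k2 = K1K2(t)
    arg = 2.0 * (t * u_obs - K(t))
    if arg <= 0 or k2 <= 0 or t == 0:
        return np.nan
    w = np.sign(t) * np.sqrt(arg)
    v = t * np.sqrt(k2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z_star = w + np.log(v / w) / w
    if not np.isfinite(z_star):
        return np.nan
    return float(ndtr(-z_star))


def _score_all(
    null: NullModel,
    dosages: np.ndarray,
    spa_threshold: float = SPA_SWITCH_DEFAULT,
) -> pd.DataFrame:
    """Score statistics, variances and p-values for a (n, p) dosage block."""
    Gd = np.asarray(dosages, dtype=float)
    if Gd.ndim == 1:
        Gd = Gd[:, None]
    n, p = Gd.shape
    col_sd = Gd.std(axis=0)
    mono = col_sd == 0

    if null.mode == "fixed":
        s = null.score_residuals
        U = Gd.T @ s
        I_bb = (Gd * Gd).T @ null.weights
        Q = Gd.T @ null.cross_info
        sol = np.linalg.solve(null.info_theta, Q.T).T
        var = I_bb - np.sum(sol * Q, axis=1)
    else:
        U = Gd.T @ null.working_residual
        PG = null.P @ Gd
        var = np.sum(Gd * PG, axis=0)

    var = np.where(var > 1e-12, var, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = U / np.sqrt(var)
        p_normal = chi2.sf(z * z, df=1)

    # covariate-residualized genotype feeds the per-individual CGF; the
    # variance-ratio rescaling keeps SPA and normal p consistent in the bulk
    W = null.weights
    Xp = null.X if null.X.shape[1] else np.ones((n, 1))
    if null.mode == "fixed":
        Xp = np.column_stack([np.ones(n), null.X])
    XtWX = Xp.T @ (Xp * W[:, None])
    H = np.linalg.solve(XtWX, Xp.T @ (Gd * W[:, None]))
    Gt = Gd - Xp @ H

    p_spa = p_normal.copy()
    need = np.isfinite(z) & (np.abs(z) > spa_threshold)
    for j in np.flatnonzero(need):
        zeta = Gt[:, j][:, None] * null.s_cat
        var_k = float(np.sum(null.probs * zeta * zeta))
        if var_k <= 0 or not np.isfinite(var[j]):
            continue
        u_star = abs(U[j]) * np.sqrt(var_k / var[j])
        upper = _saddlepoint_p(zeta, null.probs, u_star)
        lowr = _saddlepoint_p(-zeta, null.probs, u_star)  # lower tail via negation
        if np.isnan(upper) or np.isnan(lowr):
            continue
        p_spa[j] = min(max(upper + lowr, 5e-324), 1.0)

    out = pd.DataFrame(
        {
            "score": U,
            "variance": var,
            "p_normal": p_normal,
            "p_spa": p_spa,
            "sign": np.sign(U).astype(int),
        }
    )
    out.loc[mono, ["score", "variance", "p_normal", "p_spa"]] = np.nan
    out["reason"] = np.where(mono, "monomorphic", "")
    return out


def score_test(
    null: NullModel,
    snp_dosages,
    snp_id: str = "snp",
    chrom: str = "",
    pos: int = 0,
    threshold: float = 1e-6,
    spa_threshold: float = SPA_SWITCH_DEFAULT,
) -> ScoreTestResult:
    """Score test of one SNP against the fitted null model."""
    tab = _score_all(null, np.asarray(snp_dosages, float), spa_threshold)
    row = tab.iloc[0]
    p = row["p_spa"]
    return ScoreTestResult(
        snp_id=snp_id,
        chrom=chrom,
        pos=pos,
        score=row["score"],
        variance=row["variance"],
        p_normal=row["p_normal"],
        p_spa=row["p_spa"],
        sign=int(row["sign"]) if np.isfinite(row["score"]) else 0,
        significant=bool(p < threshold) if np.isfinite(p) else False,
        reason=row["reason"],
    )


def genome_scan(
    panel: GenotypePanel,
    null: NullModel,
    threshold: float = 1e-6,
    spa_threshold: float = SPA_SWITCH_DEFAULT,
) -> pd.DataFrame:
    """Score-test every SNP in the panel against the null model.

    Returns a Manhattan-ready table sorted by (chrom, pos) with columns
    ``chrom, pos, id, score, variance, p_normal, p_spa, p, neglog10_p,
    significant, reason``; the genomic-control lambda is logged.
    """
    if np.isnan(panel.dosages).any():
        raise ValueError("genome scan requires complete dosages; impute first")
    tab = _score_all(null, panel.dosages, spa_threshold)
    tab.insert(0, "chrom", panel.snp_map["chrom"].to_numpy())
    tab.insert(1, "pos", panel.snp_map["pos"].to_numpy())
    tab.insert(2, "id", panel.snp_map["id"].to_numpy())
    tab["p"] = tab["p_spa"]
    with np.errstate(divide="ignore"):
        tab["neglog10_p"] = -np.log10(tab["p"])
    tab["significant"] = tab["p"] < threshold
    tab = tab.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    pvals = tab["p"].dropna()
    if len(pvals):
        lam = float(np.median(chi2.isf(pvals, df=1)) / chi2.isf(0.5, df=1))
        logger.info("genome scan: %d SNPs, lambda_GC = %.3f", len(tab), lam)
    return tab


def genomic_control_lambda(p_values) -> float:
    """Median-based genomic-control inflation factor of a p-value vector."""
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    return float(np.median(chi2.isf(p, df=1)) / chi2.isf(0.5, df=1))


def candidate_gene_window(
    hits,
    genes: list[GeneRecord],
    flank_bp: int = 30_000,
) -> pd.DataFrame:
    """Genes overlapping ±``flank_bp`` (1-based inclusive) around each hit.

    ``hits`` is a DataFrame with ``chrom, pos, id`` columns (e.g. significant
    rows of :func:`genome_scan`) or a list of :class:`ScoreTestResult`.
    Distance is from the SNP to the nearest gene edge, 0 when the SNP lies
    inside the gene.
    """
    if isinstance(hits, pd.DataFrame):
        records = hits[["chrom", "pos", "id"]].to_dict("records")
        records = [(r["chrom"], int(r["pos"]), r["id"]) for r in records]
    else:
        records = [(h.chrom, int(h.pos), h.snp_id) for h in hits]
    gene_chroms = {g.chrom for g in genes}
    rows = []
    for chrom, pos, snp_id in records:
        if chrom not in gene_chroms:
            warnings.warn(
                f"hit {snp_id}: chromosome {chrom!r} absent from the annotation; skipped",
                stacklevel=2,
            )
            continue
        lo, hi = pos - flank_bp, pos + flank_bp
        for gene in genes:
            if gene.chrom != chrom or gene.end < lo or gene.start > hi:
                continue
            if gene.start <= pos <= gene.end:
                dist = 0
            else:
                dist = min(abs(pos - gene.start), abs(pos - gene.end))
            rows.append(
                {
                    "snp_id": snp_id,
                    "chrom": chrom,
                    "pos": pos,
                    "gene_id": gene.gene_id,
                    "gene_start": gene.start,
                    "gene_end": gene.end,
                    "strand": gene.strand,
                    "distance": dist,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "snp_id", "chrom", "pos", "gene_id", "gene_start", "gene_end", "strand", "distance",
        ],
    )
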