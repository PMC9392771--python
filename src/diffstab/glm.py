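"""Negative-binomial GLM machinery: size factors, likelihoods, batched IRLS.

All genes in a dataset share one design matrix and one offset vector (the log
size factors), so fitting is vectorized across genes: a single Fisher-scoring
iteration solves one small weighted least-squares system per gene via batched
``numpy.linalg.solve``. The NB parameterization is mean/dispersion with
``Var = mu + alpha * mu**2``; ``alpha = 0`` is the Poisson limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

ALPHA_MIN = 1e-8
ALPHA_MAX = 10.0
_POISSON_EPS = 1e-10  # below this, alpha is treated as exactly Poisson

MU_FLOOR = 1e-10
MU_CEIL = 1e12


# ---------------------------------------------------------------------------
# size factors

def median_of_ratios(matrix: np.ndarray) -> np.ndarray:
    """DESeq-style median-of-ratios size factors, one per column.

    The reference is the per-gene geometric mean over all columns, restricted
    to genes with no zero count; each column's factor is the median ratio of
    its counts to the reference. Columns with no usable gene fall back to the
    genes positive in that column, with a warning.
    """
    m = np.asarray(matrix, dtype=float)
    with np.errstate(divide="ignore"):
        logm = np.log(m)
    allpos = np.all(m > 0, axis=1)
    factors = np.empty(m.shape[1])
    if allpos.any():
        ref = logm[allpos].mean(axis=1)
        factors = np.exp(np.median(logm[allpos] - ref[:, None], axis=0))
    else:
        import logging

        logging.getLogger(__name__).warning(
            "no gene has positive counts in every pseudo-library; "
            "falling back to per-column positive genes"
        )
        ref = np.where(
            (m > 0).sum(axis=1) > 0,
            np.nanmean(np.where(m > 0, logm, np.nan), axis=1),
            0.0,
        )
        for j in range(m.shape[1]):
            pos = m[:, j] > 0
            if not pos.any():
                raise ValueError(f"pseudo-library {j} has no positive counts")
            factors[j] = np.exp(np.median(logm[pos, j] - ref[pos]))
    return factors


def estimate_size_factors(stacked) -> np.ndarray:
    """Size factors for the stacked gene x 2n matrix.

    Each (sample, feature-type) pair is its own pseudo-library; after the
    median-of-ratios step the factors are renormalized to geometric mean 1
    within the intronic block and within the exonic block separately, so the
    intronic/exonic scale difference is absorbed by the model's gene-level
    intercepts rather than the offsets.
    """
    matrix = stacked.matrix if hasattr(stacked, "matrix") else np.asarray(stacked)
    s = median_of_ratios(matrix)
    n = matrix.shape[1] // 2
    for block in (slice(0, n), slice(n, 2 * n)):
        s[block] /= np.exp(np.mean(np.log(s[block])))
    return s


# ---------------------------------------------------------------------------
# likelihood

def nb_log_likelihood(y, mu, alpha) -> np.ndarray:
    """Sum of NB log-pmf over the trailing axis; Poisson at ``alpha = 0``.

    ``y`` and ``mu`` broadcast; ``alpha`` may be scalar or per-row.
    """
    y = np.asarray(y, dtype=float)
    mu = np.clip(np.asarray(mu, dtype=float), MU_FLOOR, MU_CEIL)
    alpha = np.asarray(alpha, dtype=float)
    if alpha.ndim and y.ndim > 1:
        alpha = alpha[:, None]
    pois = y * np.log(mu) - mu - gammaln(y + 1)
    if np.all(alpha <= _POISSON_EPS):
        return pois.sum(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        k = 1.0 / np.maximum(alpha, _POISSON_EPS)
        nb = (
            gammaln(y + k)
            - gammaln(k)
            - gammaln(y + 1)
            + k * np.log(k / (k + mu))
            + y * np.log(mu / (k + mu))
        )
    out = np.where(alpha <= _POISSON_EPS, pois, nb)
    return out.sum(axis=-1)


def _weights(mu, alpha):
    """Fisher-scoring working weights for the log link: mu / (1 + alpha mu)."""
    return mu / (1.0 + alpha * mu)


# ---------------------------------------------------------------------------
# batched IRLS

@dataclass
class BatchFit:
    """Per-gene NB-GLM fits against a shared design.

    Attributes
    ----------
    coefficients : (G, p) natural-log-scale coefficient estimates.
    standard_errors : (G, p) from the inverse observed Fisher information.
    log_likelihood : (G,) NB log-likelihood at the optimum.
    fitted_means : (G, N) ``exp(design @ beta + offset)``.
    alpha : (G,) dispersions used.
    converged : (G,) bool.
    iterations : (G,) int.
    """

    coefficients: np.ndarray
    standard_errors: np.ndarray
    log_likelihood: np.ndarray
    fitted_means: np.ndarray
    alpha: np.ndarray
    converged: np.ndarray
    iterations: np.ndarray


def fit_genes(
    Y: np.ndarray,
    design: np.ndarray,
    offset: np.ndarray | None = None,
    alpha=0.0,
    beta0: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
    compute_se: bool = True,
) -> BatchFit:
    """Fit one NB GLM per row of ``Y`` against a shared design matrix.

    Fisher scoring with per-gene step halving on log-likelihood decrease;
    convergence when the relative log-likelihood change drops below ``tol``.
    ``offset`` is the log size-factor vector (length N). ``alpha`` is a scalar
    or per-gene dispersion vector held fixed during the fit.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    G, N = Y.shape
    A = np.asarray(design, dtype=float)
    p = A.shape[1]
    if A.shape[0] != N:
        raise ValueError(f"design has {A.shape[0]} rows but counts have {N} columns")
    if N - p < 0:
        raise ValueError("more coefficients than observations")
    if np.linalg.matrix_rank(A) < p:
        raise ValueError("design matrix is rank-deficient")
    off = np.zeros(N) if offset is None else np.asarray(offset, dtype=float)
    al = np.broadcast_to(np.asarray(alpha, dtype=float), (G,)).copy()
    al2 = al[:, None]

    if beta0 is not None:
        beta = np.array(beta0, dtype=float, copy=True)
        eta = beta @ A.T + off
    else:
        # moment start: regress log(y + 0.5) - offset on the design
        z0 = np.log(Y + 0.5) - off
        beta, *_ = np.linalg.lstsq(A, z0.T, rcond=None)
        beta = beta.T
        eta = beta @ A.T + off
    mu = np.clip(np.exp(np.clip(eta, -500, 500)), MU_FLOOR, MU_CEIL)
    ll = nb_log_likelihood(Y, mu, al)

    converged = np.zeros(G, dtype=bool)
    iters = np.zeros(G, dtype=int)
    ridge = 1e-10 * np.eye(p)
    active = np.arange(G)

    for it in range(max_iter):
        if active.size == 0:
            break
        Ya, mua, etaa = Y[active], mu[active], eta[active]
        ala, al2a, lla = al[active], al2[active], ll[active]
        betaa = beta[active]
        W = _weights(mua, al2a)
        z = (etaa - off) + (Ya - mua) / mua
        XtWX = np.einsum("ni,gn,nj->gij", A, W, A, optimize=True)
        XtWz = np.einsum("ni,gn,gn->gi", A, W, z, optimize=True)
        try:
            beta_new = np.linalg.solve(XtWX + ridge, XtWz[..., None])[..., 0]
        except np.linalg.LinAlgError:
            beta_new = np.stack(
                [np.linalg.lstsq(XtWX[g], XtWz[g], rcond=None)[0]
                 for g in range(len(active))]
            )
        # per-gene step halving on log-likelihood decrease
        step = np.ones((len(active), 1))
        delta = beta_new - betaa
        for _ in range(12):
            cand = betaa + step * delta
            eta_c = np.clip(cand @ A.T + off, -500, 500)
            mu_c = np.clip(np.exp(eta_c), MU_FLOOR, MU_CEIL)
            ll_c = nb_log_likelihood(Ya, mu_c, ala)
            worse = (ll_c < lla - 1e-12) & (step[:, 0] > 1e-6)
            if not worse.any():
                break
            step[worse] *= 0.5
        upd = ll_c >= lla - 1e-10
        rel = np.abs(ll_c - lla) / (np.abs(lla) + 0.1)
        small_move = np.max(np.abs(step * delta), axis=1) < 1e-10
        betaa = np.where(upd[:, None], cand, betaa)
        beta[active] = betaa
        eta[active] = np.clip(betaa @ A.T + off, -500, 500)
        mu[active] = np.clip(np.exp(eta[active]), MU_FLOOR, MU_CEIL)
        ll[active] = np.where(upd, ll_c, lla)
        iters[active] = it + 1
        done = (upd & (rel < tol)) | small_move
        converged[active[done]] = True
        active = active[~done]

    se = np.full((G, p), np.nan)
    if compute_se:
        se = _observed_info_se(Y, mu, al2, A, ridge)
    return BatchFit(
        coefficients=beta,
        standard_errors=se,
        log_likelihood=ll,
        fitted_means=mu,
        alpha=al,
        converged=converged,
        iterations=iters,
    )


def _observed_info_se(Y, mu, al2, A, ridge):
    """SEs from the observed Fisher information of the log-link NB model.

    The per-observation curvature is ``(y + k) mu k / (k + mu)^2`` with
    ``k = 1/alpha``; at ``y = mu`` it reduces to the expected information
    weight ``mu / (1 + alpha mu)``. Falls back to the expected information
    when the observed matrix is not positive definite for a gene.
    """
    with np.errstate(divide="ignore", over="ignore"):
        k = 1.0 / np.maximum(al2, _POISSON_EPS)
        w_obs = np.where(
            al2 <= _POISSON_EPS, mu, (Y + k) * mu * k / (k + mu) ** 2
        )
    info = np.einsum("ni,gn,nj->gij", A, w_obs, A, optimize=True) + ridge
    G, p = info.shape[0], info.shape[1]
    se = np.empty((G, p))
    try:
        cov = np.linalg.inv(info)
        diag = np.einsum("gii->gi", cov)
    except np.linalg.LinAlgError:
        diag = np.full((G, p), -1.0)
    bad = np.any(diag <= 0, axis=1) | ~np.all(np.isfinite(diag), axis=1)
    se[~bad] = np.sqrt(diag[~bad])
    if bad.any():
        w_exp = _weights(mu, al2)
        info_e = np.einsum("ni,gn,nj->gij", A, w_exp, A, optimize=True) + ridge
        for g in np.where(bad)[0]:
            se[g] = np.sqrt(np.abs(np.diag(np.linalg.pinv(info_e[g]))))
    return se


# ---------------------------------------------------------------------------
# dispersion estimation

_ALPHA_GRID = np.concatenate([[ALPHA_MIN], np.geomspace(1e-4, ALPHA_MAX, 27)])


def profile_dispersion_grid(
    Y, design, offset=None, grid: np.ndarray = _ALPHA_GRID
) -> tuple[np.ndarray, np.ndarray]:
    """Profile log-likelihood over a shared dispersion grid, batched.

    Returns ``(alpha_hat, ll_at_hat)`` with each gene's grid argmax. The
    coefficients are refit at every grid point (true profile likelihood).
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    G = Y.shape[0]
    lls = np.empty((len(grid), G))
    beta = None
    for i, a in enumerate(grid):
        fit = fit_genes(Y, design, offset, alpha=a, beta0=beta, compute_se=False)
        beta = fit.coefficients
        lls[i] = fit.log_likelihood
    best = np.argmax(lls, axis=0)
    return grid[best], lls[best, np.arange(G)]


def estimate_dispersion(
    Y, design, offset=None, grid: np.ndarray = _ALPHA_GRID,
    refine_iter: int = 12, df_correction: bool = True
) -> np.ndarray:
    """Per-gene profile-MLE dispersion, clamped to [1e-8, 10].

    A coarse geometric grid brackets each gene's optimum; a batched
    golden-section search on log-alpha then refines it. Falls back to
    method-of-moments for genes where the profile is degenerate (all-zero
    counts).

    The raw profile MLE of a variance-type parameter is biased low by a
    factor of roughly (N - p)/N because the fitted mean absorbs p degrees of
    freedom; with ``df_correction`` (default) the estimate is rescaled by
    N/(N - p) — the NB analogue of the ddof correction in a sample variance —
    which restores calibrated Wald inference downstream. Set it to False for
    the uncorrected maximum-likelihood value.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    G, N = Y.shape
    p = np.asarray(design).shape[1]
    if N - p < 1:
        raise ValueError("no residual degrees of freedom for dispersion estimation")
    lls = np.empty((len(grid), G))
    beta = None
    for i, a in enumerate(grid):
        fit = fit_genes(Y, design, offset, alpha=a, beta0=beta, compute_se=False)
        beta = fit.coefficients
        lls[i] = fit.log_likelihood
    best = np.argmax(lls, axis=0)

    lo_i = np.maximum(best - 1, 0)
    hi_i = np.minimum(best + 1, len(grid) - 1)
    lo = np.log(grid[lo_i])
    hi = np.log(grid[hi_i])

    gr = (np.sqrt(5.0) - 1.0) / 2.0
    x1 = hi - gr * (hi - lo)
    x2 = lo + gr * (hi - lo)
    f1, beta = _profile_ll_at(Y, design, offset, np.exp(x1), beta)
    f2, beta = _profile_ll_at(Y, design, offset, np.exp(x2), beta)
    for _ in range(refine_iter):
        take1 = f1 >= f2  # keep the higher-likelihood bracket
        hi = np.where(take1, x2, hi)
        lo = np.where(take1, lo, x1)
        x1 = hi - gr * (hi - lo)
        x2 = lo + gr * (hi - lo)
        f1, beta = _profile_ll_at(Y, design, offset, np.exp(x1), beta)
        f2, beta = _profile_ll_at(Y, design, offset, np.exp(x2), beta)
    alpha = np.exp((lo + hi) / 2.0)
    if df_correction:
        alpha = alpha * (N / (N - p))
    alpha = np.clip(alpha, ALPHA_MIN, ALPHA_MAX)
    # degenerate profiles (e.g. all-zero genes): method-of-moments fallback
    flat = np.ptp(lls, axis=0) < 1e-12
    if flat.any():
        alpha[flat] = _moments_alpha(Y[flat])
    return alpha


def _profile_ll_at(Y, design, offset, alpha_vec, beta0=None):
    fit = fit_genes(Y, design, offset, alpha=alpha_vec, beta0=beta0,
                    compute_se=False)
    return fit.log_likelihood, fit.coefficients


def _moments_alpha(Y):
    m = Y.mean(axis=1)
    v = Y.var(axis=1, ddof=1) if Y.shape[1] > 1 else np.zeros(Y.shape[0])
    with np.errstate(divide="ignore", invalid="ignore"):
        a = (v - m) / np.maximum(m, MU_FLOOR) ** 2
    return np.clip(np.nan_to_num(a, nan=ALPHA_MIN), ALPHA_MIN, ALPHA_MAX)


# ---------------------------------------------------------------------------
# inference helpers

def wald_test(coefficients, standard_errors):
    """Two-sided Wald z-test per coefficient; returns (statistic, p)."""
    coef = np.asarray(coefficients, dtype=float)
    se = np.asarray(standard_errors, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = coef / se
    pval = 2.0 * norm.sf(np.abs(stat))
    pval = np.where(np.isfinite(stat), pval, np.nan)
    return stat, pval


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini–Hochberg q-values; missing p-values stay missing and are
    excluded from the number of tests."""
    p = np.asarray(p_values, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q
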