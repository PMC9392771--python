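"""Synthetic data generators with known ground truth.

Every generator follows the same generative chain the stability model
inverts: per-gene latent pre-mRNA abundance ``p`` across samples, a
power-law-coupled mature abundance ``m = p**b * phi * gamma`` with
``log gamma = X @ beta``, and observed intronic/exonic counts drawn NB with
means ``p * l * s_int`` and ``m * l' * s_exo`` (gene-length factors ``l``,
``l'``; per-pseudo-library size factors ``s``). Generators are pure functions
of their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import StabilityDataset
from .design import CovariateMatrix


@dataclass
class SimulationTruth:
    """Latent generative quantities behind a simulated dataset.

    Shapes: per-gene-per-sample arrays are (G, n); per-gene arrays (G,);
    per-gene-per-covariate arrays (G, k); size factors length n each.
    """

    p: np.ndarray            # pre-mRNA abundance
    m: np.ndarray            # mature mRNA abundance
    gamma: np.ndarray        # stability (natural scale)
    phi: np.ndarray          # processing capacity (stability intercept absorbed)
    l: np.ndarray            # intronic length factor
    l_prime: np.ndarray      # exonic length factor
    beta: np.ndarray         # true stability coefficients (natural log)
    omega: np.ndarray        # true pre-mRNA covariate effects (natural log)
    rho: np.ndarray          # per-gene baseline log pre-mRNA abundance
    alpha: np.ndarray        # true NB dispersion per gene
    b: float                 # transcription-processing coupling exponent
    s_int: np.ndarray        # intronic size factors
    s_exo: np.ndarray        # exonic size factors


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Gamma-Poisson NB draw with Var = mu + alpha mu^2; Poisson at alpha ~ 0."""
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float)[:, None], mean.shape)
    out = np.empty(mean.shape, dtype=np.int64)
    pois = alpha < 1e-12
    if pois.any():
        out[pois] = rng.poisson(mean[pois])
    if (~pois).any():
        lam = rng.gamma(shape=1.0 / alpha[~pois], scale=alpha[~pois] * mean[~pois])
        out[~pois] = rng.poisson(lam)
    return out


def simulate_stability_dataset(
    n_genes: int,
    X: CovariateMatrix,
    b: float = 1.0,
    beta_sd: float = 0.5,
    dispersion=0.1,
    libsize_range: tuple[float, float] = (0.5, 2.0),
    seed: int = 0,
    logp_mean: float = 4.0,
    logp_sd: float = 1.5,
    omega_sd: float = 0.5,
    logphi_sd: float = 0.5,
    length_sd: float = 0.5,
    gamma_shift=None,
    logp_shift=None,
) -> tuple[StabilityDataset, SimulationTruth]:
    """Simulate intronic/exonic counts for ``n_genes`` genes over ``X``'s samples.

    Per gene g: baseline ``rho_g ~ N(logp_mean, logp_sd^2)``, covariate
    effects ``omega_g ~ N(0, omega_sd^2)`` give ``log p = rho_g + X omega_g``;
    stability effects ``beta_g ~ N(0, beta_sd^2)`` give ``log gamma = X
    beta_g``; ``log phi_g ~ N(0, logphi_sd^2)``; length factors LogNormal(0,
    ``length_sd``); ``dispersion`` is a scalar, a length-G vector, or a
    callable ``rng -> (G,) array``. Size factors are drawn uniformly on
    ``libsize_range`` per pseudo-library.

    ``gamma_shift`` / ``logp_shift`` (optional, length-n arrays on the
    natural-log scale) add sample-wise offsets to ``log gamma`` / ``log p``
    outside the covariate model — used for perturbation experiments.
    """
    if not 0.0 <= b <= 1.0:
        raise ValueError("b must lie in [0, 1]")
    if beta_sd < 0 or logp_sd < 0:
        raise ValueError("standard deviations must be non-negative")
    rng = np.random.default_rng(seed)
    n, k = X.n, X.k
    G = int(n_genes)

    rho = rng.normal(logp_mean, logp_sd, size=G)
    omega = rng.normal(0.0, omega_sd, size=(G, k))
    beta = rng.normal(0.0, beta_sd, size=(G, k)) if beta_sd > 0 else np.zeros((G, k))
    logphi = rng.normal(0.0, logphi_sd, size=G)
    l = rng.lognormal(0.0, length_sd, size=G)
    l_prime = rng.lognormal(0.0, length_sd, size=G)
    if callable(dispersion):
        alpha = np.asarray(dispersion(rng), dtype=float)
    else:
        alpha = np.broadcast_to(np.asarray(dispersion, dtype=float), (G,)).copy()
    s_int = rng.uniform(*libsize_range, size=n)
    s_exo = rng.uniform(*libsize_range, size=n)

    logp = rho[:, None] + omega @ X.X.T
    if logp_shift is not None:
        logp = logp + np.asarray(logp_shift, dtype=float)[None, :]
    loggamma = beta @ X.X.T
    if gamma_shift is not None:
        loggamma = loggamma + np.asarray(gamma_shift, dtype=float)[None, :]
    p = np.exp(logp)
    gamma = np.exp(loggamma)
    phi = np.exp(logphi)
    m = p**b * phi[:, None] * gamma

    lam_int = p * l[:, None] * s_int[None, :]
    lam_exo = m * l_prime[:, None] * s_exo[None, :]
    intronic = _nb_draw(rng, lam_int, alpha)
    exonic = _nb_draw(rng, lam_exo, alpha)

    dataset = StabilityDataset(
        gene_ids=[f"gene{i:05d}" for i in range(G)],
        exonic_counts=exonic,
        intronic_counts=intronic,
        sample_ids=[f"sample{j:02d}" for j in range(n)],
    )
    truth = SimulationTruth(
        p=p, m=m, gamma=gamma, phi=phi, l=l, l_prime=l_prime,
        beta=beta, omega=omega, rho=rho, alpha=alpha, b=float(b),
        s_int=s_int, s_exo=s_exo,
    )
    return dataset, truth


def simulate_transcription_only(
    n_genes: int,
    X: CovariateMatrix,
    b: float = 1.0,
    fold_change_p: float = 4.0,
    seed: int = 0,
    **kwargs,
) -> tuple[StabilityDataset, SimulationTruth]:
    """Perturb transcription only: shift pre-mRNA abundance, keep stability flat.

    Pre-mRNA abundance is multiplied by ``fold_change_p`` wherever the first
    covariate equals 1, while ``gamma`` stays constant across samples (all
    true ``beta = 0``). At ``b = 1`` the exon/intron ratio is unchanged by
    construction, so a correct stability model must call every gene null.
    """
    if fold_change_p <= 0:
        raise ValueError("fold_change_p must be positive")
    shift = np.log(fold_change_p) * X.X[:, 0]
    return simulate_stability_dataset(
        n_genes, X, b=b, beta_sd=0.0, seed=seed, logp_shift=shift, **kwargs
    )


def simulate_timecourse(
    n_genes: int,
    halflife_mean: float = 4.0,
    halflife_sd: float = 0.5,
    diff_halflife_sd: float = 0.3,
    halflife_ratio: float = 1.0,
    timepoints=(0.0, 2.0, 4.0, 8.0, 16.0),
    replicates: int = 2,
    dispersion: float = 0.05,
    log_level_mean: float = 6.0,
    log_level_sd: float = 1.0,
    seed: int = 0,
):
    """Simulate a transcription-chase decay time-course in two cell lines.

    Per gene, labelled-RNA abundance decays exponentially from a time-zero
    level at rate ``ln 2 / halflife``; cell line 0 half-lives are
    LogNormal(log ``halflife_mean``, ``halflife_sd``), and line 1 half-lives
    differ by a fixed factor ``halflife_ratio`` times a LogNormal factor of
    SD ``diff_halflife_sd``. Counts are NB
    around the decayed means. Returns ``(counts (G, n), cell, time, truth)``
    where ``truth['diff_rate']`` is the true ``cell:time`` interaction
    coefficient ``ln2/h0 - ln2/h1`` (per hour, natural log).
    """
    timepoints = np.asarray(timepoints, dtype=float)
    if len(timepoints) < 2:
        raise ValueError("need at least two time points")
    if halflife_mean <= 0:
        raise ValueError("half-lives must be positive")
    rng = np.random.default_rng(seed)
    G = int(n_genes)
    h0 = rng.lognormal(np.log(halflife_mean), halflife_sd, size=G)
    h1 = h0 * halflife_ratio * rng.lognormal(0.0, diff_halflife_sd, size=G)
    a0 = rng.lognormal(log_level_mean, log_level_sd, size=G)
    a1 = a0 * rng.lognormal(0.0, 0.3, size=G)

    cell = np.repeat([0.0, 1.0], len(timepoints) * replicates)
    time = np.tile(np.repeat(timepoints, replicates), 2)
    rate = np.where(cell[None, :] == 0, (np.log(2) / h0)[:, None],
                    (np.log(2) / h1)[:, None])
    level = np.where(cell[None, :] == 0, a0[:, None], a1[:, None])
    mean = level * np.exp(-rate * time[None, :])
    counts = _nb_draw(rng, mean, np.full(G, dispersion))
    truth = {
        "halflife_0": h0,
        "halflife_1": h1,
        "diff_rate": np.log(2) / h0 - np.log(2) / h1,
        "level_0": a0,
        "level_1": a1,
        "dispersion": np.full(G, dispersion),
    }
    return counts, cell, time, truth


def simulate_regulon(
    n_genes: int,
    n_factors: int = 1,
    focal_odds_ratio: float = 2.0,
    status_proportions=(0.1, 0.8, 0.1),
    mean_total_sites: float = 20.0,
    baseline_prob: float = 0.10,
    seed: int = 0,
):
    """Simulate per-gene binding-site totals, focal-factor successes and status.

    Status is drawn from {-1, 0, +1} with the given proportions; totals are
    Poisson(``mean_total_sites``) + 1; focal successes are Binomial(total,
    pi_status) with ``logit(pi) = logit(baseline_prob) +
    log(focal_odds_ratio) * status``. With ``n_factors > 1`` the non-focal
    factors split the failures uniformly. Returns ``(site_counts (G, F),
    status (G,), truth)``; factor 0 is the focal factor.
    """
    props = np.asarray(status_proportions, dtype=float)
    if props.min() < 0 or abs(props.sum() - 1.0) > 1e-9:
        raise ValueError("status proportions must be non-negative and sum to 1")
    if focal_odds_ratio <= 0:
        raise ValueError("odds ratio must be positive")
    rng = np.random.default_rng(seed)
    G = int(n_genes)
    status = rng.choice([-1, 0, 1], size=G, p=props)
    totals = rng.poisson(mean_total_sites, size=G) + 1
    logit0 = np.log(baseline_prob / (1 - baseline_prob))
    logit = logit0 + np.log(focal_odds_ratio) * status
    pi = 1.0 / (1.0 + np.exp(-logit))
    focal = rng.binomial(totals, pi)
    counts = np.zeros((G, max(int(n_factors), 1)), dtype=np.int64)
    counts[:, 0] = focal
    rest = totals - focal
    if counts.shape[1] > 1:
        share = np.ones(counts.shape[1] - 1) / (counts.shape[1] - 1)
        counts[:, 1:] = rng.multinomial(rest, share)
    truth = {
        "log_odds_ratio": np.log(focal_odds_ratio),
        "baseline_prob": baseline_prob,
        "totals": totals,
    }
    return counts, status, truth
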