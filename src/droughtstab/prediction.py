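"""Genomic prediction: single-trait GBLUP (REML) and the Bayesian multi-trait model.

The single-trait model is y_i = mu + u_i + e_i with u ~ MVN(0, G sigma_g^2) and
e ~ MVN(0, I sigma_e^2); variance components are estimated by REML on a 1-D
profile over the variance ratio after an eigendecomposition of G (EMMA-style),
and genomic heritability is h^2 = sigma_g^2 / (sigma_g^2 + sigma_e^2).

The multi-trait model (MTM) stacks the target trait (the stability CV) with M
secondary traits (RRM coefficients L0..Lnr or raw per-date VI values):
y_im = mu_m + u_im + e_im, u ~ MVN(0, Sigma kron G), e ~ MVN(0, R kron I).
It is fitted by Gibbs sampling with inverse-Wishart full conditionals for
Sigma and R and data augmentation for missing phenotypes, which is what lets
test genotypes carry secondary traits while their CV is masked.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from droughtstab.genomics import RelationshipMatrix

__all__ = [
    "GBLUPFit",
    "MTMFit",
    "GibbsConfig",
    "fit_gblup",
    "fit_mtm",
    "genetic_correlation",
    "predict_target",
]

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class GBLUPFit:
    """REML variance components, heritability and genetic-value BLUPs."""

    mu: float
    sigma_g2: float
    sigma_e2: float
    h2: float
    u: pd.Series
    reml_loglik: float
    converged: bool = True


@dataclass
class GibbsConfig:
    """Gibbs chain settings for the multi-trait model."""

    n_iter: int = 12_000
    burn_in: int = 2_000
    thin: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iter <= self.burn_in:
            raise ValueError("chain length must exceed burn_in")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class MTMFit:
    """Posterior means from the multi-trait Gibbs sampler.

    Trait 0 is always the prediction target. ``chain`` carries the sampler
    settings and effective sample sizes of the variance components.
    """

    trait_names: list[str]
    Sigma: np.ndarray
    R: np.ndarray
    mu: np.ndarray
    U: pd.DataFrame
    chain: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# single-trait GBLUP


def _profile_reml(delta_log: float, d: np.ndarray, yr: np.ndarray, xr: np.ndarray) -> tuple[float, float, float]:
    """Profiled REML at ratio delta = sigma_e^2 / sigma_g^2 on the rotated data.

    Returns (negative loglik, sigma_g^2, mu) at this delta.
    """
    delta = np.exp(delta_log)
    w = d + delta
    xwx = float(np.sum(xr * xr / w))
    xwy = float(np.sum(xr * yr / w))
    mu = xwy / xwx
    r = yr - mu * xr
    quad = float(np.sum(r * r / w))
    n = len(yr)
    sg2 = quad / (n - 1)
    ll = -0.5 * (
        (n - 1) * np.log(sg2)
        + np.sum(np.log(w))
        + np.log(xwx)
        + (n - 1)
        + (n - 1) * _LOG2PI
    )
    return -float(ll), float(sg2), float(mu)


def fit_gblup(y: pd.Series, G: RelationshipMatrix, method: str = "reml") -> GBLUPFit:
    """Fit y = mu + u + e with u ~ MVN(0, G sigma_g^2) by spectral REML.

    Only the 1-D ratio lambda = sigma_e^2 / sigma_g^2 needs numerical search
    (bracketed on log lambda in [-10, 10]); sigma_g^2 and mu come in closed
    form at each lambda. Genetic values are BLUPs for every genotype in G,
    including those with missing phenotype, via the cross-covariance block.
    """
    if method != "reml":
        raise ValueError("only method='reml' is implemented")
    ids_all = G.genotype_ids
    y = y.reindex(ids_all)
    obs = y.notna().to_numpy()
    if obs.sum() < 10:
        raise ValueError("need >= 10 non-missing records")
    y_obs = y.to_numpy(dtype=float)[obs]

    G_oo = G.values[np.ix_(obs, obs)]
    d, V = np.linalg.eigh(G_oo)
    d = np.clip(d, 0.0, None)
    yr = V.T @ y_obs
    xr = V.T @ np.ones(obs.sum())

    if float(np.var(y_obs)) < 1e-14:
        # degenerate: no phenotypic variance at all
        u = pd.Series(np.zeros(len(ids_all)), index=ids_all, name="u")
        return GBLUPFit(mu=float(y_obs.mean()), sigma_g2=0.0, sigma_e2=0.0, h2=0.0,
                        u=u, reml_loglik=np.inf, converged=True)

    # coarse grid then local refinement: the profile can be multimodal-ish
    grid = np.linspace(-10.0, 10.0, 41)
    vals = [_profile_reml(g, d, yr, xr)[0] for g in grid]
    g0 = grid[int(np.argmin(vals))]
    res = optimize.minimize_scalar(
        lambda g: _profile_reml(g, d, yr, xr)[0],
        bounds=(max(g0 - 1.0, -10.0), min(g0 + 1.0, 10.0)),
        method="bounded",
        options={"xatol": 1e-8},
    )
    neg_ll, sg2, mu = _profile_reml(res.x, d, yr, xr)
    delta = float(np.exp(res.x))
    se2 = sg2 * delta
    # boundary handling: ratio pinned at the search bound collapses a component
    if res.x >= 10.0 - 1e-6:
        sg2 = 0.0
    h2 = sg2 / (sg2 + se2) if (sg2 + se2) > 0 else 0.0

    # BLUP of u for all genotypes: u_hat = sg2 * G[:, obs] V_obs^-1 (y - mu)
    Vinv_r = V @ ((yr - mu * xr) / (d + delta))  # (sg2*(G+delta I))^-1 scaled by sg2 below
    u_all = G.values[:, obs] @ Vinv_r  # sg2 cancels: sg2 * G (sg2 (G + delta I))^-1 = G (G+delta I)^-1
    if sg2 == 0.0:
        u_all = np.zeros(len(ids_all))
    u = pd.Series(u_all, index=ids_all, name="u")
    return GBLUPFit(mu=mu, sigma_g2=float(sg2), sigma_e2=float(se2), h2=float(h2),
                    u=u, reml_loglik=-neg_ll, converged=bool(res.success))


# ---------------------------------------------------------------------------
# multi-trait Gibbs sampler


def _ess(x: np.ndarray) -> float:
    """Effective sample size from the initial-positive-sequence autocorrelation sum."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 4 or np.var(x) < 1e-300:
        return float(n)
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[n - 1:] / (np.arange(n, 0, -1) * np.var(x))
    s = 0.0
    for k in range(1, n // 2):
        if acf[k] <= 0:
            break
        s += acf[k]
    return float(n / (1.0 + 2.0 * s))


def fit_mtm(
    Y: pd.DataFrame,
    G: RelationshipMatrix,
    gibbs: GibbsConfig | None = None,
    fix_sigma: np.ndarray | None = None,
    fix_r: np.ndarray | None = None,
) -> MTMFit:
    """Gibbs sampler for the multi-trait genomic model.

    Each sweep (i) samples the genetic values U given (Sigma, R) in the
    eigenbasis of G — there the N x (M+1) conditional factorizes into
    independent rows, and a generalized eigendecomposition of (Sigma, R)
    diagonalizes each row, so the update is fully vectorized; (ii) samples
    missing phenotype cells from their conditional normal given U and R
    (data augmentation); (iii) samples trait means mu (flat prior); and
    (iv) draws Sigma and R from inverse-Wishart full conditionals with
    weakly-informative priors (nu0 = n_traits + 2, scale = diag of half the
    phenotypic variances, so the prior mean sits at half the phenotypic
    variance). ``fix_sigma`` / ``fix_r`` freeze a matrix instead of sampling
    it (degenerate prior), which is useful for validation against the
    closed-form BLUP.

    Near-zero eigenvalues of G are floored at 1e-8 so that the Sigma
    conditional (which needs G^-1) is defined.
    """
    gibbs = gibbs or GibbsConfig()
    rng = np.random.default_rng(gibbs.seed)
    ids = list(Y.index)
    if set(ids) - set(G.genotype_ids):
        raise ValueError("G does not cover all genotypes in Y")
    Gm = G.subset(ids).values
    n, p = Y.shape
    trait_names = [str(c) for c in Y.columns]

    d, Ug = np.linalg.eigh(Gm)
    if d.min() < -1e-8:
        raise ValueError("G is not positive semidefinite")
    d = np.clip(d, 1e-8, None)

    Yv = Y.to_numpy(dtype=float)
    obs = ~np.isnan(Yv)
    if not obs.any(axis=0).all():
        raise ValueError("every trait needs at least one observed value")
    col_var = np.array([np.nanvar(Yv[:, j]) for j in range(p)])
    col_var = np.maximum(col_var, 1e-8)
    col_mean = np.nanmean(Yv, axis=0)

    # missingness patterns (tuple of observed column indices -> row indices)
    patterns: dict[tuple[int, ...], np.ndarray] = {}
    for i in range(n):
        key = tuple(np.nonzero(obs[i])[0])
        patterns.setdefault(key, []).append(i)
    patterns = {k: np.asarray(v) for k, v in patterns.items()}

    nu0 = p + 2
    S0 = np.diag(0.5 * col_var)

    Sigma = np.diag(0.5 * col_var) if fix_sigma is None else np.asarray(fix_sigma, dtype=float)
    R = np.diag(0.5 * col_var) if fix_r is None else np.asarray(fix_r, dtype=float)
    mu = col_mean.copy()
    Yc = np.where(obs, Yv, col_mean)  # complete-data matrix, missing cells imputed
    Ut = np.zeros((n, p))  # genetic values in the eigenbasis of G

    keep_idx = range(gibbs.burn_in, gibbs.n_iter, gibbs.thin)
    n_keep = len(list(keep_idx))
    sum_U = np.zeros((n, p))
    sum_Sigma = np.zeros((p, p))
    sum_R = np.zeros((p, p))
    sum_mu = np.zeros(p)
    draws_sig = np.empty((n_keep, p))
    draws_r = np.empty((n_keep, p))
    kept = 0

    for it in range(gibbs.n_iter):
        # --- (i) genetic values
        lam, W = linalg.eigh(Sigma, R)  # W' Sigma W = diag(lam), W' R W = I
        lam = np.clip(lam, 1e-12, None)
        RW = R @ W  # (W')^{-1}
        Yt = Ug.T @ (Yc - mu)  # rotated, centred data; rows independent
        A = Yt @ W
        prior = d[:, None] * lam[None, :]
        post_var = prior / (1.0 + prior)
        post_mean = post_var * A
        alpha = post_mean + np.sqrt(post_var) * rng.standard_normal((n, p))
        Ut = alpha @ RW.T
        U = Ug @ Ut

        # --- (ii) missing-cell augmentation
        for key, rows in patterns.items():
            mis = np.setdiff1d(np.arange(p), key)
            if mis.size == 0:
                continue
            o = np.asarray(key)
            mean_full = mu + U[rows]
            if o.size == 0:
                cond_mean = mean_full[:, mis]
                cov = R[np.ix_(mis, mis)]
            else:
                Roo_inv = np.linalg.inv(R[np.ix_(o, o)])
                B = R[np.ix_(mis, o)] @ Roo_inv
                cond_mean = mean_full[:, mis] + (Yc[np.ix_(rows, o)] - mean_full[:, o]) @ B.T
                cov = R[np.ix_(mis, mis)] - B @ R[np.ix_(o, mis)]
            cov = (cov + cov.T) / 2.0 + 1e-12 * np.eye(mis.size)
            Lc = np.linalg.cholesky(cov)
            Yc[np.ix_(rows, mis)] = cond_mean + rng.standard_normal((len(rows), mis.size)) @ Lc.T

        # --- (iii) trait means, flat prior
        resid_mean = (Yc - U).mean(axis=0)
        Lr = np.linalg.cholesky(R / n + 1e-14 * np.eye(p))
        mu = resid_mean + Lr @ rng.standard_normal(p)

        # --- (iv) covariance matrices
        if fix_sigma is None:
            Sg = S0 + Ut.T @ (Ut / d[:, None])  # U' G^-1 U in the eigenbasis
            Sigma = stats.invwishart.rvs(df=nu0 + n, scale=Sg, random_state=rng)
            Sigma = np.atleast_2d(Sigma)
        if fix_r is None:
            E = Yc - mu - U
            Sr = S0 + E.T @ E
            R = stats.invwishart.rvs(df=nu0 + n, scale=Sr, random_state=rng)
            R = np.atleast_2d(R)

        if it >= gibbs.burn_in and (it - gibbs.burn_in) % gibbs.thin == 0:
            sum_U += U
            sum_Sigma += Sigma
            sum_R += R
            sum_mu += mu
            draws_sig[kept] = np.diag(Sigma)
            draws_r[kept] = np.diag(R)
            kept += 1

    chain = {
        "n_iter": gibbs.n_iter,
        "burn_in": gibbs.burn_in,
        "thin": gibbs.thin,
        "seed": gibbs.seed,
        "n_samples": kept,
        "ess_sigma_diag": [_ess(draws_sig[:kept, j]) for j in range(p)],
        "ess_r_diag": [_ess(draws_r[:kept, j]) for j in range(p)],
    }
    return MTMFit(
        trait_names=trait_names,
        Sigma=sum_Sigma / kept,
        R=sum_R / kept,
        mu=sum_mu / kept,
        U=pd.DataFrame(sum_U / kept, index=ids, columns=trait_names),
        chain=chain,
    )


def genetic_correlation(fit: MTMFit, i: int, j: int) -> float:
    """Genetic correlation Sigma_ij / sqrt(Sigma_ii Sigma_jj) from the posterior mean."""
    S = fit.Sigma
    if S[i, i] <= 0 or S[j, j] <= 0:
        warnings.warn("zero genetic variance on the diagonal: correlation undefined", stacklevel=2)
        return float("nan")
    return float(S[i, j] / np.sqrt(S[i, i] * S[j, j]))


def predict_target(fit: GBLUPFit | MTMFit, test_ids: list[str]) -> pd.Series:
    """Genetic value of the target trait for the requested genotypes.

    GBLUP returns the REML BLUP; the MTM returns the posterior mean of trait 0.
    """
    if isinstance(fit, GBLUPFit):
        source = fit.u
    else:
        source = fit.U.iloc[:, 0]
    missing = [t for t in test_ids if t not in source.index]
    if missing:
        raise KeyError(f"unknown genotype id(s): {missing[:5]}")
    out = source.loc[list(test_ids)].copy()
    out.name = "predicted"
    return out
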