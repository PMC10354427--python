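"""Legendre-basis random regression model (RRM) for vegetation-index trajectories.

The model for the VI value of genotype i at timepoint t is

    y_it = b_t + sum_{k=0..nr} phi_k(t) u_ik + e_it,

with b_t a fixed effect per measurement date, phi_k the normalized Legendre
polynomial of degree k evaluated at the min-max standardized time in [-1, 1],
genotype coefficient vectors u_i = (u_i0..u_inr) i.i.d. MVN(0, Q) across
genotypes, and e_it ~ N(0, sigma_e^2). Q and sigma_e^2 are estimated by REML;
the polynomial order nr is chosen by AIC.

Because genotypes are independent given the variance parameters, the REML
criterion decomposes over per-genotype blocks and is evaluated per distinct
missingness pattern, so fits stay cheap even for hundreds of genotypes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial import legendre as npleg
from scipy import optimize

from droughtstab.spectral import TimeSeriesTrait

__all__ = ["LegendreBasis", "RRMFit", "legendre_basis", "fit_rrm", "model_aic",
           "select_by_aic", "select_order"]

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class LegendreBasis:
    """Normalized Legendre design over standardized measurement times.

    ``phi[t, k]`` = sqrt((2k+1)/2) * P_k(x_t) with x_t = -1 + 2(t - t_min)/(t_max - t_min).
    The sqrt((2k+1)/2) factor makes the columns orthonormal under the uniform
    measure on [-1, 1], so Q stays on a comparable scale across orders.
    """

    order: int
    timepoints: np.ndarray
    standardized_times: np.ndarray
    phi: np.ndarray


def legendre_basis(timepoints: np.ndarray, order: int) -> LegendreBasis:
    """Build the T x (order+1) normalized Legendre design matrix."""
    t = np.asarray(timepoints, dtype=float)
    if order < 0:
        raise ValueError("order must be >= 0")
    if len(np.unique(t)) < order + 2:
        raise ValueError(f"need >= {order + 2} distinct timepoints for order {order}")
    t_min, t_max = t.min(), t.max()
    x = -1.0 + 2.0 * (t - t_min) / (t_max - t_min)
    phi = np.empty((len(t), order + 1))
    for k in range(order + 1):
        coef = np.zeros(k + 1)
        coef[k] = 1.0
        phi[:, k] = np.sqrt((2 * k + 1) / 2.0) * npleg.legval(x, coef)
    return LegendreBasis(order=order, timepoints=t, standardized_times=x, phi=phi)


@dataclass
class RRMFit:
    """REML estimates and BLUPs for one polynomial order.

    ``U`` rows are per-genotype coefficient BLUPs, columns named L0..Lnr; these
    are the secondary traits used downstream in multi-trait genomic prediction.
    """

    order: int
    b: pd.Series
    Q: np.ndarray
    resid_var: float
    U: pd.DataFrame
    reml_loglik: float
    n_params: int
    aic: float
    converged: bool
    basis: LegendreBasis = field(repr=False)

    @property
    def coefficient_names(self) -> list[str]:
        return [f"L{k}" for k in range(self.order + 1)]


def model_aic(reml_loglik: float, n_params: int) -> float:
    """Akaike information criterion, AIC = -2 * loglik + 2 * p."""
    return -2.0 * reml_loglik + 2.0 * n_params


def _pattern_groups(Y: np.ndarray) -> dict[tuple[int, ...], np.ndarray]:
    """Group genotype rows by the set of observed timepoint indices."""
    groups: dict[tuple[int, ...], list[int]] = {}
    obs = ~np.isnan(Y)
    for i in range(Y.shape[0]):
        key = tuple(np.nonzero(obs[i])[0])
        groups.setdefault(key, []).append(i)
    return {k: np.asarray(v) for k, v in groups.items() if len(k) > 0}


def _theta_to_vc(theta: np.ndarray, k: int) -> tuple[np.ndarray, float]:
    """Unpack optimizer vector into (Q, sigma_e^2) via a Cholesky factor with log-diagonal."""
    L = np.zeros((k, k))
    pos = 0
    for j in range(k):
        L[j, j] = np.exp(theta[pos])
        pos += 1
        L[j + 1:, j] = theta[pos: pos + k - j - 1]
        pos += k - j - 1
    return L @ L.T, float(np.exp(theta[pos]))


def _reml_neg_loglik(theta: np.ndarray, Phi: np.ndarray, Y: np.ndarray,
                     groups: dict[tuple[int, ...], np.ndarray]) -> float:
    """Negative REML log-likelihood, decomposed over missingness-pattern blocks.

    X is the timepoint-indicator fixed-effect design; for genotype i with
    observed set o, the marginal block is V_o = Phi_o Q Phi_o' + se2 I.
    """
    T, k = Phi.shape
    Q, se2 = _theta_to_vc(theta, k)
    if not np.isfinite(se2) or se2 <= 0:
        return np.inf
    logdet_V = 0.0
    XtViX = np.zeros((T, T))
    XtViy = np.zeros(T)
    ytViy = 0.0
    n_obs = 0
    for o, rows in groups.items():
        o = np.asarray(o)
        Phi_o = Phi[o]
        V = Phi_o @ Q @ Phi_o.T + se2 * np.eye(len(o))
        try:
            Lc = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return np.inf
        logdet_V += 2.0 * len(rows) * np.log(np.diag(Lc)).sum()
        Vi = np.linalg.inv(V)
        Yo = Y[np.ix_(rows, o)]
        XtViX[np.ix_(o, o)] += len(rows) * Vi
        XtViy[o] += Vi @ Yo.sum(axis=0)
        ytViy += float(np.einsum("ij,jk,ik->", Yo, Vi, Yo))
        n_obs += len(rows) * len(o)
    sign, logdet_X = np.linalg.slogdet(XtViX)
    if sign <= 0:
        return np.inf
    b = np.linalg.solve(XtViX, XtViy)
    yPy = ytViy - float(XtViy @ b)
    ll = -0.5 * (logdet_V + logdet_X + yPy + (n_obs - T) * _LOG2PI)
    return -ll


def fit_rrm(
    trait: TimeSeriesTrait,
    order: int,
    maxiter: int = 500,
    tol: float = 1e-8,
    extra_starts: int = 2,
) -> RRMFit:
    """REML fit of the random regression model at a fixed polynomial order.

    The criterion is maximized over the Cholesky factor of Q (log-diagonal) and
    log sigma_e^2 with L-BFGS-B from multiple starts (diagonal Q at 0.5x and 2x
    the phenotypic variance split). Records with missing VI are dropped from
    the likelihood. Fixed timepoint effects b_t are the GLS solution at the
    optimum and U holds the coefficient BLUPs
    u_i = Q Phi_o' V_o^{-1} (y_i - b_o).
    """
    Y = trait.values.to_numpy(dtype=float)
    basis = legendre_basis(trait.timepoints, order)
    Phi = basis.phi
    T, k = Phi.shape
    groups = _pattern_groups(Y)
    if not groups:
        raise ValueError("no observed values")

    var_y = float(np.nanvar(Y))
    var_y = max(var_y, 1e-10)
    n_theta = k * (k + 1) // 2 + 1

    def start_vector(frac_g: float) -> np.ndarray:
        theta = np.zeros(n_theta)
        pos = 0
        for j in range(k):
            theta[pos] = 0.5 * np.log(frac_g * var_y / k)
            pos += 1 + (k - j - 1)
        theta[-1] = np.log((1.0 - frac_g) * var_y)
        return theta

    starts = [start_vector(0.5), start_vector(1.0 / 3.0), start_vector(2.0 / 3.0)][: 1 + extra_starts]
    best = None
    converged = False
    for x0 in starts:
        res = optimize.minimize(
            _reml_neg_loglik,
            x0,
            args=(Phi, Y, groups),
            method="L-BFGS-B",
            options={"maxiter": maxiter, "ftol": tol, "gtol": 1e-7},
        )
        if best is None or res.fun < best.fun - 1e-12:
            best = res
            converged = bool(res.success)
    assert best is not None
    if not converged:
        warnings.warn("REML optimizer did not report convergence", stacklevel=2)

    Q, se2 = _theta_to_vc(best.x, k)
    # Cholesky parameterization keeps Q PSD; clip roundoff negatives anyway
    w, V = np.linalg.eigh(Q)
    if w.min() < 0:
        Q = (V * np.clip(w, 0.0, None)) @ V.T

    # GLS fixed effects and per-genotype BLUPs at the optimum
    XtViX = np.zeros((T, T))
    XtViy = np.zeros(T)
    for o, rows in groups.items():
        o = np.asarray(o)
        Phi_o = Phi[o]
        Vi = np.linalg.inv(Phi_o @ Q @ Phi_o.T + se2 * np.eye(len(o)))
        Yo = Y[np.ix_(rows, o)]
        XtViX[np.ix_(o, o)] += len(rows) * Vi
        XtViy[o] += Vi @ Yo.sum(axis=0)
    b = np.linalg.solve(XtViX, XtViy)

    U = np.zeros((Y.shape[0], k))
    for o, rows in groups.items():
        o = np.asarray(o)
        Phi_o = Phi[o]
        Vi = np.linalg.inv(Phi_o @ Q @ Phi_o.T + se2 * np.eye(len(o)))
        resid = Y[np.ix_(rows, o)] - b[o]
        U[rows] = resid @ Vi @ Phi_o @ Q  # (Q Phi' V^-1 r)' rows

    n_params = (T - 1) + k * (k + 1) // 2 + 1
    loglik = -float(best.fun)
    return RRMFit(
        order=order,
        b=pd.Series(b, index=trait.timepoints, name="b_t"),
        Q=Q,
        resid_var=se2,
        U=pd.DataFrame(U, index=trait.values.index, columns=[f"L{j}" for j in range(k)]),
        reml_loglik=loglik,
        n_params=n_params,
        aic=model_aic(loglik, n_params),
        converged=converged,
        basis=basis,
    )


def select_by_aic(aic_by_order: dict[int, float]) -> int:
    """Order with the lowest AIC; ties break toward the smaller order."""
    if not aic_by_order:
        raise ValueError("no candidates")
    best_order = min(aic_by_order)
    for nr in sorted(aic_by_order):
        if aic_by_order[nr] < aic_by_order[best_order]:
            best_order = nr
    return best_order


def select_order(trait: TimeSeriesTrait, orders: list[int], **fit_kwargs) -> RRMFit:
    """Fit each candidate order and return the fit with the lowest AIC.

    Ties break toward the smaller order.
    """
    if not orders:
        raise ValueError("orders must be non-empty")
    fits: dict[int, RRMFit] = {}
    errors: list[str] = []
    for nr in sorted(orders):
        try:
            fits[nr] = fit_rrm(trait, nr, **fit_kwargs)
        except ValueError as exc:  # infeasible order for this T
            errors.append(f"nr={nr}: {exc}")
    if not fits:
        raise ValueError("no order could be fitted: " + "; ".join(errors))
    if all(not f.converged for f in fits.values()):
        raise RuntimeError("no candidate order converged")
    return fits[select_by_aic({nr: f.aic for nr, f in fits.items()})]
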