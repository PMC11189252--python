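"""Multi-site harmonization via parametric empirical-Bayes ComBat.

Removes per-site additive (location) and multiplicative (scale) effects from
a subjects x measures matrix while preserving the structure explained by
protected covariates (age, sex, eTIV by default in the pipeline). Site
effects are shrunk across measures with the standard parametric empirical
Bayes scheme: a normal prior on the location effects and an inverse-gamma
prior on the scale effects, hyperparameters moment-matched, conditional
estimates iterated to convergence.

Used at two points in the pipeline: on vectorized MSN upper-triangle edges
before averaging into the group template, and on dispersion measures before
trajectory fitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

__all__ = ["HarmonizationModel", "ComBat", "combat_fit_transform"]


@dataclass
class HarmonizationModel:
    """Fitted ComBat parameters (location/scale model per measure)."""

    sites: list
    alpha: np.ndarray          # (m,) grand mean per measure
    beta: np.ndarray           # (c, m) covariate coefficients
    sigma: np.ndarray          # (m,) pooled residual sd
    gamma_star: np.ndarray     # (K, m) EB-shrunk additive site effects
    delta2_star: np.ndarray    # (K, m) EB-shrunk multiplicative site effects


class ComBat(BaseEstimator):
    """Parametric empirical-Bayes ComBat harmonizer.

    Parameters
    ----------
    tol : float, default=1e-6
        Convergence tolerance of the iterative conditional EB estimates.
    max_iter : int, default=500
    """

    def __init__(self, tol=1e-6, max_iter=500):
        self.tol = tol
        self.max_iter = max_iter

    def fit_transform(self, values, site, covariates=None):
        """Harmonize ``values`` (subjects x measures) across sites.

        ``covariates`` (subjects x C, optional) are protected: their
        predicted structure is standardized out before site-effect
        estimation and restored afterwards.
        """
        Y = np.asarray(values, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        n, m = Y.shape
        site = np.asarray(site)
        if site.shape[0] != n:
            raise ValueError("site labels must match number of subjects")
        const = np.flatnonzero(Y.std(axis=0) == 0)
        if const.size:
            raise ValueError(f"measure(s) {const.tolist()} are constant; ComBat undefined")
        sites = sorted(np.unique(site).tolist())
        K = len(sites)
        counts = {s: int(np.sum(site == s)) for s in sites}
        if K >= 2:
            lonely = [s for s, c in counts.items() if c < 2]
            if lonely:
                raise ValueError(f"site(s) {lonely} have fewer than 2 subjects")

        if covariates is not None:
            C = np.asarray(covariates, dtype=float)
            if C.ndim == 1:
                C = C[:, None]
            if C.shape[0] != n:
                raise ValueError("covariate rows must match number of subjects")
        else:
            C = np.empty((n, 0))

        # design: site one-hot + covariates (no global intercept; the grand
        # mean is the site-size-weighted combination of site intercepts)
        site_idx = np.array([sites.index(s) for s in site])
        D_site = np.eye(K)[site_idx]
        X = np.hstack([D_site, C])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("design matrix (site + covariates) is rank deficient")
        B, *_ = np.linalg.lstsq(X, Y, rcond=None)
        site_means = B[:K]                      # (K, m)
        beta = B[K:]                            # (c, m)
        w = np.array([counts[s] for s in sites], dtype=float) / n
        alpha = w @ site_means                  # (m,)

        stand_mean = alpha[None, :] + C @ beta  # (n, m)
        resid = Y - D_site @ site_means - C @ beta
        sigma2 = (resid**2).sum(axis=0) / n
        sigma = np.sqrt(sigma2)

        if K == 1:
            # nothing to harmonize; standardize/restore is the identity
            self.model_ = HarmonizationModel(
                sites=sites, alpha=alpha, beta=beta, sigma=sigma,
                gamma_star=np.zeros((1, m)), delta2_star=np.ones((1, m)),
            )
            return Y.copy()

        Z = (Y - stand_mean) / sigma[None, :]

        gamma_hat = np.stack([Z[site_idx == k].mean(axis=0) for k in range(K)])
        delta2_hat = np.stack([Z[site_idx == k].var(axis=0, ddof=1) for k in range(K)])

        if m < 2:
            # EB pools across measures; with one measure use direct estimates
            adj = (Z - gamma_hat[site_idx]) / np.sqrt(delta2_hat[site_idx])
            out = adj * sigma[None, :] + stand_mean
            self.model_ = HarmonizationModel(
                sites=sites, alpha=alpha, beta=beta, sigma=sigma,
                gamma_star=gamma_hat, delta2_star=delta2_hat,
            )
            return out

        # EB hyperparameters, moment-matched across measures
        gamma_bar = gamma_hat.mean(axis=1)              # (K,)
        tau2 = gamma_hat.var(axis=1, ddof=1)            # (K,)
        d_mean = delta2_hat.mean(axis=1)
        d_var = np.maximum(delta2_hat.var(axis=1, ddof=1), 1e-12)
        lam = (2.0 * d_var + d_mean**2) / d_var         # inverse-gamma shape
        theta = (d_mean * d_var + d_mean**3) / d_var    # inverse-gamma scale

        gamma_star = gamma_hat.copy()
        delta2_star = delta2_hat.copy()
        ns = np.array([counts[s] for s in sites], dtype=float)
        for k in range(K):
            Zk = Z[site_idx == k]
            g, d2 = gamma_hat[k].copy(), delta2_hat[k].copy()
            for _ in range(self.max_iter):
                g_new = (ns[k] * tau2[k] * gamma_hat[k] + d2 * gamma_bar[k]) / (
                    ns[k] * tau2[k] + d2
                )
                ss = ((Zk - g_new[None, :]) ** 2).sum(axis=0)
                d2_new = (theta[k] + 0.5 * ss) / (ns[k] / 2.0 + lam[k] - 1.0)
                change = max(
                    np.abs(g_new - g).max(), np.abs(d2_new - d2).max()
                )
                g, d2 = g_new, d2_new
                if change < self.tol:
                    break
            gamma_star[k], delta2_star[k] = g, d2

        adj = (Z - gamma_star[site_idx]) / np.sqrt(delta2_star[site_idx])
        out = adj * sigma[None, :] + stand_mean
        self.model_ = HarmonizationModel(
            sites=sites, alpha=alpha, beta=beta, sigma=sigma,
            gamma_star=gamma_star, delta2_star=delta2_star,
        )
        return out


def combat_fit_transform(values, site, covariates=None, tol=1e-6):
    """Functional wrapper: returns (harmonized matrix, HarmonizationModel)."""
    cb = ComBat(tol=tol)
    out = cb.fit_transform(values, site, covariates)
    return out, cb.model_
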