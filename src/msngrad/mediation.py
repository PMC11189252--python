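"""Bootstrap mediation analysis (OLS path models).

Estimates whether dispersion measures mediate the age -> cognition
association. The model is the standard (parallel) mediation path analysis:

    a_j:  m_j ~ x + covariates
    b_j, c': y ~ x + m_1..m_J + covariates
    c:    y ~ x + covariates

All variables are z-scored so the coefficients are standardized betas. The
indirect effect of mediator j is a_j * b_j; the joint indirect effect is
their sum, and the proportion mediated is

    (a_1 b_1 + ... + a_J b_J) / (a_1 b_1 + ... + a_J b_J + c').

Inference is by percentile bootstrap over subjects (default 5,000
resamples); an effect is significant when its 95% CI excludes zero. For
linear OLS paths with identical covariate sets the in-sample decomposition
c = c' + sum(a_j b_j) holds exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .trajectories import fdr_correct

__all__ = ["MediationResult", "simple_mediation", "multiple_mediation"]


@dataclass
class MediationResult:
    a: np.ndarray                 # (J,) exposure -> mediator paths
    b: np.ndarray                 # (J,) mediator -> outcome paths
    c: float                      # total effect
    c_prime: float                # direct effect
    indirect: np.ndarray          # (J,) a_j * b_j
    indirect_joint: float
    proportion_mediated: float
    ci: dict = field(default_factory=dict)       # name -> (lo, hi)
    p: dict = field(default_factory=dict)        # name -> bootstrap p
    p_fdr: np.ndarray = None                     # per-mediator indirect, BH-adjusted
    n_boot: int = 0
    seed: int = 0


def _z(v):
    v = np.asarray(v, dtype=float)
    sd = v.std()
    if sd == 0:
        raise ValueError("cannot z-score a constant variable")
    return (v - v.mean()) / sd


def _ols(X, y):
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise ValueError("design matrix is rank deficient (collinear predictors)")
    return coef


def _paths(x, M, y, C):
    """Return (a, b, c_prime, c) for z-scored inputs with covariates C."""
    n, J = M.shape
    ones = np.ones((n, 1))
    Xa = np.hstack([ones, x[:, None], C])
    a = np.array([_ols(Xa, M[:, j])[1] for j in range(J)])
    Xb = np.hstack([ones, x[:, None], M, C])
    cb = _ols(Xb, y)
    c_prime, b = cb[1], cb[2 : 2 + J]
    c = _ols(Xa, y)[1]
    return a, b, c_prime, c


def _mediate(x, M, y, covariates, n_boot, seed, min_n):
    x = _z(x)
    y = _z(y)
    M = np.asarray(M, dtype=float)
    if M.ndim == 1:
        M = M[:, None]
    n, J = M.shape
    if x.shape[0] != n or y.shape[0] != n:
        raise ValueError("x, mediators and y must have equal length")
    if n < min_n:
        raise ValueError(f"need at least {min_n} subjects, got {n}")
    if J >= 2:
        cm = np.corrcoef(M.T)
        iu = np.triu_indices(J, k=1)
        dup = np.argwhere(np.abs(cm[iu]) > 1 - 1e-10)
        if dup.size:
            i, j = iu[0][dup[0][0]], iu[1][dup[0][0]]
            raise ValueError(f"mediators {i} and {j} are collinear")
    M = np.column_stack([_z(M[:, j]) for j in range(J)])
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        C = np.column_stack([_z(C[:, k]) for k in range(C.shape[1])])
    else:
        C = np.empty((n, 0))

    a, b, c_prime, c = _paths(x, M, y, C)
    indirect = a * b
    joint = float(indirect.sum())
    prop = joint / (joint + c_prime)

    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, J + 2))   # per-mediator indirects, joint, c'
    for r in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            ar, br, cpr, _ = _paths(x[idx], M[idx], y[idx], C[idx])
        except ValueError:
            ar, br, cpr = a, b, c_prime   # degenerate resample; keep point estimate
        boots[r, :J] = ar * br
        boots[r, J] = (ar * br).sum()
        boots[r, J + 1] = cpr

    def pct_ci(col):
        return (float(np.percentile(col, 2.5)), float(np.percentile(col, 97.5)))

    def boot_p(col):
        lo = (1 + np.sum(col <= 0)) / (n_boot + 1)
        hi = (1 + np.sum(col >= 0)) / (n_boot + 1)
        return float(min(1.0, 2 * min(lo, hi)))

    ci = {f"indirect_{j}": pct_ci(boots[:, j]) for j in range(J)}
    ci["indirect_joint"] = pct_ci(boots[:, J])
    ci["c_prime"] = pct_ci(boots[:, J + 1])
    p = {f"indirect_{j}": boot_p(boots[:, j]) for j in range(J)}
    p["indirect_joint"] = boot_p(boots[:, J])
    p["c_prime"] = boot_p(boots[:, J + 1])
    p_fdr, _ = fdr_correct([p[f"indirect_{j}"] for j in range(J)])

    return MediationResult(
        a=a, b=b, c=float(c), c_prime=float(c_prime),
        indirect=indirect, indirect_joint=joint,
        proportion_mediated=float(prop), ci=ci, p=p, p_fdr=p_fdr,
        n_boot=n_boot, seed=seed,
    )


def simple_mediation(x, m, y, covariates=None, n_boot=5000, seed=0) -> MediationResult:
    """Single-mediator model; indirect effect a*b, proportion a*b/(a*b + c')."""
    m = np.asarray(m, dtype=float)
    if m.ndim != 1:
        raise ValueError("simple_mediation takes a single mediator vector")
    return _mediate(x, m, y, covariates, n_boot, seed, min_n=50)


def multiple_mediation(x, mediators, y, covariates=None, n_boot=5000, seed=0) -> MediationResult:
    """Parallel multiple-mediator model (J >= 2 mediators)."""
    M = np.asarray(mediators, dtype=float)
    if M.ndim != 2 or M.shape[1] < 2:
        raise ValueError("multiple_mediation needs an n x J mediator matrix with J >= 2")
    return _mediate(x, M, y, covariates, n_boot, seed, min_n=50)
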