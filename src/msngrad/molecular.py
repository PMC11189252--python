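"""Molecular association of an age-effect brain map.

Two analyses link a per-region age-effect map (e.g., regional R-squared of
the eccentricity trajectory) to molecular annotation matrices:

- PLS1 against a regions x genes expression matrix: the first partial least
  squares component is the gene combination maximally covarying with the
  map. Significance comes from spatial-autocorrelation-preserving (spin)
  permutations; genes are ranked by the ratio of their PLS1 weight to its
  bootstrap standard error (a z-score), and the top-k genes form the
  derived gene list.
- Multiple regression against a regions x receptors density matrix, with
  the LMG relative-importance decomposition (each predictor's incremental
  R-squared averaged over all predictor orderings, computed exactly from
  the 2^P subset R-squared table), bootstrap CIs on the importance shares,
  and per-receptor spin p-values.

Spin nulls rotate the parcel coordinates on the sphere by a uniform random
rotation and map rotated to original parcels by greedy one-to-one nearest
neighbor assignment, yielding exact permutations that preserve spatial
autocorrelation.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial

import numpy as np
from scipy import stats
from scipy.stats import special_ortho_group

from .trajectories import fdr_correct

__all__ = [
    "NullEnsemble",
    "PLSResult",
    "ReceptorModel",
    "spin_permutations",
    "null_pvalue",
    "pls1",
    "pls_significance",
    "bootstrap_gene_z",
    "receptor_regression",
    "lmg_importance",
]


@dataclass
class NullEnsemble:
    """Set of spatial-null permutations (each row permutes 0..R-1)."""

    perms: np.ndarray     # (n_perm, R) int
    method: str = "spin"
    seed: int = 0

    @property
    def n_perm(self) -> int:
        return self.perms.shape[0]


@dataclass
class PLSResult:
    weights: np.ndarray               # (G,) PLS1 gene weights
    scores: np.ndarray                # (R,) per-region PLS1 scores
    explained_variance: float         # fraction of response variance
    p_perm: float = np.nan
    gene_z: np.ndarray = None
    gene_p: np.ndarray = None
    gene_p_fdr: np.ndarray = None
    ranked_genes: np.ndarray = None   # indices ordered by z descending
    top_list: np.ndarray = None


@dataclass
class ReceptorModel:
    coefficients: np.ndarray          # (P,) standardized betas
    r2: float
    adjusted_r2: float
    lmg_shares: np.ndarray            # (P,) sum to r2
    share_cis: np.ndarray = None      # (P, 2)
    p_spin: np.ndarray = None
    p_spin_fdr: np.ndarray = None


def spin_permutations(coords, n_perm=1000, seed=0) -> NullEnsemble:
    """Spatial-null permutations from random sphere rotations.

    Each null applies a uniform random 3-D rotation to the unit-sphere
    parcel coordinates, then greedily assigns each rotated parcel to its
    nearest unassigned original parcel (globally closest pair first),
    producing an exact permutation.
    """
    coords = np.asarray(coords, dtype=float)
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if not np.allclose(np.linalg.norm(coords, axis=1), 1.0, atol=1e-8):
        raise ValueError("coordinates must be unit-norm")
    R = coords.shape[0]
    rng = np.random.default_rng(seed)
    perms = np.empty((n_perm, R), dtype=np.intp)
    for r in range(n_perm):
        Q = special_ortho_group.rvs(3, random_state=rng)
        rotated = coords @ Q.T
        perms[r] = _greedy_assignment(rotated, coords)
    return NullEnsemble(perms=perms, method="spin", seed=seed)


def _greedy_assignment(rotated, original):
    """One-to-one rotated->original map, closest pair assigned first.

    Returns perm with perm[i] = original index assigned to rotated parcel i,
    so map[perm] relabels an original-space map into the null configuration.
    """
    R = rotated.shape[0]
    D = np.linalg.norm(rotated[:, None, :] - original[None, :, :], axis=2)
    perm = np.full(R, -1, dtype=np.intp)
    for _ in range(R):
        i, j = np.unravel_index(np.argmin(D), D.shape)
        perm[i] = j
        D[i, :] = np.inf
        D[:, j] = np.inf
    return perm


def null_pvalue(observed_stat, null_stats, two_sided=True) -> float:
    """Finite-sample permutation p-value: (1 + #extreme) / (1 + n_perm)."""
    nulls = np.asarray(null_stats, dtype=float)
    if nulls.size == 0:
        raise ValueError("empty null distribution")
    if two_sided:
        count = np.sum(np.abs(nulls) >= abs(observed_stat))
    else:
        count = np.sum(nulls >= observed_stat)
    return float((1 + count) / (1 + nulls.size))


def _z_cols(X):
    X = np.asarray(X, dtype=float)
    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (X - X.mean(axis=0)) / sd


def pls1(gene_matrix, response_map) -> PLSResult:
    """First-component partial least squares of a map on an annotation matrix.

    Predictors and response are z-scored internally. The PLS1 weight vector
    is proportional to X'y (normalized), scores are Xw, and explained
    variance is the squared correlation of the scores with the response.
    The sign is fixed so that corr(scores, response) >= 0.
    """
    X = np.asarray(gene_matrix, dtype=float)
    y = np.asarray(response_map, dtype=float)
    if X.ndim != 2 or X.shape[0] < 10:
        raise ValueError("need a regions x genes matrix with at least 10 regions")
    if y.shape[0] != X.shape[0]:
        raise ValueError("response length must match number of regions")
    if y.std() == 0:
        raise ValueError("response map is constant")
    Xz = _z_cols(X)
    yz = (y - y.mean()) / y.std()
    w = Xz.T @ yz
    nrm = np.linalg.norm(w)
    if nrm == 0:
        raise ValueError("response is orthogonal to every gene")
    w = w / nrm
    scores = Xz @ w
    r = float(np.corrcoef(scores, yz)[0, 1])
    if r < 0:
        w, scores, r = -w, -scores, -r
    return PLSResult(weights=w, scores=scores, explained_variance=r**2)


def pls_significance(gene_matrix, response_map, nulls: NullEnsemble) -> float:
    """One-sided spin p for PLS1 explained variance (response permuted)."""
    X = np.asarray(gene_matrix, dtype=float)
    y = np.asarray(response_map, dtype=float)
    if nulls.perms.shape[1] != X.shape[0]:
        raise ValueError("null ensemble region count does not match the matrix")
    obs = pls1(X, y).explained_variance
    # vectorized: EV for all permuted responses at once
    Xz = _z_cols(X)
    Y = _z_cols(y[nulls.perms].T)             # (R, n_perm) permuted responses
    W = Xz.T @ Y                              # (G, n_perm)
    W = W / np.linalg.norm(W, axis=0, keepdims=True)
    S = Xz @ W                                # (R, n_perm) scores
    Sz = _z_cols(S)
    r = (Sz * Y).mean(axis=0)
    null_ev = r**2
    return null_pvalue(obs, null_ev, two_sided=False)


def bootstrap_gene_z(gene_matrix, response_map, n_boot=1000, top_k=1000, seed=0) -> PLSResult:
    """Rank genes by PLS1 weight / bootstrap SE.

    Regions are resampled with replacement; each bootstrap weight vector is
    sign-aligned to the original (dot-product sign) before the SE is taken.
    z = original weight / bootstrap SE; genes are ranked by z descending,
    with two-sided normal p-values and a BH-FDR mask.
    """
    X = np.asarray(gene_matrix, dtype=float)
    G = X.shape[1]
    if top_k > G:
        raise ValueError(f"top_k={top_k} exceeds the number of genes ({G})")
    res = pls1(X, response_map)
    y = np.asarray(response_map, dtype=float)
    R = X.shape[0]
    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, G))
    for r in range(n_boot):
        idx = rng.integers(0, R, size=R)
        yb = y[idx]
        if yb.std() == 0:
            boots[r] = res.weights
            continue
        wb = pls1(X[idx], yb).weights
        if wb @ res.weights < 0:
            wb = -wb
        boots[r] = wb
    se = boots.std(axis=0, ddof=1)
    se = np.where(se == 0, np.inf, se)
    z = res.weights / se
    p = 2 * stats.norm.sf(np.abs(z))
    p_fdr, _ = fdr_correct(p)
    order = np.argsort(-z, kind="stable")
    res.gene_z, res.gene_p, res.gene_p_fdr = z, p, p_fdr
    res.ranked_genes = order
    res.top_list = order[:top_k]
    return res


def _subset_r2_table(X, y):
    """R-squared of OLS on every predictor subset (bitmask indexed)."""
    n, P = X.shape
    tss = float(y @ y)
    r2 = np.zeros(1 << P)
    for mask in range(1, 1 << P):
        cols = [j for j in range(P) if mask & (1 << j)]
        Xs = X[:, cols]
        coef, *_ = np.linalg.lstsq(Xs, y, rcond=None)
        resid = y - Xs @ coef
        r2[mask] = 1.0 - float(resid @ resid) / tss
    return r2


def lmg_importance(X, y):
    """Exact LMG relative importance via the 2^P subset-R2 table.

    Share of predictor j = average over all P! predictor orderings of the
    incremental R2 when j enters; shares sum to the full-model R2. Inputs
    are centered internally (intercept handled by centering).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    n, P = Xc.shape
    r2 = _subset_r2_table(Xc, yc)
    shares = np.zeros(P)
    for j in range(P):
        bit = 1 << j
        for mask in range(1 << P):
            if mask & bit:
                continue
            s = bin(mask).count("1")
            wgt = factorial(s) * factorial(P - s - 1) / factorial(P)
            shares[j] += wgt * (r2[mask | bit] - r2[mask])
    return shares, float(r2[(1 << P) - 1])


def receptor_regression(receptor_matrix, response_map, nulls: NullEnsemble = None,
                        n_boot=1000, seed=0) -> ReceptorModel:
    """Multiple regression of the age-effect map on receptor densities.

    OLS on z-scored inputs, adjusted R-squared, exact LMG importance shares
    with percentile bootstrap 95% CIs, and (when a null ensemble is given)
    per-receptor spin p-values from refitting with the permuted response,
    BH-FDR corrected.
    """
    X = np.asarray(receptor_matrix, dtype=float)
    y = np.asarray(response_map, dtype=float)
    n, P = X.shape
    if P < 1:
        raise ValueError("need at least one predictor")
    if n <= P + 1:
        raise ValueError("need more regions than predictors + 1")
    if y.shape[0] != n:
        raise ValueError("response length mismatch")
    Xz = _z_cols(X)
    if np.linalg.matrix_rank(Xz) < P:
        raise ValueError("singular receptor design (collinear columns)")
    yz = (y - y.mean()) / y.std()
    coef, *_ = np.linalg.lstsq(Xz, yz, rcond=None)
    resid = yz - Xz @ coef
    r2 = 1.0 - float(resid @ resid) / float(yz @ yz)
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - P - 1)
    shares, r2_check = lmg_importance(Xz, yz)

    rng = np.random.default_rng(seed)
    boot_shares = np.empty((n_boot, P))
    for r in range(n_boot):
        idx = rng.integers(0, n, size=n)
        yb = yz[idx]
        if yb.std() == 0 or np.linalg.matrix_rank(Xz[idx]) < P:
            boot_shares[r] = shares
            continue
        boot_shares[r], _ = lmg_importance(Xz[idx], yb)
    cis = np.column_stack([
        np.percentile(boot_shares, 2.5, axis=0),
        np.percentile(boot_shares, 97.5, axis=0),
    ])

    p_spin = p_fdr = None
    if nulls is not None:
        if nulls.perms.shape[1] != n:
            raise ValueError("null ensemble region count mismatch")
        null_betas = np.empty((nulls.n_perm, P))
        for r in range(nulls.n_perm):
            yp = yz[nulls.perms[r]]
            null_betas[r] = np.linalg.lstsq(Xz, yp, rcond=None)[0]
        p_spin = np.array([
            null_pvalue(coef[j], null_betas[:, j], two_sided=True) for j in range(P)
        ])
        p_fdr, _ = fdr_correct(p_spin)

    return ReceptorModel(
        coefficients=coef, r2=r2, adjusted_r2=adj, lmg_shares=shares,
        share_cis=cis, p_spin=p_spin, p_spin_fdr=p_fdr,
    )
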