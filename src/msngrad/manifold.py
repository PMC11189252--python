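"""Gradient (manifold) embedding of morphometric similarity networks.

Pipeline: row-wise sparsification of the MSN (top 10% strongest connections
per row), cosine affinity between the sparsified rows, then diffusion map
embedding of the resulting non-negative affinity matrix with density
normalization alpha = 0.5 and automatic diffusion time (t = 0, i.e. each
component scaled by lambda / (1 - lambda)). Individual embeddings are aligned
to a group template (built from the subject-averaged MSN) with an orthogonal
Procrustes rotation, so gradient coordinates are comparable across subjects.

`DiffusionGradients` and `ProcrustesAlignment` are scikit-learn style
estimators; the module-level functions are thin wrappers over them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from scipy.sparse.csgraph import connected_components
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.metrics.pairwise import cosine_similarity

from .msn import MSNMatrix

__all__ = [
    "GradientSet",
    "DiffusionGradients",
    "ProcrustesAlignment",
    "threshold_rows",
    "cosine_affinity",
    "diffusion_embedding",
    "build_template",
    "align_gradients",
]


@dataclass
class GradientSet:
    """Low-dimensional embedding of one MSN.

    Attributes
    ----------
    gradients : ndarray of shape (R, k)
        Embedding coordinates; column m is gradient G(m+1), ordered by
        explained variance (descending eigenvalue).
    eigenvalues : ndarray of shape (k,)
        Non-trivial diffusion-operator eigenvalues, strictly in (0, 1],
        non-increasing.
    params : dict
        Embedding parameters (density, alpha, t, n_components).
    """

    gradients: np.ndarray
    eigenvalues: np.ndarray
    params: dict = field(default_factory=dict)

    @property
    def n_regions(self) -> int:
        return self.gradients.shape[0]

    @property
    def n_components(self) -> int:
        return self.gradients.shape[1]


def threshold_rows(msn, density: float = 0.10) -> np.ndarray:
    """Keep the top ``floor(density * R)`` off-diagonal entries per row.

    The diagonal is zeroed first. Ties at the cutoff are broken in favor of
    the lower column index. The result is generally asymmetric. Thresholding
    keeps the largest signed correlations (not absolute values).
    """
    W = msn.values if isinstance(msn, MSNMatrix) else np.asarray(msn, dtype=float)
    R = W.shape[0]
    if not 0 < density < 1:
        raise ValueError("density must be in (0, 1)")
    k = int(np.floor(density * R))
    if k < 1:
        raise ValueError(f"floor(density * R) = {k}; too few regions for density {density}")
    A = W.copy()
    np.fill_diagonal(A, 0.0)
    out = np.zeros_like(A)
    for i in range(R):
        row = A[i].copy()
        row[i] = -np.inf  # diagonal never kept
        # stable sort on descending value keeps lower column index on ties
        order = np.argsort(-row, kind="stable")[:k]
        out[i, order] = A[i, order]
    return out


def cosine_affinity(S: np.ndarray) -> np.ndarray:
    """Cosine similarity between sparsified rows, clipped to [0, 1].

    Entry (i, j) is the cosine similarity of rows i and j of the thresholded
    matrix; negative similarities are clipped to 0 (the diffusion operator
    requires a non-negative affinity) and the diagonal is zeroed.
    """
    S = np.asarray(S, dtype=float)
    norms = np.linalg.norm(S, axis=1)
    bad = np.flatnonzero(norms == 0)
    if bad.size:
        raise ValueError(f"all-zero thresholded row(s) for region(s) {bad.tolist()}")
    W = cosine_similarity(S)
    np.clip(W, 0.0, 1.0, out=W)
    W = (W + W.T) / 2.0
    np.fill_diagonal(W, 0.0)
    return W


class DiffusionGradients(BaseEstimator, TransformerMixin):
    """Diffusion map embedding of an MSN.

    Parameters
    ----------
    n_components : int, default=3
        Number of gradients retained.
    density : float, default=0.10
        Fraction of strongest connections kept per MSN row before the
        affinity computation.
    alpha : float, default=0.5
        Density-normalization exponent of the diffusion operator. 0.5
        approximates the Fokker-Planck diffusion and preserves global
        relations between points.
    diffusion_time : float, default=0
        0 selects the automatic-time convention: component m is scaled by
        lambda_m / (1 - lambda_m). A positive value scales by lambda_m**t.

    Attributes
    ----------
    gradients_ : ndarray of shape (R, n_components)
    eigenvalues_ : ndarray of shape (n_components,)
    affinity_ : ndarray of shape (R, R)
    """

    def __init__(self, n_components=3, density=0.10, alpha=0.5, diffusion_time=0):
        self.n_components = n_components
        self.density = density
        self.alpha = alpha
        self.diffusion_time = diffusion_time

    def fit(self, X, y=None):
        W = X.values if isinstance(X, MSNMatrix) else np.asarray(X, dtype=float)
        S = threshold_rows(W, self.density)
        A = cosine_affinity(S)
        self.affinity_ = A
        gs = _diffusion_embedding_core(
            A, k=self.n_components, alpha=self.alpha, t=self.diffusion_time
        )
        gs.params["density"] = self.density
        self.gradients_ = gs.gradients
        self.eigenvalues_ = gs.eigenvalues
        self.params_ = gs.params
        return self

    def transform(self, X=None):
        return self.gradients_

    def to_gradient_set(self) -> GradientSet:
        return GradientSet(self.gradients_.copy(), self.eigenvalues_.copy(), dict(self.params_))


def _diffusion_embedding_core(W: np.ndarray, k: int, alpha: float, t: float) -> GradientSet:
    W = np.asarray(W, dtype=float)
    R = W.shape[0]
    if k >= R:
        raise ValueError("n_components must be smaller than the number of regions")
    if np.any(W < 0):
        raise ValueError("affinity matrix must be non-negative")
    n_comp, labels = connected_components(W > 0, directed=False)
    if n_comp > 1:
        sizes = np.bincount(labels).tolist()
        raise ValueError(f"affinity graph is disconnected; component sizes {sizes}")

    # alpha-normalization: W_a = D^-a W D^-a, with D = diag(row sums)
    d = W.sum(axis=1)
    d_alpha = np.power(d, -alpha)
    W_a = W * np.outer(d_alpha, d_alpha)
    # Markov operator P = D_a^-1 W_a; eigendecompose its symmetric conjugate
    d_a = W_a.sum(axis=1)
    d_a_isqrt = 1.0 / np.sqrt(d_a)
    S = W_a * np.outer(d_a_isqrt, d_a_isqrt)
    S = (S + S.T) / 2.0
    evals, evecs = linalg.eigh(S, subset_by_index=[R - (k + 1), R - 1])
    # eigh returns ascending order; flip to descending
    evals = evals[::-1]
    evecs = evecs[:, ::-1]
    # eigenvectors of P: psi = D_a^-1/2 v; normalize so the trivial
    # (lambda = 1) eigenvector is the constant vector
    psi = evecs * d_a_isqrt[:, None]
    psi = psi / psi[:, [0]]
    lam = evals[1:]
    if np.any(lam >= 1.0 - 1e-12):
        raise ValueError("non-trivial eigenvalue numerically >= 1; affinity graph may be disconnected")
    # non-positive eigenvalues carry no diffusion structure (they arise only
    # in fully degenerate graphs); collapse those components to the origin
    lam_pos = np.clip(lam, 0.0, None)
    if t == 0:
        scale = lam_pos / (1.0 - lam_pos)
    else:
        scale = np.power(lam_pos, t)
    G = psi[:, 1:] * scale[None, :]
    # deterministic sign convention: largest-magnitude element positive
    for j in range(G.shape[1]):
        i = np.argmax(np.abs(G[:, j]))
        if G[i, j] < 0:
            G[:, j] = -G[:, j]
    return GradientSet(G, lam, {"alpha": alpha, "t": t, "n_components": k})


def diffusion_embedding(W: np.ndarray, k: int = 3, alpha: float = 0.5, t: float = 0) -> GradientSet:
    """Embed a non-negative affinity matrix directly (no thresholding)."""
    return _diffusion_embedding_core(np.asarray(W, dtype=float), k=k, alpha=alpha, t=t)


def embed_msn(msn, n_components=3, density=0.10, alpha=0.5, t=0) -> GradientSet:
    """Full per-subject pipeline: threshold -> cosine affinity -> embedding."""
    dg = DiffusionGradients(
        n_components=n_components, density=density, alpha=alpha, diffusion_time=t
    ).fit(msn)
    return dg.to_gradient_set()


def build_template(msns, n_components=3, density=0.10, alpha=0.5, t=0) -> GradientSet:
    """Group template: element-wise mean MSN run through the same pipeline."""
    msns = list(msns)
    if not msns:
        raise ValueError("need at least one MSN to build a template")
    shapes = {m.values.shape for m in msns}
    if len(shapes) != 1:
        raise ValueError("all MSNs must have identical shape/region order")
    mean_msn = MSNMatrix(
        np.mean([m.values for m in msns], axis=0), list(msns[0].region_ids)
    )
    return embed_msn(mean_msn, n_components=n_components, density=density, alpha=alpha, t=t)


class ProcrustesAlignment(BaseEstimator, TransformerMixin):
    """Orthogonal Procrustes alignment of individual gradients to a template.

    Rotation + reflection only: no scaling and no translation, so all
    inter-region distances (hence every dispersion statistic) are preserved.
    """

    def fit(self, template):
        T = template.gradients if isinstance(template, GradientSet) else np.asarray(template)
        self.template_ = np.asarray(T, dtype=float)
        return self

    def transform(self, X):
        G = X.gradients if isinstance(X, GradientSet) else np.asarray(X, dtype=float)
        if G.shape != self.template_.shape:
            raise ValueError(
                f"shape mismatch: gradients {G.shape} vs template {self.template_.shape}"
            )
        Q, _ = linalg.orthogonal_procrustes(G, self.template_)
        return G @ Q


def align_gradients(individual: GradientSet, template: GradientSet) -> GradientSet:
    """Align one subject's gradients to the template; eigenvalues unchanged."""
    aligned = ProcrustesAlignment().fit(template).transform(individual)
    return GradientSet(aligned, individual.eigenvalues.copy(), dict(individual.params))
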