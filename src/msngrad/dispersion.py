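"""Dispersion statistics on 3-D gradient coordinates.

Three statistics summarize how spread out regions are in gradient space:

- global dispersion: sum of squared Euclidean distances of all regions to
  the global centroid (whole-brain integration/segregation index);
- within-network dispersion: per network, sum of squared distances of member
  regions to that network's centroid (uniformity of profiles in a network);
- between-network dispersion: Euclidean distance between network centroids
  (differentiation of two networks from one another).

Per-region analyses use manifold eccentricity, the unsquared distance of a
region from the global centroid. Centroids are unweighted region means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DispersionTable",
    "manifold_eccentricity",
    "global_dispersion",
    "within_network_dispersion",
    "between_network_dispersion",
    "dispersion_table",
]


def _coords(g) -> np.ndarray:
    G = getattr(g, "gradients", g)
    G = np.asarray(G, dtype=float)
    if G.ndim == 1:
        G = G[:, None]
    if not np.all(np.isfinite(G)):
        raise ValueError("gradient coordinates must be finite")
    return G


def _check_labels(labels, n_regions) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.shape[0] != n_regions:
        raise ValueError(
            f"partition covers {labels.shape[0]} regions but gradients have {n_regions}"
        )
    return labels


@dataclass
class DispersionTable:
    """All dispersion statistics for one subject."""

    global_dispersion: float
    eccentricity: np.ndarray        # (R,)
    within: np.ndarray              # (K,)
    between: np.ndarray             # (K, K), symmetric, zero diagonal
    global_centroid: np.ndarray     # (k,)
    network_centroids: np.ndarray   # (K, k)
    network_names: list


def manifold_eccentricity(g):
    """Per-region Euclidean distance from the global centroid.

    Returns
    -------
    eccentricity : ndarray of shape (R,)
    centroid : ndarray of shape (k,)
    """
    G = _coords(g)
    centroid = G.mean(axis=0)
    return np.linalg.norm(G - centroid, axis=1), centroid


def global_dispersion(g) -> float:
    """Sum of squared distances of all regions to the global centroid."""
    ecc, _ = manifold_eccentricity(g)
    return float(np.sum(ecc**2))


def within_network_dispersion(g, labels, names=None) -> np.ndarray:
    """Per network: sum of squared distances of members to the network centroid."""
    G = _coords(g)
    labels = _check_labels(labels, G.shape[0])
    if names is None:
        names = sorted(np.unique(labels).tolist())
    out = np.empty(len(names))
    for i, name in enumerate(names):
        mask = labels == name
        if not mask.any():
            raise ValueError(f"network {name!r} has no member regions")
        pts = G[mask]
        out[i] = np.sum((pts - pts.mean(axis=0)) ** 2)
    return out


def between_network_dispersion(g, labels, names=None) -> np.ndarray:
    """K x K matrix of Euclidean distances between network centroids."""
    G = _coords(g)
    labels = _check_labels(labels, G.shape[0])
    if names is None:
        names = sorted(np.unique(labels).tolist())
    centroids = np.stack([
        G[labels == name].mean(axis=0) if (labels == name).any()
        else _raise_empty(name)
        for name in names
    ])
    diff = centroids[:, None, :] - centroids[None, :, :]
    return np.linalg.norm(diff, axis=2)


def _raise_empty(name):
    raise ValueError(f"network {name!r} has no member regions")


def dispersion_table(g, partition) -> DispersionTable:
    """Compute every dispersion statistic for one subject's aligned gradients."""
    G = _coords(g)
    labels = _check_labels(partition.labels, G.shape[0])
    names = list(partition.names)
    codes = list(range(len(names)))   # labels store integer network codes
    ecc, centroid = manifold_eccentricity(G)
    within = within_network_dispersion(G, labels, codes)
    between = between_network_dispersion(G, labels, codes)
    net_centroids = np.stack([G[labels == c].mean(axis=0) for c in codes])
    return DispersionTable(
        global_dispersion=float(np.sum(ecc**2)),
        eccentricity=ecc,
        within=within,
        between=between,
        global_centroid=centroid,
        network_centroids=net_centroids,
        network_names=names,
    )
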