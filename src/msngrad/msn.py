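"""Morphometric similarity network (MSN) construction.

An MSN is a region x region Pearson-correlation matrix computed over a small
set of structural morphometric features (by default five: gray matter volume,
surface area, cortical thickness, Gaussian curvature, mean curvature). Each
feature is first z-scored across regions so that features on very different
scales contribute equally; the correlation between two regions' normalized
feature vectors then measures how similar their morphometric profiles are.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["MSNMatrix", "zscore_features", "build_msn", "compare_msn"]


@dataclass
class MSNMatrix:
    """Square symmetric matrix of inter-regional morphometric similarity.

    Attributes
    ----------
    values : ndarray of shape (R, R)
        Pearson correlations in [-1, 1]; diagonal stored as 1 but excluded
        from all downstream computations.
    region_ids : list of str
        Region identifiers in row/column order.
    """

    values: np.ndarray
    region_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("MSN values must be a square matrix")
        if not self.region_ids:
            self.region_ids = [f"r{i:04d}" for i in range(self.values.shape[0])]
        if len(self.region_ids) != self.values.shape[0]:
            raise ValueError("region_ids length must match matrix size")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


def zscore_features(X: np.ndarray) -> np.ndarray:
    """Z-score each feature column across regions (sample sd, n-1 denominator).

    Raises
    ------
    ValueError
        If any feature has zero variance across regions.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("feature table must be 2-D (regions x features)")
    sd = X.std(axis=0, ddof=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(f"feature column(s) {bad.tolist()} have zero variance across regions")
    return (X - X.mean(axis=0)) / sd


def build_msn(X: np.ndarray, region_ids=None) -> MSNMatrix:
    """Build one subject's MSN from a regions x features table.

    Columns are z-scored across regions, then entry (i, j) is the Pearson
    correlation of region i's and region j's F-length normalized feature
    vectors. Works for any F >= 2 (5-feature default, 7-feature variant).

    Raises
    ------
    ValueError
        If F < 2, a feature has zero variance across regions, or any region's
        normalized feature vector is constant (correlation undefined).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a 2-D table with at least 2 features")
    Z = zscore_features(X)
    row_sd = Z.std(axis=1, ddof=1)
    bad = np.flatnonzero(row_sd == 0)
    if bad.size:
        raise ValueError(
            f"region(s) {bad.tolist()} have a constant normalized feature vector; "
            "Pearson correlation is undefined"
        )
    C = np.corrcoef(Z)
    C = np.clip(C, -1.0, 1.0)
    C = (C + C.T) / 2.0
    np.fill_diagonal(C, 1.0)
    return MSNMatrix(C, list(region_ids) if region_ids is not None else [])


def compare_msn(m1: MSNMatrix, m2: MSNMatrix) -> float:
    """Pearson correlation of two MSNs' strictly-upper-triangle vectors.

    Used to quantify agreement between MSN variants (e.g., 5- vs 7-feature).
    """
    if m1.values.shape != m2.values.shape:
        raise ValueError("MSN shape mismatch")
    if m1.region_ids != m2.region_ids:
        raise ValueError("MSN region ordering differs")
    iu = np.triu_indices(m1.n_regions, k=1)
    return float(np.corrcoef(m1.values[iu], m2.values[iu])[0, 1])
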