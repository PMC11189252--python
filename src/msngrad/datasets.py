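"""Synthetic cohorts with known ground-truth structure.

The generator emulates the data layout of a multi-site lifespan structural
MRI study: per subject a regions x features morphometric table, metadata
(age, sex, site, estimated total intracranial volume), a region-to-network
partition with spherical parcel coordinates, behavioral scores generated
under a known mediation model, and spatially autocorrelated annotation maps
(gene-expression- or receptor-like) with a controllable correlation to a
target map.

Subject feature tables follow a latent-factor model: one latent factor per
network plus a global factor, with loadings that are smooth functions of
age. Regions sharing a network factor correlate more strongly than regions
that share only the global factor, so the expected population MSN has
higher within- than between-network correlation whenever the within-network
coupling exceeds the between-network coupling — and the age modulation of
the couplings induces known dispersion trajectories for the downstream
stages to recover. Site effects are additive per-feature mean shifts plus a
multiplicative noise scale, i.e. exactly the location/scale family that
ComBat harmonization models.

Everything is deterministic given (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

__all__ = [
    "CohortSpec",
    "SubjectFeatures",
    "NetworkPartition",
    "generate_partition",
    "generate_cohort",
    "generate_behavior",
    "generate_annotation_maps",
]

#: age strata used for windowed analyses (years): late childhood to
#: adolescence, young adulthood, middle adulthood, late adulthood
AGE_WINDOWS = ((8.0, 19.0), (20.0, 39.0), (40.0, 59.0), (60.0, 89.0))


@dataclass
class NetworkPartition:
    """Region-to-network assignment plus optional spherical parcel coordinates."""

    labels: np.ndarray                      # (R,) integer network index
    names: list                             # K network names
    coords: Optional[np.ndarray] = None     # (R, 3) unit vectors

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=float)
            norms = np.linalg.norm(self.coords, axis=1)
            if not np.allclose(norms, 1.0, atol=1e-9):
                raise ValueError("parcel coordinates must be unit-norm")

    @property
    def n_regions(self) -> int:
        return self.labels.shape[0]

    @property
    def n_networks(self) -> int:
        return len(self.names)


@dataclass
class SubjectFeatures:
    """One subject's morphometric table plus metadata."""

    subject_id: str
    age: float
    sex: str
    site: str
    etiv: float
    X: np.ndarray   # (R, F) morphometric features, pre-normalization

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        if not np.all(np.isfinite(self.X)):
            raise ValueError(f"subject {self.subject_id}: non-finite feature values")


@dataclass
class CohortSpec:
    """Generative parameters for a synthetic cohort.

    ``within_coupling`` / ``between_coupling`` map age (years) to the
    loading of the network-specific / global latent factor; larger within
    coupling tightens within-network similarity relative to between.
    """

    n_subjects: int = 60
    n_regions: int = 150
    n_features: int = 5
    n_networks: int = 4
    age_range: tuple = (8.0, 89.0)
    site_labels: Sequence[str] = ("siteA", "siteB", "siteC")
    site_offsets: dict = field(
        default_factory=lambda: {"siteA": 0.0, "siteB": 0.3, "siteC": -0.2}
    )                                                    # site -> additive shift
    site_scales: dict = field(
        default_factory=lambda: {"siteA": 1.0, "siteB": 1.1, "siteC": 0.9}
    )                                                    # site -> noise scale
    within_coupling: Callable[[float], float] = lambda age: 0.5 + 0.008 * age
    between_coupling: Callable[[float], float] = lambda age: 0.5
    noise_sd: float = 1.0
    #: smooth spatial field amplitude; float or callable(age). Rising with
    #: age makes within-network profiles increasingly heterogeneous, the
    #: generative analogue of communities dispersing across the lifespan
    spatial_coupling: object = staticmethod(lambda age: 0.8 + 0.008 * age)
    spatial_scale: float = 0.8                           # RBF width (chordal distance)
    n_spatial_factors: int = 12                          # rank of the spatial field
    noise_smooth_scale: float = 0.3                      # RBF width of smooth noise part
    noise_smooth_mix: float = 0.5                        # fraction of noise variance smooth
    sex_effect: float = 0.1                              # additive shift for males
    etiv_params: tuple = (1.5e6, 1.5e5, 1.0e5)           # mean, sd, male shift (mm^3)
    age_strata: Optional[Sequence[tuple]] = None         # uniform over age_range if None
    seed: int = 0

    def validate(self):
        if self.n_networks > self.n_regions:
            raise ValueError("n_networks cannot exceed n_regions")
        if self.n_subjects < 1 or self.n_features < 2:
            raise ValueError("need at least 1 subject and 2 features")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic low-discrepancy layout of n points on the unit sphere."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def generate_partition(n_regions: int, n_networks: int, seed: int = 0) -> NetworkPartition:
    """Contiguous balanced-as-possible network blocks with clustered coordinates.

    Labels are contiguous index blocks (remainder regions go to the first
    blocks). Coordinates come from a single Fibonacci lattice over the whole
    sphere, whose points descend monotonically in latitude with index, so
    the contiguous blocks become adjacent latitude bands: same-network
    regions are spatially clustered (the property spin-test nulls rely on)
    while neighboring networks share a border, as cortical parcellations do.
    """
    if n_networks < 1:
        raise ValueError("n_networks must be >= 1")
    if n_networks > n_regions:
        raise ValueError("n_networks cannot exceed n_regions")
    sizes = np.full(n_networks, n_regions // n_networks)
    sizes[: n_regions % n_networks] += 1
    labels = np.repeat(np.arange(n_networks), sizes)
    coords = _fibonacci_sphere(n_regions)
    coords /= np.linalg.norm(coords, axis=1, keepdims=True)
    names = [f"net{b}" for b in range(n_networks)]
    return NetworkPartition(labels=labels, names=names, coords=coords)


def generate_cohort(spec: CohortSpec, partition: NetworkPartition) -> list:
    """Draw a cohort of SubjectFeatures under the latent-factor model.

    For subject s with age t, region r in network k(r) and feature f:

        X[r, f] = w_in(t) * U[k(r), f] + w_bt(t) * V[f]
                  + w_sp * (Phi @ W_s)[r, f]
                  + sex/eTIV shifts + site offset + scale(site) * noise

    with U, V, W_s standard-normal latent factors redrawn per subject. Phi
    is a fixed low-rank basis of a spatial RBF kernel on the parcel sphere
    (rows scaled to unit average power), so the third term is a smooth
    spatial field: spatially adjacent regions correlate regardless of their
    network. It emulates the smooth decline of morphometric similarity
    across network borders seen in real cortex — without it the population
    mean MSN is exactly block structured and its top-10% thresholded graph
    disconnects into the networks, which real group-average similarity
    matrices do not do.

    The noise itself is an equal-parts mix (``noise_smooth_mix``) of a
    spatially smooth component (RBF width ``noise_smooth_scale``) and
    independent noise, emulating the spatial autocorrelation of
    morphometric measurement error; this keeps each individual's
    thresholded similarity graph connected across network borders.
    """
    spec.validate()
    if partition.n_regions != spec.n_regions:
        raise ValueError("partition region count must match spec.n_regions")
    rng = np.random.default_rng(spec.seed)
    R, F = spec.n_regions, spec.n_features
    labels = partition.labels
    sites = list(spec.site_labels)

    if spec.age_strata:
        strata = list(spec.age_strata)
        which = rng.integers(0, len(strata), size=spec.n_subjects)
        ages = np.array([rng.uniform(*strata[w]) for w in which])
    else:
        ages = rng.uniform(spec.age_range[0], spec.age_range[1], size=spec.n_subjects)
    sexes = rng.choice(["F", "M"], size=spec.n_subjects)
    site_idx = rng.integers(0, len(sites), size=spec.n_subjects)
    etiv_mean, etiv_sd, etiv_male = spec.etiv_params
    etivs = rng.normal(etiv_mean, etiv_sd, size=spec.n_subjects)
    etivs += np.where(sexes == "M", etiv_male, 0.0)

    # fixed spatial structure (deterministic given the partition geometry):
    # low-rank smooth population field + smooth-noise Cholesky factor
    w_sp_fn = (
        spec.spatial_coupling
        if callable(spec.spatial_coupling)
        else (lambda age, _c=spec.spatial_coupling: _c)
    )
    q = 0
    Lnoise = None
    if partition.coords is not None:
        d2 = np.sum(
            (partition.coords[:, None, :] - partition.coords[None, :, :]) ** 2, axis=2
        )
        if any(w_sp_fn(a) > 0 for a in np.linspace(*spec.age_range, 5)):
            q = min(spec.n_spatial_factors, R)
            Kern = np.exp(-d2 / (2.0 * spec.spatial_scale**2))
            evals, evecs = np.linalg.eigh(Kern)
            Phi = evecs[:, -q:] * np.sqrt(np.maximum(evals[-q:], 0.0))
            Phi /= np.sqrt((Phi**2).sum(axis=1).mean())
        if 0 < spec.noise_smooth_mix <= 1:
            Kn = spec.noise_smooth_mix * np.exp(
                -d2 / (2.0 * spec.noise_smooth_scale**2)
            ) + (1.0 - spec.noise_smooth_mix) * np.eye(R)
            Lnoise = np.linalg.cholesky(Kn + 1e-10 * np.eye(R))

    cohort = []
    for s in range(spec.n_subjects):
        age = float(ages[s])
        w_in = float(spec.within_coupling(age))
        w_bt = float(spec.between_coupling(age))
        if not (np.isfinite(w_in) and np.isfinite(w_bt)):
            raise ValueError(f"non-finite coupling value at age {age:.2f}")
        U = rng.standard_normal((partition.n_networks, F))
        V = rng.standard_normal(F)
        noise = rng.standard_normal((R, F))
        if Lnoise is not None:
            noise = Lnoise @ noise
        site = sites[site_idx[s]]
        scale = float(spec.site_scales.get(site, 1.0))
        X = w_in * U[labels] + w_bt * V[None, :] + spec.noise_sd * scale * noise
        if q:
            w_sp = float(w_sp_fn(age))
            if not np.isfinite(w_sp):
                raise ValueError(f"non-finite spatial coupling at age {age:.2f}")
            X += w_sp * (Phi @ rng.standard_normal((q, F)))
        X += float(spec.site_offsets.get(site, 0.0))
        if sexes[s] == "M":
            X += spec.sex_effect
        cohort.append(
            SubjectFeatures(
                subject_id=f"sub-{s:04d}",
                age=age,
                sex=str(sexes[s]),
                site=site,
                etiv=float(etivs[s]),
                X=X,
            )
        )
    return cohort


def _zscore(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    sd = v.std()
    if sd == 0:
        raise ValueError("cannot z-score a constant vector")
    return (v - v.mean()) / sd


def generate_behavior(
    cohort,
    mediator_values=None,
    a: float = 0.5,
    b: float = 0.4,
    c_prime: float = 0.8,
    noise_sd: float = 1.0,
    seed: int = 0,
):
    """Behavioral scores under a known mediation model.

    outcome = c_prime * z(age) + b * z(mediator) + noise. When
    ``mediator_values`` is None the mediator is itself generated as
    a * z(age) + noise, so the true path coefficients (a, b, c') are known.

    Returns
    -------
    mediator : ndarray of shape (n,)
    score : ndarray of shape (n,)
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    ages = np.array([s.age for s in cohort], dtype=float)
    z_age = _zscore(ages)
    if mediator_values is None:
        mediator = a * z_age + noise_sd * rng.standard_normal(len(cohort))
    else:
        mediator = np.asarray(mediator_values, dtype=float)
        if mediator.shape[0] != len(cohort):
            raise ValueError("mediator_values length must equal cohort size")
    if mediator.std() == 0:
        if b != 0:
            raise ValueError("mediator is constant but b is nonzero")
        zm = np.zeros(len(cohort))
    else:
        zm = _zscore(mediator)
    score = c_prime * z_age + b * zm + noise_sd * rng.standard_normal(len(cohort))
    return mediator, score


def generate_annotation_maps(
    partition: NetworkPartition,
    n_maps: int,
    target_map=None,
    rho: float = 0.0,
    smoothing_scale: float = 0.5,
    n_correlated: int = 1,
    seed: int = 0,
) -> np.ndarray:
    """Spatially autocorrelated annotation maps (gene- or receptor-like).

    Maps are Gaussian noise smoothed over the parcel sphere with an RBF
    kernel of width ``smoothing_scale`` (chordal distance units; 0 disables
    smoothing). The first ``n_correlated`` maps are constructed to have
    sample correlation exactly ``rho`` with ``target_map`` (noise component
    orthogonalized against the target before mixing). All columns are
    z-scored across regions.
    """
    if not -1.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [-1, 1]")
    if partition.coords is None:
        raise ValueError("partition must carry parcel coordinates")
    rng = np.random.default_rng(seed)
    R = partition.n_regions
    raw = rng.standard_normal((R, n_maps))
    if smoothing_scale > 0:
        d2 = np.sum(
            (partition.coords[:, None, :] - partition.coords[None, :, :]) ** 2, axis=2
        )
        K = np.exp(-d2 / (2.0 * smoothing_scale**2))
        K /= K.sum(axis=1, keepdims=True)
        raw = K @ raw

    if target_map is not None and n_correlated > 0:
        t = np.asarray(target_map, dtype=float)
        if t.shape[0] != R:
            raise ValueError("target_map length must equal region count")
        zt = _zscore(t)
        for j in range(min(n_correlated, n_maps)):
            e = raw[:, j] - raw[:, j].mean()
            e = e - (e @ zt) / (zt @ zt) * zt   # orthogonalize against target
            if np.linalg.norm(e) > 0 and abs(rho) < 1.0:
                e = _zscore(e)
                raw[:, j] = rho * zt + np.sqrt(1.0 - rho**2) * e
            else:
                raw[:, j] = rho * zt
    out = (raw - raw.mean(axis=0)) / raw.std(axis=0)
    return out
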