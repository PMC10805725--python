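"""K*-means time-domain feature learning and pseudo-inverse unmixing.

A time-resolved non-radiative signal is treated as a vector in R^n whose
*shape* — not its amplitude or polarity — identifies the absorbing
structure.  K*-means is a K-means variant adapted to this reading:

* the distance between two signals is the **sine of the angle** between
  them, so scaled or inverted copies of a shape are at distance zero and
  orthogonal shapes are maximally distant;
* a cluster centroid is the **principal component of the cluster unioned
  with its negation**, which makes the learned shape resilient to noise
  and indifferent to signal polarity.

The K learned centroids f_1..f_K form the columns of a feature matrix F;
per-pixel feature amplitudes are obtained by applying the Moore–Penrose
pseudo-inverse of F to each time-domain signal (the least-squares mixing
weights), yielding K feature images m_f1..m_fK.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from .signals import ChannelImage, TDSignalRaster, TimeWindow

__all__ = [
    "ZeroVectorError",
    "FeatureSet",
    "FeatureImages",
    "ClusterAssignment",
    "angular_distance",
    "pairwise_angular_distance",
    "update_centroid",
    "kstar_cluster",
    "unmix",
    "learn_features",
    "save_featureset",
    "load_featureset",
    "feature_channel_names",
]

logger = logging.getLogger(__name__)

#: signals with norm below DEAD_PIXEL_REL x median norm carry no usable shape
DEAD_PIXEL_REL = 1e-3
#: relative singular-value cutoff for the pseudo-inverse
PINV_RCOND = 1e-10
#: default bounds on the examined cluster counts
K_BOUNDS = (2, 6)


class ZeroVectorError(ValueError):
    """A zero vector has no direction; angular distance is undefined."""


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------


def angular_distance(x: np.ndarray, y: np.ndarray) -> float:
    """Sine of the acute angle between the lines spanned by ``x`` and ``y``.

    Scale- and sign-invariant: ``d(ax, by) == d(x, y)`` for any nonzero
    ``a, b``.  Zero for collinear vectors, one for orthogonal vectors.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("vectors must have the same length")
    nx = np.linalg.norm(x)
    ny = np.linalg.norm(y)
    if nx == 0.0 or ny == 0.0:
        raise ZeroVectorError("angular distance undefined for a zero vector")
    c = float(np.dot(x, y) / (nx * ny))
    c = min(1.0, max(-1.0, c))
    return float(np.sqrt(max(0.0, 1.0 - c * c)))


def pairwise_angular_distance(S: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Angular distances between rows of ``S`` (m, n) and rows of ``C`` (k, n).

    Rows must be nonzero (pre-filter dead pixels).
    """
    S = np.asarray(S, dtype=float)
    C = np.asarray(C, dtype=float)
    sn = np.linalg.norm(S, axis=1)
    cn = np.linalg.norm(C, axis=1)
    if np.any(sn == 0) or np.any(cn == 0):
        raise ZeroVectorError("zero vector in pairwise angular distance")
    G = (S / sn[:, None]) @ (C / cn[:, None]).T
    return np.sqrt(np.clip(1.0 - G * G, 0.0, 1.0))


def _sign_normalize(v: np.ndarray) -> np.ndarray:
    """Orient a unit vector so its largest-magnitude element is positive."""
    i = int(np.argmax(np.abs(v)))
    return -v if v[i] < 0 else v


def update_centroid(member_signals: np.ndarray) -> np.ndarray:
    """Principal direction of the members unioned with their negation.

    Equivalently the leading eigenvector of the scatter matrix
    ``sum_s s s^T`` (the union with negations has zero mean, so the
    principal component reduces to the leading right singular vector of
    the stacked member matrix).  Returned unit-norm, oriented so the
    largest-magnitude element is positive.
    """
    M = np.atleast_2d(np.asarray(member_signals, dtype=float))
    norms = np.linalg.norm(M, axis=1)
    if np.all(norms == 0):
        raise ZeroVectorError("all member signals are zero")
    # leading right singular vector of M == leading eigenvector of M^T M
    _, _, Vh = np.linalg.svd(M, full_matrices=False)
    return _sign_normalize(Vh[0])


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class FeatureSet:
    """K unit-norm centroid shapes plus fit metadata."""

    K: int
    centroids: np.ndarray  # (K, n_samples)
    subset_size: int = 0
    seed: int = 0
    n_iter: int = 0
    converged: bool = False
    inertia: float = float("nan")
    inertia_history: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float)
        if self.centroids.shape[0] != self.K:
            raise ValueError("centroid count must equal K")
        norms = np.linalg.norm(self.centroids, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("centroids must be unit-norm")

    @property
    def n_samples(self) -> int:
        return self.centroids.shape[1]

    @property
    def feature_matrix(self) -> np.ndarray:
        """The n_samples x K matrix F whose columns are the centroids."""
        return self.centroids.T.copy()


@dataclass
class ClusterAssignment:
    labels: np.ndarray  # (m,) cluster index in [0, K)
    distances: np.ndarray  # (m,) angular distance to the assigned centroid

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.distances = np.asarray(self.distances, dtype=float)
        if self.labels.shape != self.distances.shape:
            raise ValueError("labels and distances must align")
        if self.distances.size and (
            self.distances.min() < -1e-12 or self.distances.max() > 1 + 1e-12
        ):
            raise ValueError("distances must lie in [0, 1]")


@dataclass
class FeatureImages:
    """Ordered feature amplitude maps m_f1..m_fK with their provenance."""

    images: list[ChannelImage]
    provenance: FeatureSet = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self.provenance is not None and len(self.images) != self.provenance.K:
            raise ValueError("image count must equal FeatureSet.K")

    def __len__(self) -> int:
        return len(self.images)


def feature_channel_names(K: int) -> list[str]:
    return [f"m_f{i + 1}" for i in range(K)]


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------


def _farthest_point_init(
    Shat: np.ndarray, K: int, rng: np.random.Generator, norms: np.ndarray
) -> np.ndarray:
    """Seed centroids: energy-weighted farthest-point picking.

    The first seed is sampled with probability proportional to squared
    signal norm; each further seed maximizes (normalized norm)^2 x
    (min angular distance to the seeds so far)^2.  Weighting by energy
    matches the amplitude-weighted centroid update and keeps weak noisy
    pixels — which are angularly far from everything — from hijacking the
    initialization.  Deterministic given the generator state.
    """
    m = Shat.shape[0]
    w = norms**2
    first = int(rng.choice(m, p=w / w.sum()))
    chosen = [first]
    wn = (norms / norms.max()) ** 2
    dmin = pairwise_angular_distance(Shat, Shat[first][None, :])[:, 0]
    for _ in range(1, K):
        nxt = int(np.argmax(wn * dmin**2))
        chosen.append(nxt)
        d_new = pairwise_angular_distance(Shat, Shat[nxt][None, :])[:, 0]
        dmin = np.minimum(dmin, d_new)
    return np.stack([_sign_normalize(Shat[i]) for i in chosen], axis=0)


def kstar_cluster(
    signals: np.ndarray,
    K: int,
    seed: int = 0,
    max_iter: int = 100,
    tol: float = 1e-4,
    k_bounds: tuple[int, int] = K_BOUNDS,
    n_init: int = 4,
) -> tuple[FeatureSet, ClusterAssignment]:
    """Cluster signal shapes with angular distance and PCA centroids.

    Alternates (i) assigning each signal to the centroid minimizing the
    sine-of-angle distance and (ii) recomputing each centroid as the
    principal component of its *raw* members unioned with their negation,
    until the largest centroid movement falls below ``tol`` or ``max_iter``
    is reached.  Assignment is scale-invariant; using unnormalized members
    in the centroid update weights each signal by its squared amplitude,
    which is what makes the learned shapes resilient to weak noisy pixels.

    ``n_init`` independent seeded initializations (farthest-point seeding
    from a random first pick) are run and the solution with the lowest
    final inertia is kept; the whole procedure is deterministic for a
    fixed ``seed``.  ``inertia`` is the sum of squared angular distances.
    """
    S = np.asarray(signals, dtype=float)
    if S.ndim != 2:
        raise ValueError("signals must be a 2-D array (m, n_samples)")
    m = S.shape[0]
    if not (k_bounds[0] <= K <= k_bounds[1]):
        raise ValueError(f"K={K} outside bounds {k_bounds}")
    if K > m:
        raise ValueError(f"K={K} exceeds the number of signals ({m})")
    if n_init < 1:
        raise ValueError("n_init must be >= 1")
    norms = np.linalg.norm(S, axis=1)
    if np.any(norms == 0):
        raise ZeroVectorError(
            "zero signals present; filter dead pixels before clustering"
        )
    Shat = S / norms[:, None]
    best: tuple[FeatureSet, ClusterAssignment] | None = None
    for trial in range(n_init):
        rng = np.random.default_rng(np.random.SeedSequence([seed, trial]))
        fs, asn = _lloyd(S, Shat, K, rng, max_iter, tol)
        if best is None or fs.inertia < best[0].inertia:
            best = (fs, asn)
    fs, asn = best
    fs.seed = seed
    return fs, asn


def _lloyd(
    S: np.ndarray,
    Shat: np.ndarray,
    K: int,
    rng: np.random.Generator,
    max_iter: int,
    tol: float,
) -> tuple[FeatureSet, ClusterAssignment]:
    m = S.shape[0]
    C = _farthest_point_init(Shat, K, rng, np.linalg.norm(S, axis=1))
    inertia = np.inf
    converged = False
    it = 0
    inertia_history: list[float] = []
    for it in range(1, max_iter + 1):
        D = pairwise_angular_distance(Shat, C)
        labels = np.argmin(D, axis=1)
        dist = D[np.arange(m), labels]
        # re-seed empty clusters from the worst-fit signal
        for k in range(K):
            if not np.any(labels == k):
                far = int(np.argmax(dist))
                logger.warning(
                    "cluster %d empty at iteration %d; re-seeding from signal %d",
                    k,
                    it,
                    far,
                )
                C[k] = _sign_normalize(Shat[far])
                labels[far] = k
                dist[far] = 0.0
        inertia = float(np.sum(dist**2))
        inertia_history.append(inertia)
        C_new = np.stack(
            [update_centroid(S[labels == k]) for k in range(K)], axis=0
        )
        movement = max(angular_distance(C[k], C_new[k]) for k in range(K))
        C = C_new
        if movement < tol:
            converged = True
            break

    D = pairwise_angular_distance(Shat, C)
    labels = np.argmin(D, axis=1)
    dist = D[np.arange(m), labels]
    inertia = float(np.sum(dist**2))
    inertia_history.append(inertia)
    fs = FeatureSet(
        K=K,
        centroids=C,
        subset_size=m,
        n_iter=it,
        converged=converged,
        inertia=inertia,
        inertia_history=inertia_history,
    )
    return fs, ClusterAssignment(labels=labels, distances=dist)


# ---------------------------------------------------------------------------
# unmixing
# ---------------------------------------------------------------------------


def _check_full_rank(fs: FeatureSet) -> None:
    F = fs.feature_matrix
    s = np.linalg.svd(F, compute_uv=False)
    if s[-1] <= PINV_RCOND * s[0]:
        G = np.abs(fs.centroids @ fs.centroids.T)
        np.fill_diagonal(G, -1.0)
        i, j = np.unravel_index(int(np.argmax(G)), G.shape)
        raise ValueError(
            f"feature matrix is rank-deficient: centroids m_f{i + 1} and "
            f"m_f{j + 1} are near-collinear (|cos| = {G[i, j]:.6f})"
        )


def unmix(
    raster: TDSignalRaster,
    fs: FeatureSet,
    window: TimeWindow,
    dead_pixel_rel: float = DEAD_PIXEL_REL,
) -> FeatureImages:
    """Per-pixel least-squares feature amplitudes a = F^+ s.

    Each baseline-subtracted time-domain signal restricted to ``window`` is
    multiplied by the Moore–Penrose pseudo-inverse of the feature matrix
    (SVD with relative cutoff), giving the least-squares solution of
    ``F a ≈ s``.  Pixels whose signal norm falls below
    ``dead_pixel_rel`` x the median norm are assigned zero amplitudes.
    """
    window.validate(raster.n_samples)
    if len(window) != fs.n_samples:
        raise ValueError(
            f"window length {len(window)} != centroid length {fs.n_samples}"
        )
    _check_full_rank(fs)
    base = raster.baseline()
    X = (raster.signals[:, :, window.slice] - base[:, :, None]).reshape(
        -1, fs.n_samples
    )
    Fp = np.linalg.pinv(fs.feature_matrix, rcond=PINV_RCOND)
    A = X @ Fp.T  # (m, K)
    norms = np.linalg.norm(X, axis=1)
    med = float(np.median(norms))
    if med > 0:
        A[norms < dead_pixel_rel * med] = 0.0
    maps = A.reshape(raster.height, raster.width, fs.K)
    images = [
        ChannelImage(name=nm, values=maps[:, :, k])
        for k, nm in enumerate(feature_channel_names(fs.K))
    ]
    return FeatureImages(images=images, provenance=fs)


def learn_features(
    raster: TDSignalRaster,
    window: TimeWindow,
    K: int,
    subset_fraction: float = 0.1,
    seed: int = 0,
    max_iter: int = 100,
    tol: float = 1e-4,
    k_bounds: tuple[int, int] = K_BOUNDS,
    dead_pixel_rel: float = DEAD_PIXEL_REL,
    n_init: int = 4,
) -> FeatureSet:
    """Learn a FeatureSet from a seeded random subset of pixel signals.

    Signals are restricted to ``window`` and baseline-subtracted; dead
    pixels (norm below ``dead_pixel_rel`` x median norm of the subset) are
    excluded from learning.
    """
    if not (0 < subset_fraction <= 1):
        raise ValueError("subset_fraction must be in (0, 1]")
    window.validate(raster.n_samples)
    base = raster.baseline()
    X = (raster.signals[:, :, window.slice] - base[:, :, None]).reshape(
        -1, len(window)
    )
    m = X.shape[0]
    if subset_fraction < 1.0:
        rng = np.random.default_rng(seed)
        size = max(K, int(round(subset_fraction * m)))
        idx = np.sort(rng.choice(m, size=min(size, m), replace=False))
        X = X[idx]
    norms = np.linalg.norm(X, axis=1)
    med = float(np.median(norms))
    usable = X[norms >= max(dead_pixel_rel * med, np.finfo(float).tiny)]
    if usable.shape[0] < K:
        raise ValueError(
            f"only {usable.shape[0]} usable signals after dead-pixel "
            f"filtering; need at least K={K}"
        )
    fs, _ = kstar_cluster(
        usable, K, seed=seed, max_iter=max_iter, tol=tol, k_bounds=k_bounds,
        n_init=n_init,
    )
    fs.subset_size = usable.shape[0]
    return fs


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def save_featureset(path: str | Path, fs: FeatureSet) -> None:
    """HDF5 centroid dataset plus a JSON metadata sidecar (round-trip exact)."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("centroids", data=fs.centroids)
        f.attrs["K"] = fs.K
    meta = {
        "K": fs.K,
        "subset_size": fs.subset_size,
        "seed": fs.seed,
        "n_iter": fs.n_iter,
        "converged": fs.converged,
        "inertia": fs.inertia,
        "sign_convention": "largest-magnitude element positive",
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))


def load_featureset(path: str | Path) -> FeatureSet:
    path = Path(path)
    with h5py.File(path, "r") as f:
        centroids = f["centroids"][...]
        K = int(f.attrs["K"])
    meta_path = path.with_suffix(path.suffix + ".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return FeatureSet(
        K=K,
        centroids=centroids,
        subset_size=int(meta.get("subset_size", 0)),
        seed=int(meta.get("seed", 0)),
        n_iter=int(meta.get("n_iter", 0)),
        converged=bool(meta.get("converged", False)),
        inertia=float(meta.get("inertia", float("nan"))),
    )
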