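"""Spectral decomposition of reaching trajectories into movement fragments.

The affinity between two trajectory samples is the connectivity kernel
``exp(-d^2)`` of the homogeneous sub-Riemannian distance (or of a
(weighted) Euclidean distance for the baselines).  The affinity matrix is
normalised into the random-walk Markov matrix ``P = D^-1 A`` (Meila-Shi),
whose leading eigenvectors embed the samples; k-means in that embedding
yields the clusters.  On reaching data the recovered clusters are the
acceleration and deceleration phases of the movement -- the "movement
fragments" whose neural counterparts are the coherent population states
observed in motor cortex, with transitions at the extrema of the
tangential speed.

Temporal contiguity of the clusters is never enforced; it is a measured
property of the result.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import connected_components

from .distance import DistanceWeights, pairwise_distance_matrix
from .space import Trajectory

__all__ = [
    "AffinityMatrix",
    "ClusterResult",
    "affinity_matrix",
    "markov_normalize",
    "choose_k",
    "spectral_cluster",
    "kmeans_baseline",
    "segment_boundaries",
    "mean_boundary_error",
]

#: A is treated as numerically block-diagonal when the affinity mass
#: outside the blocks is below this fraction of the total mass.
BLOCK_MASS_TOL = 1e-6


@dataclass
class AffinityMatrix:
    """Symmetric kernel matrix over trajectory samples, unit diagonal."""

    values: np.ndarray
    method: str = "subriemannian"

    def __post_init__(self) -> None:
        A = np.asarray(self.values, float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("affinity matrix must be square")
        if not np.allclose(A, A.T, atol=1e-12):
            raise ValueError("affinity matrix must be symmetric")
        if np.min(A) < 0 or np.max(A) > 1 + 1e-12:
            raise ValueError("affinity entries must lie in [0, 1]")
        self.values = A

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class ClusterResult:
    """Labels, spectrum, embedding and segment boundaries of one clustering."""

    labels: np.ndarray
    eigenvalues: np.ndarray
    embedding: np.ndarray
    boundaries: np.ndarray
    k: int
    method: str
    meta: dict = field(default_factory=dict)


def affinity_matrix(traj: Trajectory, distance: str = "subriemannian",
                    w: DistanceWeights | None = None) -> AffinityMatrix:
    """Pairwise connectivity kernel over all samples of a trajectory.

    Requires the kinematic fields (theta, v, a) to be populated -- lift a
    raw planar path with ``kinematics_from_path`` first.
    """
    if len(traj) < 4:
        raise ValueError("need at least 4 samples to build an affinity matrix")
    if w is None:
        w = DistanceWeights()
    if not traj.meta.get("lifted") and np.allclose(traj.data[:, 3:], 0.0):
        raise ValueError(
            "trajectory has empty kinematic fields; run kinematics_from_path first")
    dm = pairwise_distance_matrix(traj, distance, w)
    with np.errstate(over="ignore"):
        A = np.exp(-dm**2 / (2.0 * w.sigma**2))
    A[np.isinf(dm)] = 0.0
    np.fill_diagonal(A, 1.0)
    A = 0.5 * (A + A.T)
    return AffinityMatrix(A, method=distance)


def markov_normalize(A: AffinityMatrix | np.ndarray) -> np.ndarray:
    """Random-walk normalisation ``P = D^-1 A`` with row sums d_i.

    P is row-stochastic and similar to the symmetric matrix
    ``D^-1/2 A D^-1/2``, so its spectrum is real with maximum eigenvalue 1.
    """
    vals = A.values if isinstance(A, AffinityMatrix) else np.asarray(A, float)
    d = vals.sum(axis=1)
    if np.any(d <= 0):
        raise ValueError("all row sums must be positive")
    return vals / d[:, None]


def _markov_spectrum(A: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Leading eigenpairs of D^-1 A via the similar symmetric problem."""
    d = A.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d)
    sym = A * inv_sqrt[:, None] * inv_sqrt[None, :]
    evals, evecs = np.linalg.eigh(sym)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    # map back to eigenvectors of P = D^-1 A
    u = inv_sqrt[:, None] * evecs[:, :k]
    return evals, u


def _is_block_diagonal(A: np.ndarray) -> tuple[bool, np.ndarray]:
    """Detect numerical block structure: connected components of the
    thresholded affinity with negligible off-block mass."""
    mask = A > BLOCK_MASS_TOL
    n_comp, comp = connected_components(mask, directed=False)
    if n_comp < 2:
        return False, comp
    off_mass = 0.0
    for c in range(n_comp):
        idx = comp == c
        off_mass += A[np.ix_(idx, ~idx)].sum()
    return off_mass < BLOCK_MASS_TOL * A.sum(), comp


def choose_k(eigenvalues: np.ndarray, k_max: int = 8,
             override: int | None = None) -> int:
    """Cluster count from the largest gap in the leading eigenvalues.

    A configured override always wins.
    """
    if override is not None:
        return int(override)
    ev = np.asarray(eigenvalues, float)
    if len(ev) < 2:
        raise ValueError("need at least two eigenvalues")
    m = min(k_max, len(ev))
    gaps = ev[: m - 1] - ev[1:m]
    return int(np.argmax(gaps)) + 1


def _farthest_point_seeds(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = X.shape[0]
    seeds = [int(rng.integers(n))]
    d2 = np.sum((X - X[seeds[0]]) ** 2, axis=1)
    for _ in range(1, k):
        nxt = int(np.argmax(d2))
        seeds.append(nxt)
        d2 = np.minimum(d2, np.sum((X - X[nxt]) ** 2, axis=1))
    return np.array(seeds)


def _lloyd(X: np.ndarray, centers: np.ndarray, max_iter: int = 300) -> tuple[np.ndarray, float]:
    for _ in range(max_iter):
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        labels = np.argmin(d2, axis=1)
        new_centers = centers.copy()
        for j in range(centers.shape[0]):
            pts = X[labels == j]
            if len(pts):
                new_centers[j] = pts.mean(axis=0)
        if np.allclose(new_centers, centers):
            centers = new_centers
            break
        centers = new_centers
    d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    labels = np.argmin(d2, axis=1)
    inertia = float(d2[np.arange(len(X)), labels].sum())
    return labels, inertia


def _kmeans(X: np.ndarray, k: int, seed: int, restarts: int = 10) -> np.ndarray:
    """Deterministic k-means: farthest-point seeding from a fixed seed,
    several restarts, best inertia kept."""
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds the number of samples {X.shape[0]}")
    rng = np.random.default_rng(seed)
    best_labels, best_inertia = None, math.inf
    for _ in range(restarts):
        centers = X[_farthest_point_seeds(X, k, rng)]
        labels, inertia = _lloyd(X, centers)
        if inertia < best_inertia - 1e-12:
            best_labels, best_inertia = labels, inertia
    return best_labels


def _relabel_by_first_occurrence(labels: np.ndarray) -> np.ndarray:
    """Relabel so that cluster ids are ordered by time of first occurrence."""
    mapping = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


def segment_boundaries(labels: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Midpoints between consecutive samples where the label changes."""
    labels = np.asarray(labels)
    t = np.asarray(t, float)
    change = np.nonzero(labels[1:] != labels[:-1])[0]
    return 0.5 * (t[change] + t[change + 1])


def spectral_cluster(traj: Trajectory, k: int | None = None,
                     distance: str = "subriemannian",
                     w: DistanceWeights | None = None,
                     seed: int = 0, k_max: int = 8) -> ClusterResult:
    """Spectral clustering of a trajectory with the chosen kernel.

    The samples are embedded in the leading-k eigenvectors of the Markov
    matrix ``P = D^-1 A`` (of A itself when A is numerically
    block-diagonal, where the normalisation step may be skipped) and
    clustered with deterministic seeded k-means.  ``k=None`` selects the
    count by the eigengap.  Labels are contiguous in time of first
    occurrence; boundaries are the label-change midpoints.
    """
    if w is None:
        w = DistanceWeights()
    aff = affinity_matrix(traj, distance, w)
    A = aff.values
    if k is not None and k > aff.n:
        raise ValueError(f"k={k} exceeds number of samples {aff.n}")
    is_block, comp = _is_block_diagonal(A)
    if is_block:
        evals = np.sort(np.linalg.eigvalsh(A))[::-1]
        n_blocks = comp.max() + 1
        kk = k if k is not None else int(n_blocks)
        if kk == n_blocks:
            labels = comp.copy()
            embedding = np.eye(int(n_blocks))[comp]
        else:
            _, evecs = np.linalg.eigh(A)
            embedding = evecs[:, ::-1][:, :kk]
            labels = _kmeans(embedding, kk, seed)
    else:
        evals, emb_full = _markov_spectrum(A, aff.n)
        kk = k if k is not None else choose_k(evals, k_max)
        embedding = emb_full[:, :kk]
        labels = _kmeans(embedding, kk, seed)
    labels = _relabel_by_first_occurrence(labels)
    bounds = segment_boundaries(labels, traj.t)
    return ClusterResult(labels=labels, eigenvalues=np.asarray(evals),
                         embedding=embedding, boundaries=bounds, k=int(kk),
                         method=f"spectral-{distance}",
                         meta={"seed": seed, "block_diagonal": bool(is_block)})


def kmeans_baseline(traj: Trajectory, k: int,
                    w: DistanceWeights | None = None,
                    seed: int = 0) -> ClusterResult:
    """k-means directly on the weighted 6-tuples (the Euclidean baseline).

    Features are the raw coordinates scaled by the weights ``c1..c6`` in
    coordinate order (time divided by ``t_norm``); the direction is
    unwrapped along the trajectory so the angle behaves linearly.  This is
    the generalised Euclidean metric the spectral method is contrasted
    with: it ignores the differential constraints between the variables.
    """
    if w is None:
        w = DistanceWeights()
    c = np.asarray(w.c, float)
    theta_unwrapped = np.unwrap(traj.theta)
    X = np.column_stack([
        traj.t / w.t_norm, traj.x, traj.y, theta_unwrapped, traj.v, traj.a,
    ]) * c[None, :]
    labels = _relabel_by_first_occurrence(_kmeans(X, k, seed))
    bounds = segment_boundaries(labels, traj.t)
    return ClusterResult(labels=labels, eigenvalues=np.array([]),
                         embedding=X, boundaries=bounds, k=int(k),
                         method="kmeans-weighted-euclidean",
                         meta={"seed": seed})


def mean_boundary_error(boundaries: np.ndarray, extrema_times: np.ndarray,
                        dt: float) -> float:
    """Mean distance (in samples) from each predicted fragment boundary to
    the nearest extremum of the tangential speed.

    Scores how well a decomposition places its transitions at the speed
    minima and maxima: spurious boundaries inside an acceleration or
    deceleration phase raise the error.  Returns +inf when no boundary
    was predicted at all (an undecomposed movement).
    """
    boundaries = np.asarray(boundaries, float)
    extrema_times = np.asarray(extrema_times, float)
    if len(boundaries) == 0 or len(extrema_times) == 0:
        return math.inf
    errs = [np.min(np.abs(extrema_times - b)) for b in boundaries]
    return float(np.mean(errs) / dt)
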