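"""K-means over feature columns under the correlation distance 1 - |r|.

Features that are (anti-)correlated — collinear in the loose sense used for
high-dimensional expression matrices — should land in the same cluster, so
the metric is one minus the absolute Pearson coefficient between a feature
column and a centroid.  Centroids are updated as the arithmetic mean of
their member columns; Pearson correlation is invariant to the scale and
offset of its arguments, so the mean needs no re-standardization.

Because the mean centroid is not the exact minimizer of the correlation
distance, one extra rule keeps the objective trace honest: if an iteration
would increase J, the update is reverted and iteration stops.  In practice
the trace simply decreases until the change falls below ``eta``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import LabeledDataset

__all__ = [
    "KMeansParams",
    "ClusteringResult",
    "pearson_distance",
    "kmeans_correlation",
]


@dataclass
class KMeansParams:
    """k clusters; stop when |J_t - J_{t-1}| < eta or after max_iter.

    ``n_init`` independent random initializations are run and the result
    with the lowest final objective kept — random centroid seeding can
    place two centroids inside one correlated block, a local optimum a
    single Lloyd run cannot leave.
    """

    k: int = 10
    eta: float = 0.02
    max_iter: int = 300
    n_init: int = 10
    seed: int | np.random.Generator | None = None

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be at least 1")
        if self.eta <= 0:
            raise ValueError("eta must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be at least 1")
        if self.n_init < 1:
            raise ValueError("n_init must be at least 1")


@dataclass
class ClusteringResult:
    """Cluster index per feature, centroids and the objective trace."""

    assignment: np.ndarray
    centroids: np.ndarray
    objective_trace: list[float] = field(default_factory=list)
    n_iter: int = 0

    @property
    def k(self) -> int:
        return self.centroids.shape[0]

    def members(self, c: int) -> np.ndarray:
        """Global feature indices assigned to cluster ``c``."""
        return np.flatnonzero(self.assignment == c)


def _abs_corr_rows(F: np.ndarray, C: np.ndarray) -> np.ndarray:
    """|Pearson r| between every row of F and every row of C.

    Zero-variance rows on either side get correlation 0 by convention.
    """
    def center_scale(M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        Mc = M - M.mean(axis=1, keepdims=True)
        norm = np.linalg.norm(Mc, axis=1)
        ok = norm > 0
        Mc[ok] /= norm[ok, None]
        Mc[~ok] = 0.0
        return Mc, ok

    Fc, _ = center_scale(np.array(F, dtype=float))
    Cc, _ = center_scale(np.array(C, dtype=float))
    R = Fc @ Cc.T
    return np.clip(np.abs(R), 0.0, 1.0)


def pearson_distance(f: np.ndarray, a: np.ndarray) -> float:
    """Correlation distance 1 - |pearson(f, a)|, in [0, 1].

    If either vector has zero variance the correlation is taken as 0 and
    the distance is 1.
    """
    f = np.asarray(f, dtype=float)
    a = np.asarray(a, dtype=float)
    if f.shape != a.shape:
        raise ValueError(f"dimension mismatch: f {f.shape}, a {a.shape}")
    if f.size < 2:
        raise ValueError("need vectors of length >= 2")
    r = _abs_corr_rows(f[None, :], a[None, :])[0, 0]
    return float(1.0 - r)


def _assign(F: np.ndarray, C: np.ndarray) -> tuple[np.ndarray, float]:
    """Nearest-centroid assignment (ties to the lowest cluster index) and J."""
    Dist = 1.0 - _abs_corr_rows(F, C)
    assignment = Dist.argmin(axis=1)
    J = float(Dist[np.arange(F.shape[0]), assignment].sum())
    return assignment, J


def kmeans_correlation(
    ds: LabeledDataset, params: KMeansParams
) -> ClusteringResult:
    """Lloyd-style k-means on feature columns with the 1 - |r| metric.

    Runs ``n_init`` restarts and keeps the clustering with the lowest final
    objective.  Deterministic given the seed.
    """
    F = ds.X.T  # features as rows, shape (d, n)
    d, n = F.shape
    if n < 2:
        raise ValueError("need at least 2 samples to correlate features")
    if params.k > d:
        raise ValueError(f"k={params.k} exceeds feature count d={d}")
    rng = (
        params.seed
        if isinstance(params.seed, np.random.Generator)
        else np.random.default_rng(params.seed)
    )
    best: ClusteringResult | None = None
    for _ in range(params.n_init):
        res = _kmeans_single(F, params, rng)
        if best is None or res.objective_trace[-1] < best.objective_trace[-1]:
            best = res
    return best


def _kmeans_single(
    F: np.ndarray, params: KMeansParams, rng: np.random.Generator
) -> ClusteringResult:
    """One Lloyd run from a fresh random initialization.

    Initial centroids are k distinct feature columns drawn uniformly
    without replacement.  Each iteration recomputes centroids as member
    means, then reassigns every feature to its nearest centroid, repairing
    any empty cluster by reseeding it with the feature farthest from its
    own centroid.  The returned assignment is the nearest-centroid
    assignment of the returned centroids (up to repair), and the recorded
    objective J is evaluated on exactly that (centroids, assignment) pair,
    so the trace is non-increasing by construction: an iteration that
    would increase J is reverted and iteration stops.
    """
    d = F.shape[0]
    k = params.k
    C = F[rng.choice(d, size=k, replace=False)].copy()

    assignment, J = _assign_repaired(F, C, k)
    trace = [J]
    n_iter = 1
    for n_iter in range(2, params.max_iter + 1):
        C_new = _update_centroids(F, assignment, C)
        new_assignment, J_new = _assign_repaired(F, C_new, k)
        if J_new > trace[-1]:
            break  # mean update overshot under the correlation metric; stop
        assignment, C = new_assignment, C_new
        trace.append(J_new)
        if abs(trace[-1] - trace[-2]) < params.eta:
            break
    return ClusteringResult(
        assignment=assignment,
        centroids=C,
        objective_trace=trace,
        n_iter=n_iter,
    )


def _assign_repaired(
    F: np.ndarray, C: np.ndarray, k: int
) -> tuple[np.ndarray, float]:
    """Nearest-centroid assignment with empty-cluster repair, and its J.

    An empty cluster is reseeded with the feature farthest from its own
    centroid (first farthest on ties, drawn only from clusters that keep
    at least one member), so all k clusters stay populated as the subspace
    construction requires.
    """
    Dist = 1.0 - _abs_corr_rows(F, C)
    assignment = Dist.argmin(axis=1)
    own = Dist[np.arange(F.shape[0]), assignment]
    for c in range(k):
        if not np.any(assignment == c):
            counts = np.bincount(assignment, minlength=k)
            movable = counts[assignment] > 1
            cand = np.where(movable, own, -np.inf)
            far = int(np.argmax(cand))
            assignment[far] = c
            own[far] = float(Dist[far, c])
    J = float(Dist[np.arange(F.shape[0]), assignment].sum())
    return assignment, J


def _update_centroids(
    F: np.ndarray, assignment: np.ndarray, C: np.ndarray
) -> np.ndarray:
    """Arithmetic mean of member columns per cluster."""
    C_new = np.empty_like(C)
    for c in range(C.shape[0]):
        members = assignment == c
        C_new[c] = F[members].mean(axis=0) if members.any() else C[c]
    return C_new
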