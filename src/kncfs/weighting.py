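"""Per-partition importance factor alpha.

After a partition's spliced weight vector is min-max normalized to [0, 1],
features are admitted to the evaluation set when their normalized weight
exceeds a random threshold.  The thresholds are not independent: a
correlated Gaussian draw ``v = L @ theta`` (L the Cholesky factor of the
feature correlation matrix R) is pushed through an erf-based CDF, so groups
of correlated features receive similar thresholds and are admitted or
rejected together.  The admitted feature set is then scored by a 3-nearest-
neighbor classifier; its accuracy is the partition's weighting factor
alpha in [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import erf, ndtr
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.neighbors import KNeighborsClassifier

from .data import LabeledDataset

__all__ = [
    "CorrelationMatrix",
    "ThresholdSample",
    "PartitionScore",
    "correlation_matrix",
    "sample_correlated_threshold",
    "minmax_normalize",
    "select_features",
    "partition_alpha",
]

logger = logging.getLogger("kncfs")


@dataclass
class CorrelationMatrix:
    """Pairwise Pearson coefficients between feature columns.

    ``jitter`` records the diagonal inflation actually applied before the
    Cholesky factorization succeeded (0.0 until a factorization is done).
    """

    R: np.ndarray
    jitter: float = 0.0


@dataclass
class ThresholdSample:
    """One correlated threshold draw: raw normals, correlated v, CDF u."""

    theta: np.ndarray
    v: np.ndarray
    u: np.ndarray


@dataclass
class PartitionScore:
    """Weighting factor alpha and the feature set it was scored on."""

    alpha: float
    selected: np.ndarray
    classifier_spec: str


def correlation_matrix(ds: LabeledDataset) -> CorrelationMatrix:
    """Symmetric unit-diagonal matrix of pairwise feature correlations.

    Zero-variance columns correlate 0 with every other column and 1 with
    themselves, keeping R well formed for degenerate inputs.
    """
    if ds.n_samples < 2:
        raise ValueError("need at least 2 samples")
    X = ds.X
    Xc = X - X.mean(axis=0)
    norm = np.linalg.norm(Xc, axis=0)
    ok = norm > 0
    Z = np.zeros_like(Xc)
    Z[:, ok] = Xc[:, ok] / norm[ok]
    R = Z.T @ Z
    np.fill_diagonal(R, 1.0)
    R = np.clip(R, -1.0, 1.0)
    R = (R + R.T) / 2.0
    return CorrelationMatrix(R=R)


def _cholesky_with_jitter(
    R: np.ndarray, eps0: float = 1e-8, eps_cap: float = 1e-2
) -> tuple[np.ndarray, float]:
    """Cholesky factor of R + eps*I, escalating eps tenfold until it works.

    R is singular whenever there are more features than samples, so some
    jitter is the rule rather than the exception on wide matrices.
    """
    try:
        return np.linalg.cholesky(R), 0.0
    except np.linalg.LinAlgError:
        pass
    eps = eps0
    eye = np.eye(R.shape[0])
    while eps <= eps_cap:
        try:
            L = np.linalg.cholesky(R + eps * eye)
            logger.debug("cholesky succeeded with jitter %.1e", eps)
            return L, eps
        except np.linalg.LinAlgError:
            eps *= 10.0
    raise np.linalg.LinAlgError(
        f"correlation matrix not factorizable even with jitter {eps_cap:g}"
    )


def sample_correlated_threshold(
    R: CorrelationMatrix, seed=None, cdf: str = "erf"
) -> ThresholdSample:
    """Draw correlated thresholds u in (0, 1) from the correlation structure.

    theta is an iid standard-normal vector; v = L @ theta carries the
    correlation structure of R (plus the jitter actually applied).  The
    default transform is ``u = (1 + erf(v)) / 2`` — the CDF of a normal
    with variance one-half; ``cdf="gauss"`` uses the standard-normal CDF
    instead.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    L, eps = _cholesky_with_jitter(R.R)
    R.jitter = eps
    theta = rng.standard_normal(R.R.shape[0])
    v = L @ theta
    if cdf == "erf":
        u = 0.5 * (1.0 + erf(v))
    elif cdf == "gauss":
        u = ndtr(v)
    else:
        raise ValueError(f"cdf must be 'erf' or 'gauss', got {cdf!r}")
    # erf is strictly inside (-1, 1) for finite v, so u is inside (0, 1);
    # clip only guards float round-off at |v| ~ 6.
    tiny = np.finfo(float).tiny
    u = np.clip(u, tiny, 1.0 - np.finfo(float).epsneg)
    return ThresholdSample(theta=theta, v=v, u=u)


def minmax_normalize(w: np.ndarray) -> np.ndarray:
    """Map weights affinely onto [0, 1]; a constant vector maps to all 0.5.

    The 0.5 fallback keeps threshold selection possible when a partition
    learns a flat weight vector (0.5 is the midpoint of the threshold
    range, so roughly half the features remain selectable).
    """
    w = np.asarray(w, dtype=float)
    lo, hi = w.min(), w.max()
    if hi == lo:
        return np.full_like(w, 0.5)
    return (w - lo) / (hi - lo)


def select_features(pi: np.ndarray, u: np.ndarray | ThresholdSample) -> np.ndarray:
    """Indices k with pi_k strictly greater than its threshold u_k."""
    thresholds = u.u if isinstance(u, ThresholdSample) else np.asarray(u)
    pi = np.asarray(pi, dtype=float)
    if pi.shape != thresholds.shape:
        raise ValueError(
            f"length mismatch: pi {pi.shape}, u {thresholds.shape}"
        )
    return np.flatnonzero(pi > thresholds)


def partition_alpha(
    ds: LabeledDataset,
    selected: np.ndarray,
    seed=None,
    protocol: str = "cv3",
) -> PartitionScore:
    """Score the selected feature set with a 3-nearest-neighbor classifier.

    Default protocol is stratified 3-fold cross-validated accuracy with
    folds fixed by the seed; ``protocol="resub"`` scores resubstitution
    accuracy (fit and evaluate on the full data).  An empty selection gets
    alpha = 0: a partition whose thresholds admitted nothing contributes
    nothing.  If the smallest class has fewer samples than folds, the fold
    count drops to that class count (minimum 2; below that, resubstitution).
    """
    selected = np.asarray(selected, dtype=int)
    if selected.size == 0:
        return PartitionScore(
            alpha=0.0, selected=selected, classifier_spec="knn3 (unused)"
        )
    ds.require_supervised()
    Xs = ds.X[:, selected]
    knn = KNeighborsClassifier(n_neighbors=min(3, ds.n_samples - 1))
    if protocol == "resub":
        alpha = float(knn.fit(Xs, ds.y).score(Xs, ds.y))
        spec = "knn3, resubstitution accuracy"
    elif protocol == "cv3":
        min_class = int(np.bincount(ds.y).min()) if np.issubdtype(
            ds.y.dtype, np.integer
        ) else int(np.unique(ds.y, return_counts=True)[1].min())
        folds = min(3, min_class)
        if folds < 2:
            logger.info(
                "smallest class has %d sample(s); falling back to "
                "resubstitution alpha", min_class,
            )
            alpha = float(knn.fit(Xs, ds.y).score(Xs, ds.y))
            spec = "knn3, resubstitution accuracy (class too small for CV)"
        else:
            if folds < 3:
                logger.info("reducing alpha CV folds to %d", folds)
            rng = (
                seed
                if isinstance(seed, np.random.Generator)
                else np.random.default_rng(seed)
            )
            skf = StratifiedKFold(
                n_splits=folds,
                shuffle=True,
                random_state=int(rng.integers(2**31 - 1)),
            )
            scores = cross_val_score(knn, Xs, ds.y, cv=skf, scoring="accuracy")
            alpha = float(scores.mean())
            spec = f"knn3, stratified {folds}-fold CV accuracy"
    else:
        raise ValueError(f"protocol must be 'cv3' or 'resub', got {protocol!r}")
    return PartitionScore(alpha=alpha, selected=selected, classifier_spec=spec)
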