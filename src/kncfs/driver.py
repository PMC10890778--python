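"""End-to-end drivers: plain NCFS, random-subspace NCFS, and KNCFS.

KNCFS runs M iterations.  Each iteration clusters the feature columns by
correlation, builds a cluster-stratified partition of s subspaces (so
collinear features are spread out), fits NCFS independently inside every
subspace, splices the local weights into a full-length vector w_i,
min-max normalizes it, thresholds it against a correlated Gaussian draw,
scores the admitted feature set with a 3-NN classifier to get alpha_i, and
accumulates

    w  <-  w + alpha_i * w_i

starting from the all-ones vector.  The final ranking sorts w descending
(ties broken by ascending feature index); the all-ones start is a constant
offset and never changes the ordering.

The ablation variants: ``rb-ncfs`` uses uniform random partitions and the
plain average of the M spliced vectors (no clustering, no alpha); ``ncfs``
is a single full-space fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import logging

import numpy as np

from .data import LabeledDataset, standardize
from .ncfs import NCFSParams, fit_ncfs
from .cluster import KMeansParams, kmeans_correlation
from .partition import (
    FeaturePartition,
    LocalWeights,
    build_random_partition,
    build_partition_from_clusters,
    splice_weights,
)
from .weighting import (
    correlation_matrix,
    sample_correlated_threshold,
    minmax_normalize,
    select_features,
    partition_alpha,
)

__all__ = ["KNCFSConfig", "IterationRecord", "RankedFeatures", "fit"]

logger = logging.getLogger("kncfs")

MODES = ("ncfs", "rb-ncfs", "kncfs")


@dataclass
class KNCFSConfig:
    """Configuration of a fit run.

    M partitions, s subspaces per partition and k feature clusters all
    default to 10.  ``alpha_eval`` picks the protocol scoring each
    partition's selected features (``cv3`` or ``resub``); ``cdf`` picks the
    threshold transform (``erf`` or ``gauss``).
    """

    M: int = 10
    s: int = 10
    k: int = 10
    mode: str = "kncfs"
    seed: int = 0
    ncfs: NCFSParams = field(default_factory=NCFSParams)
    kmeans: KMeansParams = field(default_factory=KMeansParams)
    alpha_eval: str = "cv3"
    cdf: str = "erf"

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.M < 1:
            raise ValueError("M must be at least 1")
        if self.s < 1:
            raise ValueError("s must be at least 1")
        if self.k < 1:
            raise ValueError("k must be at least 1")

    def validate_for(self, d: int) -> None:
        """Check dimension-dependent constraints against a d-feature dataset."""
        if self.mode in ("rb-ncfs", "kncfs") and self.s > d:
            raise ValueError(
                f"s={self.s} subspaces cannot exceed d={d} features"
            )
        if self.mode == "kncfs" and self.k > d:
            raise ValueError(
                f"k={self.k} clusters cannot exceed d={d} features"
            )

    def to_dict(self) -> dict:
        out = asdict(self)
        out["kmeans"].pop("seed", None)  # streams come from the master seed
        return out


@dataclass
class IterationRecord:
    """Provenance of one accumulation iteration."""

    iteration: int
    alpha: float | None
    w_i: np.ndarray
    subspaces: list[list[int]]
    selected: list[int] | None
    objective_traces: list[list[float]]
    kmeans_trace: list[float] | None = None


@dataclass
class RankedFeatures:
    """Final weights, the descending-weight ranking, and provenance."""

    w_final: np.ndarray
    order: np.ndarray
    feature_ids: list[str]
    mode: str
    provenance: list[IterationRecord] = field(default_factory=list)

    def top(self, m: int) -> np.ndarray:
        """Global indices of the m highest-weight features."""
        return self.order[:m]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "feature_id": [self.feature_ids[i] for i in self.order],
                "weight": self.w_final[self.order],
                "rank": np.arange(1, self.order.size + 1),
            }
        )


def _rank(w: np.ndarray) -> np.ndarray:
    """Indices sorted by descending weight; ties by ascending index."""
    # lexsort's last key is primary; negate for descending weight
    return np.lexsort((np.arange(w.size), -w))


def _fit_subspaces(
    ds: LabeledDataset,
    part: FeaturePartition,
    ncfs_params: NCFSParams,
) -> tuple[np.ndarray, list[list[float]]]:
    """NCFS on every subspace; spliced full-length weights + traces."""
    locals_: list[LocalWeights] = []
    traces: list[list[float]] = []
    for sub in part.subspaces:
        res = fit_ncfs(ds.subset_features(sub), ncfs_params)
        locals_.append(LocalWeights(w=res.w, indices=sub))
        traces.append(res.objective_trace)
    return splice_weights(locals_, ds.n_features), traces


def fit(ds: LabeledDataset, cfg: KNCFSConfig) -> RankedFeatures:
    """Run the configured variant and rank all features.

    The input is z-scored first (zero-variance columns become all-zero).
    One master seed spawns an independent child stream per iteration, and
    within an iteration separate streams for clustering initialization,
    partition permutations, the threshold draw theta and the alpha CV
    folds — so changing M never perturbs earlier iterations.  Deterministic
    given (dataset, config).
    """
    cfg.validate_for(ds.n_features)
    ds = standardize(ds)
    ds.require_supervised()
    d = ds.n_features
    master = np.random.SeedSequence(cfg.seed)
    iter_seeds = master.spawn(cfg.M)

    if cfg.mode == "ncfs":
        res = fit_ncfs(ds, cfg.ncfs)
        record = IterationRecord(
            iteration=1,
            alpha=None,
            w_i=res.w,
            subspaces=[list(range(d))],
            selected=None,
            objective_traces=[res.objective_trace],
        )
        return RankedFeatures(
            w_final=res.w,
            order=_rank(res.w),
            feature_ids=list(ds.feature_ids),
            mode=cfg.mode,
            provenance=[record],
        )

    if cfg.mode == "kncfs":
        # feature correlations do not change across iterations
        R = correlation_matrix(ds)

    w = np.ones(d)
    records: list[IterationRecord] = []
    w_list: list[np.ndarray] = []
    for i in range(cfg.M):
        streams = iter_seeds[i].spawn(4)
        rng_cluster = np.random.default_rng(streams[0])
        rng_partition = np.random.default_rng(streams[1])
        rng_theta = np.random.default_rng(streams[2])
        rng_alpha = np.random.default_rng(streams[3])

        if cfg.mode == "kncfs":
            km = KMeansParams(
                k=cfg.k,
                eta=cfg.kmeans.eta,
                max_iter=cfg.kmeans.max_iter,
                seed=rng_cluster,
            )
            clustering = kmeans_correlation(ds, km)
            part = build_partition_from_clusters(
                clustering, cfg.s, seed=rng_partition
            )
            kmeans_trace = list(clustering.objective_trace)
        else:  # rb-ncfs
            part = build_random_partition(d, cfg.s, seed=rng_partition)
            kmeans_trace = None

        w_i, traces = _fit_subspaces(ds, part, cfg.ncfs)
        w_list.append(w_i)

        if cfg.mode == "kncfs":
            pi = minmax_normalize(w_i)
            thresholds = sample_correlated_threshold(
                R, seed=rng_theta, cdf=cfg.cdf
            )
            selected = select_features(pi, thresholds)
            score = partition_alpha(
                ds, selected, seed=rng_alpha, protocol=cfg.alpha_eval
            )
            logger.debug(
                "iteration %d: |selected|=%d alpha=%.3f",
                i + 1, selected.size, score.alpha,
            )
            w = w + score.alpha * w_i
            records.append(
                IterationRecord(
                    iteration=i + 1,
                    alpha=score.alpha,
                    w_i=w_i,
                    subspaces=[sub.tolist() for sub in part.subspaces],
                    selected=selected.tolist(),
                    objective_traces=traces,
                    kmeans_trace=kmeans_trace,
                )
            )
        else:
            records.append(
                IterationRecord(
                    iteration=i + 1,
                    alpha=None,
                    w_i=w_i,
                    subspaces=[sub.tolist() for sub in part.subspaces],
                    selected=None,
                    objective_traces=traces,
                )
            )

    if cfg.mode == "rb-ncfs":
        w = np.mean(w_list, axis=0)

    return RankedFeatures(
        w_final=w,
        order=_rank(w),
        feature_ids=list(ds.feature_ids),
        mode=cfg.mode,
        provenance=records,
    )
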