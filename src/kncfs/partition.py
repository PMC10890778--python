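"""Feature partitions: disjoint covers of the feature index set.

A partition splits the d feature indices into s non-empty, pairwise
disjoint subspaces whose union is the full index set.  Two constructions
are provided:

* :func:`build_random_partition` — a uniform random permutation dealt out
  in consecutive blocks (the plain random-subspace scheme).
* :func:`build_partition_from_clusters` — cluster-stratified: every feature
  cluster contributes an equal share ``floor(n_c / s)`` to each subspace,
  so correlated features are spread across subspaces instead of piling into
  one; cluster leftovers go to uniformly random subspaces.

:func:`splice_weights` inverts the split, reassembling per-subspace weight
vectors into one full-length vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cluster import ClusteringResult

__all__ = [
    "FeaturePartition",
    "LocalWeights",
    "build_random_partition",
    "build_partition_from_clusters",
    "splice_weights",
]


@dataclass
class FeaturePartition:
    """s lists of global feature indices covering {0..d-1} disjointly."""

    subspaces: list[np.ndarray]
    d: int

    def __post_init__(self) -> None:
        self.subspaces = [
            np.asarray(sub, dtype=int) for sub in self.subspaces
        ]
        self.validate()

    @property
    def s(self) -> int:
        return len(self.subspaces)

    def validate(self) -> None:
        """Assert the partition axioms: non-empty, disjoint, covering."""
        if any(sub.size == 0 for sub in self.subspaces):
            raise ValueError("empty subspace in partition")
        merged = np.concatenate(self.subspaces) if self.subspaces else (
            np.empty(0, dtype=int)
        )
        if merged.size != self.d or not np.array_equal(
            np.sort(merged), np.arange(self.d)
        ):
            raise ValueError(
                "subspaces must disjointly cover all feature indices"
            )


@dataclass
class LocalWeights:
    """A weight per feature of one subspace, with its global index map."""

    w: np.ndarray
    indices: np.ndarray

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        self.indices = np.asarray(self.indices, dtype=int)
        if self.w.shape != self.indices.shape:
            raise ValueError("weights and index map differ in length")


def _as_rng(seed) -> np.random.Generator:
    return (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )


def build_random_partition(d: int, s: int, seed=None) -> FeaturePartition:
    """Uniform random partition of d features into s subspaces.

    A random permutation is dealt in consecutive blocks of ``floor(d/s)``;
    the ``d mod s`` remaining features go one each to the first subspaces.
    Subspace sizes therefore differ by at most one.
    """
    if not 1 <= s <= d:
        raise ValueError(f"need 1 <= s <= d, got s={s}, d={d}")
    rng = _as_rng(seed)
    perm = rng.permutation(d)
    base, extra = divmod(d, s)
    subspaces: list[np.ndarray] = []
    start = 0
    for j in range(s):
        size = base + (1 if j < extra else 0)
        subspaces.append(perm[start:start + size])
        start += size
    return FeaturePartition(subspaces=subspaces, d=d)


def build_partition_from_clusters(
    clusters: ClusteringResult, s: int, seed=None
) -> FeaturePartition:
    """Cluster-stratified partition: equal shares of every cluster per subspace.

    For each cluster a random permutation of its members is cut into s
    contiguous blocks of ``floor(n_c/s)``; block j goes to subspace j.  Each
    leftover feature is then placed in an independently chosen uniform
    random subspace.  If a subspace still ends empty (possible when every
    cluster is smaller than s), it is repaired by moving one feature from
    the largest subspace.
    """
    if s < 1:
        raise ValueError("s must be at least 1")
    assignment = np.asarray(clusters.assignment)
    d = assignment.size
    if d == 0:
        raise ValueError("empty clustering")
    if s > d:
        raise ValueError(f"s={s} exceeds feature count d={d}")
    rng = _as_rng(seed)
    buckets: list[list[int]] = [[] for _ in range(s)]
    for c in range(clusters.k):
        members = np.flatnonzero(assignment == c)
        if members.size == 0:
            continue
        perm = members[rng.permutation(members.size)]
        share = members.size // s
        for j in range(s):
            buckets[j].extend(perm[j * share:(j + 1) * share].tolist())
        for leftover in perm[s * share:]:
            buckets[int(rng.integers(s))].append(int(leftover))
    # repair: no subspace may be empty
    for j in range(s):
        if not buckets[j]:
            largest = max(range(s), key=lambda b: len(buckets[b]))
            buckets[j].append(buckets[largest].pop())
    return FeaturePartition(
        subspaces=[np.asarray(b, dtype=int) for b in buckets], d=d
    )


def splice_weights(locals_: list[LocalWeights], d: int) -> np.ndarray:
    """Reassemble per-subspace weights into one full-length vector.

    The index maps must jointly cover {0..d-1} exactly once; the global
    weight of feature g is its local weight in the unique subspace
    containing g.
    """
    w = np.full(d, np.nan)
    seen = np.zeros(d, dtype=bool)
    for lw in locals_:
        if np.any(seen[lw.indices]):
            dup = lw.indices[seen[lw.indices]][0]
            raise ValueError(f"feature index {dup} appears in two subspaces")
        seen[lw.indices] = True
        w[lw.indices] = lw.w
    if not seen.all():
        missing = int(np.flatnonzero(~seen)[0])
        raise ValueError(f"feature index {missing} missing from all subspaces")
    return w
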