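"""Synthetic benchmark data and the feature-selection evaluation harness.

The generator emulates the two regimes the method targets:

* a handful of class-informative ("relevant") columns buried under many
  label-independent noise columns drawn from Normal(0, variance 5) — used
  for the success-rate benchmark, where a selector is judged by how many of
  the known-relevant features it ranks in the top-|relevant| positions;
* blocks of mutually correlated (collinear) columns built from one shared
  latent Gaussian per block — used to exercise the correlation clustering
  and the low-collinearity subspace construction.

The harness also scores a ranking's top-m features by stratified k-fold
cross-validation with four standard classifiers (3-NN, RBF-kernel SVC,
Gaussian naive Bayes, depth-5 decision tree), reporting mean +/- sd
accuracy and macro-F1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.naive_bayes import GaussianNB
from sklearn.tree import DecisionTreeClassifier
from sklearn.metrics import accuracy_score, f1_score

from .data import LabeledDataset
from .driver import RankedFeatures

__all__ = [
    "SyntheticSpec",
    "EvaluationResult",
    "make_dataset",
    "success_rate",
    "evaluate_selection",
]


@dataclass
class SyntheticSpec:
    """Recipe for a synthetic labeled dataset with known-relevant features.

    ``effect`` is the between-class mean separation of each relevant
    feature in units of its within-class standard deviation.  Noise
    features are iid Normal(noise_mean, noise_var) independent of the
    labels.  ``block_spec`` optionally appends collinear blocks, each a
    list entry ``(block_size, within_correlation)``; block members share a
    latent Gaussian so every within-block pair has correlation close to
    ``within_correlation``.  Blocks carry no label signal.
    """

    n: int = 100
    d_rel: int = 5
    n_classes: int = 2
    effect: float = 2.0
    n_noise: int = 100
    noise_mean: float = 0.0
    noise_var: float = 5.0
    block_spec: list[tuple[int, float]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2 * self.n_classes:
            raise ValueError("need n >= 2 * n_classes")
        if self.effect <= 0:
            raise ValueError("effect must be positive")
        if self.d_rel < 0 or self.n_noise < 0:
            raise ValueError("feature counts must be nonnegative")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.noise_var <= 0:
            raise ValueError("noise_var must be positive")
        for size, rho in self.block_spec:
            if size < 2 or not 0.0 <= rho < 1.0:
                raise ValueError(
                    f"invalid block ({size}, {rho}): need size >= 2 and "
                    "0 <= within_correlation < 1"
                )

    @property
    def d(self) -> int:
        return self.d_rel + self.n_noise + sum(b for b, _ in self.block_spec)


def make_dataset(spec: SyntheticSpec) -> tuple[LabeledDataset, np.ndarray]:
    """Generate (dataset, ground-truth relevant indices); bit-reproducible.

    Labels are balanced (class c gets every n_classes-th sample).  Relevant
    feature l for a sample of class c is Normal(mu_c, 1) with class means
    spread ``effect`` apart: mu_c = (c - (n_classes - 1)/2) * effect.
    Relevant columns come first, then noise, then any collinear blocks.
    """
    rng = np.random.default_rng(spec.seed)
    y = np.arange(spec.n) % spec.n_classes
    cols: list[np.ndarray] = []

    class_means = (
        np.arange(spec.n_classes) - (spec.n_classes - 1) / 2.0
    ) * spec.effect
    if spec.d_rel:
        rel = rng.standard_normal((spec.n, spec.d_rel))
        rel += class_means[y][:, None]
        cols.append(rel)
    if spec.n_noise:
        cols.append(
            rng.normal(
                spec.noise_mean,
                np.sqrt(spec.noise_var),
                size=(spec.n, spec.n_noise),
            )
        )
    for size, rho in spec.block_spec:
        latent = rng.standard_normal(spec.n)
        eps = rng.standard_normal((spec.n, size))
        # f_j = sqrt(rho)*g + sqrt(1-rho)*eps_j gives corr(f_i, f_j) = rho
        block = np.sqrt(rho) * latent[:, None] + np.sqrt(1.0 - rho) * eps
        cols.append(block)

    if not cols:
        raise ValueError("spec generates no features")
    X = np.hstack(cols)
    names = (
        [f"rel{i + 1}" for i in range(spec.d_rel)]
        + [f"noise{i + 1}" for i in range(spec.n_noise)]
        + [
            f"blk{b + 1}_{j + 1}"
            for b, (size, _) in enumerate(spec.block_spec)
            for j in range(size)
        ]
    )
    ds = LabeledDataset(X=X, y=y, feature_ids=names)
    return ds, np.arange(spec.d_rel)


def success_rate(
    ranked: RankedFeatures | np.ndarray, relevant: np.ndarray
) -> float:
    """Fraction of known-relevant features in the top-|relevant| positions.

    Accepts either a full :class:`RankedFeatures` or a plain index ordering
    (best feature first).  Invariant to strictly monotone reweighting since
    only the ordering enters.
    """
    order = ranked.order if isinstance(ranked, RankedFeatures) else (
        np.asarray(ranked, dtype=int)
    )
    relevant = np.asarray(relevant, dtype=int)
    if relevant.size == 0:
        raise ValueError("relevant set is empty")
    if relevant.size > order.size:
        raise ValueError("more relevant features than ranked features")
    top = set(order[: relevant.size].tolist())
    return len(top.intersection(relevant.tolist())) / relevant.size


@dataclass
class EvaluationResult:
    """Mean +/- sd accuracy and macro-F1 per classifier over folds x repeats."""

    acc: dict[str, tuple[float, float]]
    f1: dict[str, tuple[float, float]]
    m: int
    folds: int
    t: int

    def to_frame(self):
        import pandas as pd

        rows = []
        for name in self.acc:
            rows.append(
                {
                    "classifier": name,
                    "acc_mean": self.acc[name][0],
                    "acc_sd": self.acc[name][1],
                    "f1_mean": self.f1[name][0],
                    "f1_sd": self.f1[name][1],
                }
            )
        return pd.DataFrame(rows)


def _classifiers(seed: int) -> dict[str, object]:
    return {
        "knn": KNeighborsClassifier(n_neighbors=3),
        "svm": SVC(kernel="rbf", random_state=seed),
        "nb": GaussianNB(),
        "dt": DecisionTreeClassifier(max_depth=5, random_state=seed),
    }


def evaluate_selection(
    ds: LabeledDataset,
    ranked: RankedFeatures | np.ndarray,
    m: int,
    folds: int = 10,
    t: int = 10,
    f1_average: str = "macro",
    seed: int = 0,
) -> EvaluationResult:
    """CV accuracy and F1 of the top-m ranked features.

    For each of ``t`` repeats, runs stratified ``folds``-fold CV with the
    four benchmark classifiers on the columns the ranking puts first.  F1 is
    averaged one-vs-rest across classes (``macro`` by default, ``weighted``
    optional).  If the smallest class has fewer samples than ``folds``, the
    fold count is reduced to that class count.
    """
    order = ranked.order if isinstance(ranked, RankedFeatures) else (
        np.asarray(ranked, dtype=int)
    )
    if m > ds.n_features:
        raise ValueError(f"m={m} exceeds feature count {ds.n_features}")
    if folds < 2:
        raise ValueError("folds must be at least 2")
    ds.require_supervised()
    top = order[:m]
    X = ds.X[:, top]
    y = ds.y
    min_class = int(np.unique(y, return_counts=True)[1].min())
    folds_eff = min(folds, min_class)
    if folds_eff < folds:
        import logging

        logging.getLogger("kncfs").info(
            "reducing CV folds from %d to %d (smallest class)", folds, folds_eff
        )
    rng = np.random.default_rng(seed)
    accs: dict[str, list[float]] = {name: [] for name in _classifiers(0)}
    f1s: dict[str, list[float]] = {name: [] for name in _classifiers(0)}
    for _ in range(t):
        fold_seed = int(rng.integers(2**31 - 1))
        skf = StratifiedKFold(
            n_splits=folds_eff, shuffle=True, random_state=fold_seed
        )
        clfs = _classifiers(fold_seed)
        for train, test in skf.split(X, y):
            for name, clf in clfs.items():
                clf.fit(X[train], y[train])
                pred = clf.predict(X[test])
                accs[name].append(accuracy_score(y[test], pred))
                f1s[name].append(
                    f1_score(
                        y[test], pred, average=f1_average, zero_division=0
                    )
                )
    return EvaluationResult(
        acc={
            name: (float(np.mean(v)), float(np.std(v)))
            for name, v in accs.items()
        },
        f1={
            name: (float(np.mean(v)), float(np.std(v)))
            for name, v in f1s.items()
        },
        m=m,
        folds=folds_eff,
        t=t,
    )
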