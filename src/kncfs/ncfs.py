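"""Neighborhood Component Feature Selection (NCFS).

NCFS learns one importance weight per feature by maximizing a kernel-smoothed
leave-one-out classification criterion.  With weighted L1 distance

    d_w(x_i, x_j) = sum_l  w_l^2 |x_il - x_jl|,

each sample i picks a reference point j with probability proportional to
``exp(-d_w(x_i, x_j) / sigma)`` (self-selection excluded).  The probability
that i is classified correctly is the reference-probability mass on samples
sharing its label, and the objective is

    F(w) = sum_i p_i  -  lambda * sum_l w_l^2,

maximized by gradient ascent with an adaptive step size.  Large weights on
discriminative features sharpen the kernel along those axes, which raises
p_i; the L2 penalty shrinks everything else.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import LabeledDataset

__all__ = [
    "NCFSParams",
    "NCFSResult",
    "weighted_distance",
    "reference_probabilities",
    "ncfs_objective",
    "ncfs_gradient",
    "fit_ncfs",
]


@dataclass
class NCFSParams:
    """Hyper-parameters of the NCFS weight learner.

    sigma is the kernel width converting distances into reference
    probabilities; lam the coefficient of the squared-weight penalty.  The
    ascent step starts at ``initial_step``, grows by ``step_up`` after each
    accepted step and shrinks by ``step_down`` after each rejected one;
    iteration stops when the objective change of an accepted step falls
    below ``tol`` or after ``max_iter`` steps.
    """

    sigma: float = 1.0
    lam: float = 1.0
    initial_step: float = 1.0
    step_up: float = 1.01
    step_down: float = 0.5
    tol: float = 1e-4
    max_iter: int = 100

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.lam < 0:
            raise ValueError("lam must be nonnegative")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.initial_step <= 0:
            raise ValueError("initial_step must be positive")
        if self.max_iter < 0:
            raise ValueError("max_iter must be nonnegative")


@dataclass
class NCFSResult:
    """Fitted weights plus the accepted-step objective trace."""

    w: np.ndarray
    objective_trace: list[float] = field(default_factory=list)
    n_iter: int = 0

    @property
    def objective(self) -> float:
        return self.objective_trace[-1]


def weighted_distance(xi: np.ndarray, xj: np.ndarray, w: np.ndarray) -> float:
    """Weighted L1 distance sum_l w_l^2 |x_il - x_jl| between two samples."""
    xi = np.asarray(xi, dtype=float)
    xj = np.asarray(xj, dtype=float)
    w = np.asarray(w, dtype=float)
    if not (xi.shape == xj.shape == w.shape):
        raise ValueError(
            f"dimension mismatch: xi {xi.shape}, xj {xj.shape}, w {w.shape}"
        )
    return float(np.sum(w**2 * np.abs(xi - xj)))


def _abs_diff_tensor(X: np.ndarray) -> np.ndarray:
    """Pairwise per-feature absolute differences, shape (n, n, d).

    Does not depend on w, so it is computed once per fit.
    """
    return np.abs(X[:, None, :] - X[None, :, :])


def _reference_matrix(
    D: np.ndarray, sigma: float
) -> np.ndarray:
    """Row-stochastic reference probabilities from a distance matrix.

    Each row is shifted by its minimum off-diagonal distance before
    exponentiation, so the kernel never underflows to an all-zero row no
    matter how large the distances are; the shift cancels in the
    normalization.
    """
    n = D.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples for reference probabilities")
    off = D + np.diag(np.full(n, np.inf))
    shift = off.min(axis=1, keepdims=True)
    K = np.exp(-(off - shift) / sigma)
    np.fill_diagonal(K, 0.0)
    row_sums = K.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        P = np.where(row_sums > 0, K / row_sums, 0.0)
    return P


def reference_probabilities(
    ds: LabeledDataset, w: np.ndarray, sigma: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Reference-selection matrix P and per-sample correctness p.

    Returns
    -------
    P : ndarray of shape (n, n)
        ``P[i, j]`` is the probability that sample i selects sample j as its
        reference point; ``P[i, i] = 0`` and every row sums to 1.
    p_correct : ndarray of shape (n,)
        ``p_correct[i]`` is the reference mass sample i places on samples
        with its own label.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    w = np.asarray(w, dtype=float)
    A = _abs_diff_tensor(ds.X)
    D = A @ (w**2)
    P = _reference_matrix(D, sigma)
    same = (ds.y[:, None] == ds.y[None, :]).astype(float)
    p_correct = (P * same).sum(axis=1)
    return P, p_correct


def ncfs_objective(
    ds: LabeledDataset, w: np.ndarray, params: NCFSParams
) -> float:
    """Leave-one-out objective F(w) = sum_i p_i - lam * ||w||^2; at most n."""
    _, p_correct = reference_probabilities(ds, w, params.sigma)
    return float(p_correct.sum() - params.lam * np.sum(np.asarray(w) ** 2))


def _objective_and_gradient(
    A: np.ndarray,
    same: np.ndarray,
    w: np.ndarray,
    params: NCFSParams,
) -> tuple[float, np.ndarray]:
    """Objective and its analytic gradient from the cached |diff| tensor.

    dF/dw_l = 2 w_l [ (1/sigma) sum_i ( p_i sum_j P_ij A_ijl
                                        - sum_j same_ij P_ij A_ijl ) - lam ].
    """
    D = A @ (w**2)
    P = _reference_matrix(D, params.sigma)
    p_correct = (P * same).sum(axis=1)
    F = float(p_correct.sum() - params.lam * np.sum(w**2))
    # E_all[i, l] = sum_j P_ij A_ijl ; E_same likewise restricted to same-label
    E_all = np.einsum("ij,ijl->il", P, A)
    E_same = np.einsum("ij,ijl->il", P * same, A)
    inner = (p_correct[:, None] * E_all - E_same).sum(axis=0)
    grad = 2.0 * w * (inner / params.sigma - params.lam)
    return F, grad


def ncfs_gradient(
    ds: LabeledDataset, w: np.ndarray, params: NCFSParams
) -> np.ndarray:
    """Analytic gradient of the NCFS objective with respect to w."""
    w = np.asarray(w, dtype=float)
    A = _abs_diff_tensor(ds.X)
    same = (ds.y[:, None] == ds.y[None, :]).astype(float)
    _, grad = _objective_and_gradient(A, same, w, params)
    return grad


def fit_ncfs(
    ds: LabeledDataset,
    params: NCFSParams | None = None,
    w0: np.ndarray | None = None,
) -> NCFSResult:
    """Learn feature weights by adaptive-step gradient ascent.

    Starts from all-ones weights (or ``w0``).  A proposed step is accepted
    if it increases the objective, after which the step size is multiplied
    by ``step_up``; otherwise the step is reverted and the step size is
    multiplied by ``step_down``.  Stops when an accepted step improves the
    objective by less than ``tol``, after ``max_iter`` proposals, or when
    the step size underflows.  The accepted-step objective trace is strictly
    increasing by construction.

    Weights are not constrained to be nonnegative: the squared-weight
    penalty and the squared weights in the distance are both sign-symmetric,
    so ranking uses the weights as returned.
    """
    if params is None:
        params = NCFSParams()
    ds.require_supervised()
    d = ds.n_features
    w = np.ones(d) if w0 is None else np.asarray(w0, dtype=float).copy()
    if w.shape != (d,):
        raise ValueError(f"w0 has shape {w.shape}, expected ({d},)")

    A = _abs_diff_tensor(ds.X)
    same = (ds.y[:, None] == ds.y[None, :]).astype(float)

    F, grad = _objective_and_gradient(A, same, w, params)
    if not np.isfinite(F):
        raise FloatingPointError(f"non-finite objective at start: F={F}")
    trace = [F]
    step = params.initial_step
    n_iter = 0
    for n_iter in range(1, params.max_iter + 1):
        w_new = w + step * grad
        F_new, grad_new = _objective_and_gradient(A, same, w_new, params)
        if not np.isfinite(F_new):
            raise FloatingPointError(
                f"non-finite objective at iteration {n_iter}: "
                f"F={F_new}, step={step}"
            )
        if F_new > F:
            delta = F_new - F
            w, F, grad = w_new, F_new, grad_new
            trace.append(F)
            step *= params.step_up
            if delta < params.tol:
                break
        else:
            step *= params.step_down
            if step < 1e-12:
                break
    return NCFSResult(w=w, objective_trace=trace, n_iter=n_iter)
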