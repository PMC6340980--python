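"""Fast kernel learning: convex combination weights by kernel–target alignment.

Given J base kernels ``K_1..K_J`` for one molecular space and a target kernel
``Y`` derived from the training interactions, the weights solve

    min_w  || sum_a w_a K_a - Y ||_F^2 + lambda ||w||^2    s.t.  sum_a w_a = 1

which reduces to the quadratic program ``min_w w^T (A + lambda I) w - 2 b^T w``
with ``A_uv = tr(K_u^T K_v)`` and ``b_v = tr(Y^T K_v)``. The equality-constrained
problem is solved through its KKT linear system; non-negativity (on by
default, since convex kernel combinations preserve positive semidefiniteness)
is enforced by exact minimisation over the probability simplex.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .data_io import InteractionMatrix
from .kernels import KernelMatrix

logger = logging.getLogger(__name__)

DEFAULT_LAMBDA = 10000.0


@dataclass
class KernelBank:
    """Ordered collection of same-space, same-axis kernels entering fusion."""

    kernels: list[KernelMatrix]

    def __post_init__(self) -> None:
        if not self.kernels:
            raise ValueError("kernel bank needs at least one kernel")
        ids = self.kernels[0].axis_ids
        for k in self.kernels:
            if k.axis_ids != ids:
                raise ValueError("kernel bank members disagree on axis ids")

    @property
    def names(self) -> list[str]:
        return [k.name for k in self.kernels]

    @property
    def J(self) -> int:
        return len(self.kernels)

    @property
    def axis_ids(self) -> tuple[str, ...]:
        return self.kernels[0].axis_ids

    def stacked(self) -> np.ndarray:
        return np.stack([k.values for k in self.kernels])


@dataclass
class FastKLProblem:
    """The assembled quadratic program: alignment matrix A, vector b, tradeoff."""

    A: np.ndarray
    b: np.ndarray
    lambda_: float
    target: np.ndarray = field(repr=False, default=None)

    def objective(self, w: np.ndarray) -> float:
        """Value of w^T (A + lambda I) w - 2 b^T w."""
        w = np.asarray(w, dtype=float)
        return float(w @ (self.A + self.lambda_ * np.eye(len(w))) @ w - 2 * self.b @ w)


@dataclass(frozen=True)
class KernelWeights:
    w: tuple[float, ...]
    space: str

    def __post_init__(self) -> None:
        if abs(sum(self.w) - 1.0) > 1e-8:
            raise ValueError("kernel weights must sum to 1")


def build_target(F_train: InteractionMatrix | np.ndarray, space: str) -> np.ndarray:
    """Interaction-derived target kernel: the Gram matrix of training profiles.

    lnc space -> F F^T (m×m); pro space -> F^T F (n×n). Raises on an all-zero
    training matrix (no signal to align to).
    """
    F = F_train.train_view() if isinstance(F_train, InteractionMatrix) else np.asarray(F_train, dtype=float)
    if not F.any():
        raise ValueError("all-zero training matrix: nothing to align kernels to")
    if space == "lnc":
        return F @ F.T
    if space == "pro":
        return F.T @ F
    raise ValueError(f"unknown space {space!r}")


def assemble_problem(
    bank: KernelBank, Y: np.ndarray, lambda_: float = DEFAULT_LAMBDA
) -> FastKLProblem:
    """Fill A_uv = tr(K_u^T K_v) and b_v = tr(Y^T K_v)."""
    Y = np.asarray(Y, dtype=float)
    p = len(bank.axis_ids)
    if Y.shape != (p, p):
        raise ValueError(f"target shape {Y.shape} does not match kernels ({p},{p})")
    Ks = bank.stacked()
    flat = Ks.reshape(bank.J, -1)
    A = flat @ flat.T  # tr(Ku^T Kv) for symmetric kernels
    b = flat @ Y.ravel()
    return FastKLProblem(A=A, b=b, lambda_=lambda_, target=Y)


def _solve_equality(H: np.ndarray, b: np.ndarray, active: np.ndarray) -> np.ndarray:
    """Minimise w^T H w - 2 b^T w s.t. sum(w)=1 and w[i]=0 for i in ``active``."""
    free = np.nonzero(~active)[0]
    k = len(free)
    Hf = H[np.ix_(free, free)]
    KKT = np.zeros((k + 1, k + 1))
    KKT[:k, :k] = 2.0 * Hf
    KKT[:k, k] = 1.0
    KKT[k, :k] = 1.0
    rhs = np.concatenate([2.0 * b[free], [1.0]])
    try:
        sol = np.linalg.solve(KKT, rhs)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular KKT system in fast kernel learning; increase lambda"
        ) from exc
    w = np.zeros(len(b))
    w[free] = sol[:k]
    return w


def solve_weights(
    problem: FastKLProblem, project_simplex: bool = True, space: str = "lnc"
) -> KernelWeights:
    """Solve the weight QP subject to sum-to-one (and, by default, w >= 0).

    The equality-only optimum comes from the KKT system. If it has negative
    entries and ``project_simplex`` is on, the exact simplex-constrained
    minimiser is found by enumerating active sets (J is small), which always
    attains an objective no worse than any feasible point.
    """
    J = len(problem.b)
    H = problem.A + problem.lambda_ * np.eye(J)
    w = _solve_equality(H, problem.b, np.zeros(J, dtype=bool))
    if project_simplex and (w < 0).any():
        logger.info("negative kernel weights %s; projecting onto the simplex", w)
        best, best_obj = None, np.inf
        for r in range(J):  # force r weights to zero, keep at least one free
            for zeros in itertools.combinations(range(J), r):
                active = np.zeros(J, dtype=bool)
                active[list(zeros)] = True
                try:
                    cand = _solve_equality(H, problem.b, active)
                except np.linalg.LinAlgError:
                    continue
                if (cand < -1e-12).any():
                    continue
                obj = problem.objective(np.maximum(cand, 0.0))
                if obj < best_obj:
                    best, best_obj = np.maximum(cand, 0.0), obj
        w = best / best.sum()
    return KernelWeights(tuple(w.tolist()), space)


def fuse(bank: KernelBank, weights: KernelWeights | np.ndarray) -> KernelMatrix:
    """Weighted sum of the bank's kernels."""
    w = np.asarray(weights.w if isinstance(weights, KernelWeights) else weights, dtype=float)
    if len(w) != bank.J:
        raise ValueError(f"{len(w)} weights for {bank.J} kernels")
    fused = np.tensordot(w, bank.stacked(), axes=1)
    first = bank.kernels[0]
    return KernelMatrix(fused, bank.axis_ids, "fused", first.space)


class FastKLFusion(BaseEstimator):
    """Learn convex kernel-combination weights by regularised target alignment.

    Parameters
    ----------
    lambda_ : float, default 10000
        Ridge tradeoff on the weight vector; large values pull the weights
        toward the uniform combination.
    project_simplex : bool, default True
        Enforce non-negative weights (exact simplex-constrained solve when the
        unconstrained-sign optimum leaves the simplex).

    Attributes
    ----------
    weights_ : ndarray of shape (J,)
        Learned weights, summing to 1.
    problem_ : FastKLProblem
        The assembled alignment QP (A, b, lambda).
    """

    def __init__(self, lambda_: float = DEFAULT_LAMBDA, project_simplex: bool = True):
        self.lambda_ = lambda_
        self.project_simplex = project_simplex

    def fit(self, bank: KernelBank, Y: np.ndarray) -> "FastKLFusion":
        if self.lambda_ < 0:
            raise ValueError("lambda_ must be non-negative")
        self.problem_ = assemble_problem(bank, Y, self.lambda_)
        space = bank.kernels[0].space
        self.weights_ = np.asarray(
            solve_weights(self.problem_, self.project_simplex, space).w
        )
        self.space_ = space
        return self

    def transform(self, bank: KernelBank) -> KernelMatrix:
        """Fuse a bank (same ordering as at fit time) with the learned weights."""
        return fuse(bank, self.weights_)

    def fit_transform(self, bank: KernelBank, Y: np.ndarray) -> KernelMatrix:
        return self.fit(bank, Y).transform(bank)
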