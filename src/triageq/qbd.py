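"""Matrix-geometric solver for level-structured (quasi-birth-death) chains.

A chain is stored as a small number of boundary levels followed by a
level-independent repeating portion ``(A0, A1, A2)`` — up, local, down
transition blocks of the generator.  The stationary distribution has the
matrix-geometric form ``pi_{m+k} = pi_m R^k`` where ``R`` is the minimal
nonnegative solution of ``A0 + R A1 + R^2 A2 = 0``; boundary levels are
obtained from the balance equations and the normalization
``sum_i pi_i 1 + pi_m (I - R)^{-1} 1 = 1``.

Mean class occupancy is summed in closed form over the geometric tail
(``sum_k (m+k) R^k = m (I-R)^{-1} + R (I-R)^{-2}``), and waits follow from
Little's law: ``W = L / lambda`` and ``W_q = W - 1/mu``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import InstabilityError, SolverError

logger = logging.getLogger(__name__)

__all__ = [
    "QBDChain",
    "StationaryDistribution",
    "WaitResult",
    "solve_r_matrix",
    "stationary_distribution",
    "mean_number_in_class",
    "wait_from_distribution",
    "solve_chain_wait",
]

_ROWSUM_TOL = 1e-10
_NEG_CLIP = 1e-12
_NEG_RAISE = 1e-9


@dataclass
class QBDChain:
    """Block-structured Markov chain for one tagged priority class.

    Levels count the tagged-class images in the system (``level_meaning``).
    ``boundary_local[i]`` / ``boundary_up[i]`` / ``boundary_down[i]`` are the
    generator blocks of boundary level ``i`` (``boundary_down[0]`` is None);
    the last boundary level must share the repeating phase dimension.
    ``first_rep_down`` is the down-block from the first repeating level
    (defaults to ``A2``).
    """

    boundary_local: list[np.ndarray]
    boundary_up: list[np.ndarray]
    boundary_down: list[Optional[np.ndarray]]
    A0: np.ndarray
    A1: np.ndarray
    A2: np.ndarray
    first_rep_down: Optional[np.ndarray] = None
    level_meaning: str = "tagged-class images in system"
    phase_labels: Sequence[str] = field(default_factory=list)
    class_rates: tuple[float, float] = (0.0, 0.0)  # (lambda_j, mu_j) per min

    def __post_init__(self) -> None:
        if self.first_rep_down is None:
            self.first_rep_down = self.A2
        self.validate()

    @property
    def n_boundary(self) -> int:
        return len(self.boundary_local)

    def validate(self) -> None:
        """Check generator structure: zero row sums, nonnegative off-diagonals."""
        m = self.n_boundary
        for i in range(m):
            row = self.boundary_local[i].sum(axis=1) + self.boundary_up[i].sum(axis=1)
            if i > 0 and self.boundary_down[i] is not None:
                row = row + self.boundary_down[i].sum(axis=1)
            if np.max(np.abs(row)) > _ROWSUM_TOL:
                raise SolverError(f"boundary level {i} rows do not sum to 0")
        rep_row = (self.A0 + self.A1).sum(axis=1) + self.first_rep_down.sum(axis=1)
        if np.max(np.abs(rep_row)) > _ROWSUM_TOL:
            raise SolverError("first repeating level rows do not sum to 0")
        rep_row = (self.A0 + self.A1 + self.A2).sum(axis=1)
        if np.max(np.abs(rep_row)) > _ROWSUM_TOL:
            raise SolverError("repeating-level rows do not sum to 0")
        for name, block in (("A0", self.A0), ("A2", self.A2)):
            if np.min(block) < -_ROWSUM_TOL:
                raise SolverError(f"{name} has negative entries")
        off = self.A1 - np.diag(np.diag(self.A1))
        if np.min(off) < -_ROWSUM_TOL:
            raise SolverError("A1 has negative off-diagonal entries")

    def drift_margin(self) -> float:
        """Mean drift ``theta A2 1 - theta A0 1`` (positive iff stable),
        where ``theta`` is the stationary vector of ``A0 + A1 + A2``."""
        A = self.A0 + self.A1 + self.A2
        n = A.shape[0]
        sys = np.vstack([A.T, np.ones((1, n))])
        rhs = np.zeros(n + 1)
        rhs[-1] = 1.0
        theta, *_ = np.linalg.lstsq(sys, rhs, rcond=None)
        return float(theta @ self.A2.sum(axis=1) - theta @ self.A0.sum(axis=1))


@dataclass
class StationaryDistribution:
    """Solved state probabilities of a :class:`QBDChain`."""

    chain: QBDChain
    boundary_probs: list[np.ndarray]   # pi_0 .. pi_{m-1}
    pi_first_rep: np.ndarray           # pi_m
    rate_matrix_r: np.ndarray
    norm_check: float

    def level_probs(self, level: int) -> np.ndarray:
        """Probability vector of a given level (geometric beyond level m)."""
        m = self.chain.n_boundary
        if level < m:
            return self.boundary_probs[level]
        return self.pi_first_rep @ np.linalg.matrix_power(
            self.rate_matrix_r, level - m)

    def total_level_probability(self, level: int) -> float:
        return float(self.level_probs(level).sum())


@dataclass(frozen=True)
class WaitResult:
    """Mean occupancy and waits for one priority class."""

    l_mean: float       # mean number in system (images)
    w_response: float   # mean response time (minutes)
    w_queue: float      # mean queue wait (minutes)


def solve_r_matrix(chain: QBDChain, tol: float = 1e-12,
                   max_iter: int = 1_000_000) -> np.ndarray:
    """Minimal nonnegative solution of ``A0 + R A1 + R^2 A2 = 0``.

    Successive substitution ``R <- -(A0 + R^2 A2) A1^{-1}`` from ``R = 0``;
    monotone convergence for a stable chain.
    """
    margin = chain.drift_margin()
    if margin <= 1e-9:
        raise InstabilityError(
            f"repeating portion is not positive recurrent (drift margin "
            f"{margin:.3e} <= 0)")
    A0, A1, A2 = chain.A0, chain.A1, chain.A2
    a1_inv = np.linalg.inv(A1)
    R = np.zeros_like(A0)
    for it in range(max_iter):
        R_new = -(A0 + R @ R @ A2) @ a1_inv
        diff = np.max(np.abs(R_new - R))
        R = R_new
        if diff < tol:
            break
    else:
        raise SolverError(f"R iteration did not converge in {max_iter} steps")
    resid = np.max(np.abs(A0 + R @ A1 + R @ R @ A2))
    sr = max(abs(np.linalg.eigvals(R))) if R.size > 1 else abs(R[0, 0])
    logger.debug("R solved: %d iterations, residual %.3e, spectral radius %.6f",
                 it + 1, resid, sr)
    if sr >= 1.0 - 1e-9:
        raise InstabilityError(f"spectral radius of R is {sr:.6f} >= 1")
    if resid > max(tol * 100.0, 1e-10):
        raise SolverError(f"R residual {resid:.3e} too large")
    return R


def stationary_distribution(chain: QBDChain,
                            r: Optional[np.ndarray] = None) -> StationaryDistribution:
    """Solve boundary balance equations and normalize.

    Unknowns are ``pi_0 .. pi_m`` (boundary levels plus the first repeating
    level); the geometric tail is implied by ``R``.
    """
    if r is None:
        r = solve_r_matrix(chain)
    m = chain.n_boundary
    dims = [b.shape[0] for b in chain.boundary_local] + [chain.A1.shape[0]]
    offs = np.concatenate([[0], np.cumsum(dims)])
    n_tot = offs[-1]

    # columns of M are balance equations per state; M[j,i] block = rate from
    # level j into level i states
    M = np.zeros((n_tot, n_tot))

    def add(src_level: int, dst_level: int, block: np.ndarray) -> None:
        M[offs[src_level]:offs[src_level] + dims[src_level],
          offs[dst_level]:offs[dst_level] + dims[dst_level]] += block

    for i in range(m):
        add(i, i, chain.boundary_local[i])
        add(i, i + 1, chain.boundary_up[i])
        if i > 0:
            add(i, i - 1, chain.boundary_down[i])
    # level m: local balance includes the tail flowing back via R A2
    add(m, m, chain.A1 + r @ chain.A2)
    add(m, m - 1, chain.first_rep_down)

    # normalization replaces the last balance column
    tail_weight = np.linalg.solve(np.eye(dims[m]) - r, np.ones(dims[m]))
    norm_col = np.ones(n_tot)
    norm_col[offs[m]:] = tail_weight
    M[:, -1] = norm_col
    rhs = np.zeros(n_tot)
    rhs[-1] = 1.0
    try:
        pi = np.linalg.solve(M.T, rhs)
    except np.linalg.LinAlgError as exc:
        raise SolverError(f"singular boundary system: {exc}") from exc

    if np.min(pi) < -_NEG_RAISE:
        raise SolverError(f"negative stationary probability {np.min(pi):.3e}")
    pi = np.where(pi < 0.0, 0.0, pi)

    boundary = [pi[offs[i]:offs[i + 1]] for i in range(m)]
    pi_m = pi[offs[m]:]
    total = sum(float(b.sum()) for b in boundary) + float(pi_m @ tail_weight)
    if abs(total - 1.0) > 1e-8:
        raise SolverError(f"normalization check failed: total = {total!r}")
    return StationaryDistribution(chain=chain, boundary_probs=boundary,
                                  pi_first_rep=pi_m, rate_matrix_r=r,
                                  norm_check=total)


def mean_number_in_class(dist: StationaryDistribution) -> float:
    """Mean tagged-class count ``L = sum_n n pi_n 1`` via the closed-form
    geometric-tail summation (no truncation)."""
    chain = dist.chain
    m = chain.n_boundary
    L = sum(i * float(dist.boundary_probs[i].sum()) for i in range(m))
    r = dist.rate_matrix_r
    n = r.shape[0]
    inv = np.linalg.inv(np.eye(n) - r)
    tail = m * inv + r @ inv @ inv
    L += float(dist.pi_first_rep @ tail @ np.ones(n))
    return L


def wait_from_distribution(dist: StationaryDistribution,
                           lambda_j: float, mu_j: float) -> WaitResult:
    """Little's-law conversion ``W = L/lambda``, ``W_q = W - 1/mu``.

    An empty class (``lambda_j == 0``) has zero wait by convention so that
    sensitivity/specificity-weighted mixtures stay well defined.
    """
    if lambda_j == 0.0:
        return WaitResult(l_mean=0.0, w_response=0.0, w_queue=0.0)
    L = mean_number_in_class(dist)
    w = L / lambda_j
    w_q = w - 1.0 / mu_j
    if w_q < -_NEG_RAISE:
        raise SolverError(f"negative queue wait {w_q:.3e} min")
    return WaitResult(l_mean=L, w_response=w, w_queue=max(w_q, 0.0))


def solve_chain_wait(chain: QBDChain) -> WaitResult:
    """Convenience pipeline: R matrix, stationary distribution, Little's law."""
    lam, mu = chain.class_rates
    if lam == 0.0:
        return WaitResult(l_mean=0.0, w_response=0.0, w_queue=0.0)
    dist = stationary_distribution(chain)
    return wait_from_distribution(dist, lam, mu)
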