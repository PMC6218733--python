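"""Rank-two nonnegative matrix factorization and the cluster rule.

The factorization M ~ W H (W m-by-2, H 2-by-n, all nonnegative) treats
each voxel's feature signature as a nonnegative mixture of two
endmember signatures; comparing the two abundances per column splits
the voxels into a region-of-interest cluster and its complement.

Solver: block coordinate descent where each block subproblem is an
exact two-variable nonnegative least squares solved in closed form per
column (unconstrained 2x2 solve if feasible, else the best single-
variable solution).  Each block update is an exact minimizer, so the
objective is non-increasing.  Initialization is deterministic
(successive projection on column-normalized data), so the whole path is
reproducible without any RNG; a seeded random init exists for
robustness experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateMatrixError

_EPS = np.finfo(float).eps


@dataclass
class Rank2Factorization:
    """Result of the rank-two factorization.

    ``H`` holds column-normalized abundances (each non-degenerate column
    sums to 1); ``H_raw`` the unnormalized least-squares abundances used
    for the residual.  ``zero_abundance`` flags columns whose both
    abundances are 0 (left unnormalized).
    """

    W: np.ndarray
    H: np.ndarray
    H_raw: np.ndarray
    residual: float
    objective_trace: np.ndarray
    iterations: int
    zero_abundance: np.ndarray

    r: int = 2

    def __post_init__(self):
        if self.W.shape[1] != 2 or self.H.shape[0] != 2:
            raise ValueError("factorization rank must be 2")
        if self.W.min() < 0 or self.H.min() < 0:
            raise ValueError("factors must be nonnegative")


@dataclass
class ClusterAssignment:
    """Disjoint split of column indices into C1 (ROI) and C2 (rest)."""

    C1: np.ndarray
    C2: np.ndarray
    n: int

    def __post_init__(self):
        both = np.concatenate([self.C1, self.C2])
        if len(np.unique(both)) != self.n or both.size != self.n:
            raise ValueError("C1, C2 must partition {0..n-1}")


def spa_init(M: np.ndarray) -> tuple[np.ndarray, bool]:
    """Pick two data columns as initial endmembers by successive projection.

    Columns are L2-normalized first, which makes the selection invariant
    to per-column scaling.  The first pick is the normalized column
    farthest from the normalized-column centroid (on the unit sphere all
    raw norms tie, so the centroid supplies the needed anchor); the
    second maximizes the residual norm after projecting out the first.

    Returns (W0, degenerate).  When all columns are parallel the
    degenerate flag is set and the two largest-norm columns are
    returned as a fallback.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[1] < 2:
        raise DegenerateMatrixError("need at least two columns")
    norms = np.linalg.norm(M, axis=0)
    nz = norms > 0
    if nz.sum() < 2:
        raise DegenerateMatrixError("fewer than two nonzero columns")
    X = np.zeros_like(M)
    X[:, nz] = M[:, nz] / norms[nz]
    centroid = X[:, nz].mean(axis=1, keepdims=True)
    dist = np.linalg.norm(X - centroid, axis=0)
    dist[~nz] = -np.inf
    j1 = int(np.argmax(dist))
    u = X[:, j1]
    resid = X - np.outer(u, u @ X)
    rnorm = np.linalg.norm(resid, axis=0)
    rnorm[~nz] = -np.inf
    j2 = int(np.argmax(rnorm))
    degenerate = rnorm[j2] < 1e-9
    if degenerate:
        order = np.argsort(norms)[::-1]
        j1, j2 = int(order[0]), int(order[1])
    return np.stack([M[:, j1], M[:, j2]], axis=1), bool(degenerate)


def _nnls2_cols(W: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Exact column-wise nonnegative least squares for 2 variables.

    Minimizes ||M[:, j] - W h_j|| over h_j >= 0 for every column j.
    The optimum is either the feasible unconstrained solution or lies
    on one of the two axes; all three candidates are evaluated in
    closed form and vectorized across columns.
    """
    A = W.T @ W  # 2x2 Gram
    B = W.T @ M  # 2xn
    a00, a01, a11 = A[0, 0], A[0, 1], A[1, 1]
    det = a00 * a11 - a01 * a01

    # axis candidates h = (b0/a00, 0) and (0, b1/a11), clipped at 0
    h0 = np.clip(B[0] / max(a00, _EPS), 0.0, None)
    h1 = np.clip(B[1] / max(a11, _EPS), 0.0, None)
    # objective value up to the constant ||M_j||^2: q(h) = 0.5 h'Ah - b'h
    q0 = 0.5 * a00 * h0**2 - B[0] * h0
    q1 = 0.5 * a11 * h1**2 - B[1] * h1
    use_first = q0 <= q1
    H = np.where(
        use_first,
        np.stack([h0, np.zeros_like(h0)]),
        np.stack([np.zeros_like(h1), h1]),
    )

    if det > _EPS * max(a00 * a11, 1.0):
        u0 = (a11 * B[0] - a01 * B[1]) / det
        u1 = (a00 * B[1] - a01 * B[0]) / det
        feasible = (u0 >= 0) & (u1 >= 0)
        H[0, feasible] = u0[feasible]
        H[1, feasible] = u1[feasible]
    return H


def factorize(
    M: np.ndarray,
    tol: float = 1e-5,
    max_iter: int = 500,
    init: str = "spa",
    seed: int | None = None,
) -> Rank2Factorization:
    """Alternating exact-NNLS rank-two factorization of a nonnegative matrix.

    Stops when the relative objective change drops below ``tol`` or
    after ``max_iter`` sweeps.  Abundance columns are normalized to sum
    1 afterwards (the cluster rule is invariant to that positive
    per-column scaling); all-zero abundance columns are flagged instead.
    """
    M = np.asarray(M, dtype=float)
    if M.size == 0:
        raise ValueError("empty matrix")
    if np.isnan(M).any():
        raise ValueError("matrix contains NaN")
    if M.min() < 0:
        raise ValueError("matrix must be nonnegative")

    if init == "spa":
        W, _ = spa_init(M)
    elif init == "maxnorm":
        order = np.argsort(np.linalg.norm(M, axis=0))[::-1]
        W = M[:, order[:2]].copy()
    elif init == "random":
        rng = np.random.default_rng(seed)
        W = rng.random((M.shape[0], 2)) * max(M.max(), 1.0)
    else:
        raise ValueError(f"unknown init {init!r}")
    # guard against an all-zero initial endmember
    for k in range(2):
        if not W[:, k].any():
            W[:, k] = 1.0

    norm_M = np.linalg.norm(M)
    trace = []
    H = _nnls2_cols(W, M)
    for it in range(1, max_iter + 1):
        Wt = _nnls2_cols(H.T, M.T)  # rows of W solved as columns
        W = Wt.T
        for k in range(2):  # re-seed a collapsed endmember to keep rank 2
            if not W[:, k].any():
                W[:, k] = _EPS
        H = _nnls2_cols(W, M)
        obj = np.linalg.norm(M - W @ H)
        trace.append(obj)
        if len(trace) > 1:
            prev = trace[-2]
            if abs(prev - obj) <= tol * max(trace[0], _EPS):
                break

    H_raw = H
    sums = H_raw.sum(axis=0)
    zero = sums <= 0
    H_norm = H_raw.copy()
    H_norm[:, ~zero] = H_raw[:, ~zero] / sums[~zero]
    residual = float(trace[-1] / norm_M) if norm_M > 0 else 0.0
    return Rank2Factorization(
        W=W,
        H=H_norm,
        H_raw=H_raw,
        residual=residual,
        objective_trace=np.asarray(trace),
        iterations=len(trace),
        zero_abundance=zero,
    )


def assign_clusters(F: Rank2Factorization) -> ClusterAssignment:
    """Column j joins C1 iff H[0, j] >= H[1, j]; ties go to C1."""
    in_c1 = F.H[0] >= F.H[1]
    n = F.H.shape[1]
    idx = np.arange(n)
    return ClusterAssignment(C1=idx[in_c1], C2=idx[~in_c1], n=n)


def select_roi_component(
    F: Rank2Factorization,
    assignment: ClusterAssignment,
    guide: np.ndarray,
    polarity: str = "bright",
) -> ClusterAssignment:
    """Orient the split so C1 is the cluster matching the polarity.

    ``guide`` holds each column's intensity on the stage's driving
    modality.  With polarity "bright" C1 becomes the cluster with the
    higher mean guide intensity, with "dark" the lower.  Empty clusters
    and exactly equal means leave the assignment unchanged.
    """
    if polarity not in ("bright", "dark"):
        raise ValueError("polarity must be 'bright' or 'dark'")
    guide = np.asarray(guide, dtype=float)
    if assignment.C1.size == 0 or assignment.C2.size == 0:
        return assignment
    m1 = guide[assignment.C1].mean()
    m2 = guide[assignment.C2].mean()
    swap = (m1 < m2) if polarity == "bright" else (m1 > m2)
    if swap:
        return ClusterAssignment(
            C1=assignment.C2, C2=assignment.C1, n=assignment.n
        )
    return assignment
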