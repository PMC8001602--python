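"""Robust PCA: low-rank + sparse matrix decomposition.

A single-channel image, viewed as a matrix ``P``, is split into a low-rank
part ``L`` carrying the smooth background structure and a sparse part ``S``
carrying rare, localised deviations (the candidate targets).  Two kernels
are provided:

``GoDec``
    The non-convex alternating scheme with explicit rank and cardinality
    budgets: repeat ``L <- best rank-r approximation of (P - S)`` and
    ``S <- keep the k largest-magnitude entries of (P - L)`` until the
    reconstruction residual stabilises.  Both steps minimise
    ``||P - L - S||_F`` over one variable, so the residual sequence is
    non-increasing.

``PrincipalComponentPursuit``
    The convex relaxation ``min ||L||_* + lambda * ||S||_1`` subject to
    ``P = L + S``, solved by an inexact augmented-Lagrangian iteration with
    singular-value soft-thresholding.  This is an algorithmic stand-in for
    the stable-PCP solver family; the constraint is enforced to a relative
    Frobenius tolerance.

Estimators follow scikit-learn conventions: hyperparameters in
``__init__``, fitted arrays carry a trailing underscore
(``low_rank_``, ``sparse_``), ``fit`` validates and returns ``self``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.sparse.linalg import svds
from sklearn.base import BaseEstimator

KERNELS = ("godec", "pcp")


def _check_matrix(P) -> np.ndarray:
    P = np.asarray(P, dtype=np.float64)
    if P.ndim != 2 or P.shape[0] < 1 or P.shape[1] < 1:
        raise ValueError(f"input must be a 2-D matrix, got shape {P.shape}")
    if not np.all(np.isfinite(P)):
        raise ValueError("input matrix contains non-finite entries")
    return P


@dataclass
class RpcaConfig:
    """Kernel selection and budgets for a decomposition run.

    ``rank_bound`` and ``cardinality_bound`` are the GoDec budgets r and k;
    ``cardinality_bound=None`` defaults to ceil(0.04 * n_entries), motivated
    by the ~3-4% pixel prevalence of the rare targets the method assumes.
    ``lambda_reg=None`` defaults to 1/sqrt(max(rows, cols)) for the convex
    kernel.  The l0 regulariser weight of the original combinatorial
    objective is never used numerically (only its relaxations are solved).
    """

    kernel: str = "godec"
    rank_bound: int = 2
    cardinality_bound: Optional[int] = None
    lambda_reg: Optional[float] = None
    max_iter: int = 100
    tol: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kernel not in KERNELS:
            raise ValueError(f"kernel must be one of {KERNELS}, got {self.kernel!r}")
        if self.rank_bound < 1:
            raise ValueError("rank_bound must be a positive integer")
        if self.cardinality_bound is not None and self.cardinality_bound < 0:
            raise ValueError("cardinality_bound must be non-negative")
        if self.lambda_reg is not None and self.lambda_reg <= 0:
            raise ValueError("lambda_reg must be positive")
        if self.max_iter < 1 or self.tol <= 0:
            raise ValueError("max_iter must be >= 1 and tol > 0")

    def resolved_cardinality(self, shape: tuple[int, int]) -> int:
        n = shape[0] * shape[1]
        k = math.ceil(0.04 * n) if self.cardinality_bound is None else self.cardinality_bound
        if k > n:
            raise ValueError(f"cardinality_bound {k} exceeds matrix size {n}")
        return int(k)

    def resolved_lambda(self, shape: tuple[int, int]) -> float:
        if self.lambda_reg is not None:
            return float(self.lambda_reg)
        return 1.0 / math.sqrt(max(shape))


@dataclass
class RpcaResult:
    """L + S split of a matrix with convergence diagnostics."""

    L: np.ndarray
    S: np.ndarray
    iterations: int
    relative_residual: float
    converged: bool = True
    residual_history: list = field(default_factory=list)

    @property
    def nnz_sparse(self) -> int:
        return int(np.count_nonzero(self.S))


def _truncated_svd(M: np.ndarray, r: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exact best rank-r factors of M (deterministic)."""
    m, n = M.shape
    r = min(r, m, n)
    # svds pays off only for thin slices of large matrices
    if r < min(m, n) // 4 and min(m, n) > 100:
        v0 = np.ones(min(m, n)) / math.sqrt(min(m, n))
        U, s, Vt = svds(M, k=r, v0=v0)
        order = np.argsort(s)[::-1]
        return U[:, order], s[order], Vt[order]
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    return U[:, :r], s[:r], Vt[:r]


def _rank_r_project(M: np.ndarray, r: int) -> np.ndarray:
    U, s, Vt = _truncated_svd(M, r)
    return (U * s) @ Vt


def _hard_threshold_top_k(M: np.ndarray, k: int) -> np.ndarray:
    """Keep the k largest-magnitude entries of M, zero elsewhere."""
    if k == 0:
        return np.zeros_like(M)
    flat = np.abs(M).ravel()
    if k >= flat.size:
        return M.copy()
    cutoff_idx = np.argpartition(flat, flat.size - k)[flat.size - k:]
    S = np.zeros_like(M)
    S.ravel()[cutoff_idx] = M.ravel()[cutoff_idx]
    return S


class GoDec(BaseEstimator):
    """Rank/cardinality-budgeted alternating decomposition.

    Parameters
    ----------
    rank : int
        Rank budget r for the low-rank part.
    cardinality : int or None
        Cardinality budget k (max nonzeros of the sparse part); ``None``
        defaults to ceil(0.04 * n_entries).
    max_iter, tol : stopping rule — iterate until the relative change of the
        Frobenius residual ||P - L - S||_F falls below ``tol``.

    Attributes
    ----------
    low_rank_, sparse_ : the fitted L and S
    n_iter_, relative_residual_, residual_history_, converged_
    """

    def __init__(self, rank: int = 2, cardinality: Optional[int] = None,
                 max_iter: int = 100, tol: float = 1e-6):
        self.rank = rank
        self.cardinality = cardinality
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y=None):
        P = _check_matrix(X)
        cfg = RpcaConfig(kernel="godec", rank_bound=self.rank,
                         cardinality_bound=self.cardinality,
                         max_iter=self.max_iter, tol=self.tol)
        if self.rank > min(P.shape):
            raise ValueError(
                f"rank_bound {self.rank} exceeds min(matrix dims) {min(P.shape)}")
        k = cfg.resolved_cardinality(P.shape)

        norm_P = np.linalg.norm(P)
        if norm_P == 0.0:  # zero input: residual defined as 0 by convention
            self.low_rank_ = np.zeros_like(P)
            self.sparse_ = np.zeros_like(P)
            self.n_iter_ = 0
            self.relative_residual_ = 0.0
            self.residual_history_ = [0.0]
            self.converged_ = True
            return self

        # seed S with the k largest-magnitude raw entries so that isolated
        # strong spikes are not absorbed into the first low-rank fit
        S = _hard_threshold_top_k(P, k)
        L = np.zeros_like(P)
        history: list[float] = []
        prev = np.inf
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            L = _rank_r_project(P - S, self.rank)
            S = _hard_threshold_top_k(P - L, k)
            res = float(np.linalg.norm(P - L - S) / norm_P)
            history.append(res)
            if abs(prev - res) <= self.tol or res <= self.tol:
                converged = True
                break
            prev = res

        self.low_rank_ = L
        self.sparse_ = S
        self.n_iter_ = it
        self.relative_residual_ = history[-1]
        self.residual_history_ = history
        self.converged_ = converged
        return self

    def result_(self) -> RpcaResult:
        return RpcaResult(self.low_rank_, self.sparse_, self.n_iter_,
                          self.relative_residual_, self.converged_,
                          self.residual_history_)


class PrincipalComponentPursuit(BaseEstimator):
    """Convex low-rank + sparse split via inexact augmented Lagrangian.

    Minimises ``||L||_* + lam * ||S||_1`` subject to ``P = L + S``; the
    multiplier update drives the constraint residual to ``tol`` (relative
    Frobenius).  ``lam=None`` uses the standard 1/sqrt(max(m, n)).
    """

    def __init__(self, lam: Optional[float] = None, max_iter: int = 200,
                 tol: float = 1e-6, mu: Optional[float] = None, rho: float = 1.5):
        self.lam = lam
        self.max_iter = max_iter
        self.tol = tol
        self.mu = mu
        self.rho = rho

    def fit(self, X, y=None):
        P = _check_matrix(X)
        norm_P = np.linalg.norm(P)
        if norm_P == 0.0:
            self.low_rank_ = np.zeros_like(P)
            self.sparse_ = np.zeros_like(P)
            self.n_iter_ = 0
            self.relative_residual_ = 0.0
            self.residual_history_ = [0.0]
            self.converged_ = True
            return self

        lam = RpcaConfig(kernel="pcp", lambda_reg=self.lam).resolved_lambda(P.shape)
        spectral = np.linalg.norm(P, 2)
        mu = self.mu if self.mu is not None else 1.25 / spectral
        mu_max = mu * 1e7

        S = np.zeros_like(P)
        Y = P / max(spectral, np.abs(P).max() / lam)  # standard dual init
        L = np.zeros_like(P)
        history: list[float] = []
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            # L step: singular-value soft-thresholding
            U, s, Vt = np.linalg.svd(P - S + Y / mu, full_matrices=False)
            s_sh = np.maximum(s - 1.0 / mu, 0.0)
            L = (U * s_sh) @ Vt
            # S step: entry-wise soft-thresholding
            G = P - L + Y / mu
            S = np.sign(G) * np.maximum(np.abs(G) - lam / mu, 0.0)
            R = P - L - S
            Y = Y + mu * R
            mu = min(mu * self.rho, mu_max)
            res = float(np.linalg.norm(R) / norm_P)
            history.append(res)
            if res <= self.tol:
                converged = True
                break

        self.low_rank_ = L
        self.sparse_ = S
        self.n_iter_ = it
        self.relative_residual_ = history[-1]
        self.residual_history_ = history
        self.converged_ = converged
        return self

    def result_(self) -> RpcaResult:
        return RpcaResult(self.low_rank_, self.sparse_, self.n_iter_,
                          self.relative_residual_, self.converged_,
                          self.residual_history_)


# -- functional surface ------------------------------------------------------


def godec_decompose(P, cfg: Optional[RpcaConfig] = None) -> RpcaResult:
    cfg = cfg or RpcaConfig(kernel="godec")
    if cfg.kernel != "godec":
        raise ValueError(f"godec_decompose requires kernel='godec', got {cfg.kernel!r}")
    est = GoDec(rank=cfg.rank_bound, cardinality=cfg.cardinality_bound,
                max_iter=cfg.max_iter, tol=cfg.tol).fit(P)
    return est.result_()


def pcp_decompose(P, cfg: Optional[RpcaConfig] = None) -> RpcaResult:
    cfg = cfg or RpcaConfig(kernel="pcp")
    if cfg.kernel != "pcp":
        raise ValueError(f"pcp_decompose requires kernel='pcp', got {cfg.kernel!r}")
    est = PrincipalComponentPursuit(lam=cfg.lambda_reg, max_iter=cfg.max_iter,
                                    tol=cfg.tol).fit(P)
    return est.result_()


def decompose(P, cfg: RpcaConfig) -> RpcaResult:
    """Dispatch on cfg.kernel (extension point for further kernels)."""
    if cfg.kernel == "godec":
        return godec_decompose(P, cfg)
    if cfg.kernel == "pcp":
        return pcp_decompose(P, cfg)
    raise ValueError(f"unknown kernel {cfg.kernel!r}")
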