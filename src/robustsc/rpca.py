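"""Robust principal component analysis (low-rank + sparse decomposition).

A data matrix M is split into a low-rank part L capturing the typical,
long-range correlations and an entrywise-sparse part S holding atypical,
arbitrarily large outliers, by minimizing ``||L||_* + lambda * ||S||_1``
subject to ``L + S = M`` (nuclear norm plus entrywise l1).  The solver is
the inexact augmented-Lagrangian iteration: one singular-value-thresholding
step for L and one soft-thresholding step for S per outer iteration, with
the multiplier matrix updated and the penalty mu grown geometrically.

The trade-off lambda is reported both in absolute terms and normalized by
the reference value ``1/sqrt(max(n1, n2))``; a normalized value of 1 is the
canonical choice for exact recovery of a genuinely low-rank + sparse
matrix, while on natural stimuli (where the signal model only holds
approximately) sweeping the normalized value trades rank of L against
weight of S.

A plain PCA baseline (projecting the data out of the leading principal
subspace) is included for comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.extmath import randomized_svd

from .synthetic import PatchMatrix

__all__ = [
    "RPCAResult",
    "PCABaselineResult",
    "shrink",
    "svt",
    "reference_lambda",
    "rpca_decompose",
    "RobustPCA",
    "pca_prefilter",
    "estimate_rank",
    "lowrank_weight",
]


def shrink(x, tau: float):
    """Soft-thresholding (shrinkage) operator ``sign(x) * max(|x| - tau, 0)``.

    Applied entrywise; the proximal operator of the l1 norm.
    """
    if tau < 0:
        raise ValueError("tau must be nonnegative")
    x = np.asarray(x, dtype=float)
    out = np.sign(x) * np.maximum(np.abs(x) - tau, 0.0)
    return out if out.ndim else float(out)


def svt(X: np.ndarray, tau: float, method: str = "exact", rank: int | None = None,
        random_state: int = 0) -> np.ndarray:
    """Singular value thresholding: shrinkage applied to the singular values.

    ``U @ shrink(Sigma, tau) @ Vt`` for any SVD ``X = U Sigma Vt``; the
    proximal operator of the nuclear norm.  ``method='randomized'`` is an
    optional speed path using a truncated randomized SVD; the caller must
    supply a ``rank`` at least as large as the number of singular values
    exceeding ``tau`` for the result to match the exact path.
    """
    if tau < 0:
        raise ValueError("tau must be nonnegative")
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("svt requires finite entries")
    if method == "exact":
        U, s, Vt = np.linalg.svd(X, full_matrices=False)
    elif method == "randomized":
        if rank is None:
            raise ValueError("randomized svt requires an explicit rank")
        k = min(rank, min(X.shape))
        U, s, Vt = randomized_svd(X, n_components=k, n_iter=7,
                                  random_state=random_state)
    else:
        raise ValueError(f"unknown svt method {method!r}")
    s_thr = np.maximum(s - tau, 0.0)
    keep = s_thr > 0
    return (U[:, keep] * s_thr[keep]) @ Vt[keep]


def reference_lambda(n1: int, n2: int) -> float:
    """Reference trade-off value ``1/sqrt(max(n1, n2))``.

    The absolute trade-off is ``lambda_abs = lambda_norm * reference_lambda``
    everywhere in this package.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("matrix dimensions must be at least 1")
    return 1.0 / np.sqrt(max(n1, n2))


@dataclass
class RPCAResult:
    """Decomposition ``M ~= L + S`` with trade-off bookkeeping."""

    L: np.ndarray
    S: np.ndarray
    lambda_abs: float
    lambda_norm: float
    iterations: int
    constraint_violation: float
    converged: bool
    trace: np.ndarray = field(default_factory=lambda: np.empty(0))


def rpca_decompose(
    M,
    lambda_norm: float = 1.0,
    tol: float = 1e-7,
    max_iter: int = 500,
    mu0: float | None = None,
    rho: float = 1.5,
) -> RPCAResult:
    """Decompose M into low-rank L plus sparse S by inexact ALM.

    Alternates (i) ``L <- svt(M - S + Y/mu, 1/mu)``,
    (ii) ``S <- shrink(M - L + Y/mu, lambda/mu)``,
    (iii) ``Y <- Y + mu (M - L - S)``, growing mu geometrically by ``rho``
    per iteration (capped at ``1e7 * mu0``), until the relative constraint
    violation ``||M - L - S||_F / ||M||_F`` drops to ``tol`` or ``max_iter``
    is reached.  Non-convergence returns a result flagged
    ``converged=False`` with a warning, never silently.

    Defaults: ``mu0 = 1.25 / sigma_max(M)`` and ``rho = 1.5``, the standard
    schedule for the inexact variant of this iteration; it recovers both
    parts of planted low-rank + sparse instances to high accuracy.
    """
    if isinstance(M, PatchMatrix):
        M = M.data
    M = np.asarray(M, dtype=float)
    if M.ndim != 2:
        raise ValueError("M must be a 2-D matrix")
    if not np.all(np.isfinite(M)):
        raise ValueError("M must have finite entries")
    if lambda_norm <= 0:
        raise ValueError("lambda_norm must be positive")
    n1, n2 = M.shape
    lam = lambda_norm * reference_lambda(n1, n2)
    norm_M = np.linalg.norm(M)
    if norm_M == 0.0:
        return RPCAResult(
            L=np.zeros_like(M), S=np.zeros_like(M), lambda_abs=lam,
            lambda_norm=lambda_norm, iterations=0, constraint_violation=0.0,
            converged=True, trace=np.empty(0),
        )
    sigma_max = np.linalg.norm(M, 2)
    mu = mu0 if mu0 is not None else 1.25 / sigma_max
    mu_cap = 1e7 * mu
    # scale-free warm start for the multiplier matrix
    Y = M / max(sigma_max, np.abs(M).max() / lam)
    S = np.zeros_like(M)
    L = np.zeros_like(M)
    trace = []
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        L = svt(M - S + Y / mu, 1.0 / mu)
        S = shrink(M - L + Y / mu, lam / mu)
        R = M - L - S
        Y = Y + mu * R
        mu = min(mu * rho, mu_cap)
        cv = np.linalg.norm(R) / norm_M
        trace.append(cv)
        if cv <= tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"RPCA did not reach tol={tol:g} within {max_iter} iterations "
            f"(violation {trace[-1]:.3g})",
            RuntimeWarning,
        )
    return RPCAResult(
        L=L, S=S, lambda_abs=lam, lambda_norm=lambda_norm,
        iterations=iterations, constraint_violation=trace[-1],
        converged=converged, trace=np.asarray(trace),
    )


class RobustPCA(TransformerMixin, BaseEstimator):
    """Robust PCA as a scikit-learn style transformer.

    ``fit(X)`` decomposes the matrix ``X`` (rows are samples) into a
    low-rank part ``low_rank_`` and a sparse part ``sparse_``;
    ``fit_transform(X)`` returns the sparse (atypical) part, which is the
    signal handed to the subsequent sparse coding stage.  The decomposition
    is transductive: ``transform`` is only defined for the fitted data.
    """

    def __init__(self, lambda_norm: float = 1.0, tol: float = 1e-7,
                 max_iter: int = 500):
        self.lambda_norm = lambda_norm
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y=None):
        res = rpca_decompose(X, lambda_norm=self.lambda_norm, tol=self.tol,
                             max_iter=self.max_iter)
        self.low_rank_ = res.L
        self.sparse_ = res.S
        self.lambda_abs_ = res.lambda_abs
        self.n_iter_ = res.iterations
        self.constraint_violation_ = res.constraint_violation
        self.converged_ = res.converged
        self._fit_shape = np.asarray(
            X.data if isinstance(X, PatchMatrix) else X
        ).shape
        return self

    def transform(self, X):
        if not hasattr(self, "sparse_"):
            raise RuntimeError("RobustPCA must be fitted before transform")
        shape = np.asarray(X.data if isinstance(X, PatchMatrix) else X).shape
        if shape != self._fit_shape:
            raise ValueError(
                "RobustPCA is transductive: transform only applies to the "
                "fitted matrix"
            )
        return self.sparse_

    def fit_transform(self, X, y=None):
        return self.fit(X).sparse_


@dataclass
class PCABaselineResult:
    """PCA prefilter: orthonormal basis and the out-of-subspace residuals."""

    basis: np.ndarray
    residuals: np.ndarray
    d: int
    mean: np.ndarray = field(default_factory=lambda: np.empty(0))


def pca_prefilter(M, d: int) -> PCABaselineResult:
    """Project the data out of the subspace of the first d principal components.

    Columns of M are samples; the mean column is subtracted, the top-d left
    singular vectors form the orthonormal basis, and the residuals are the
    centered data with the basis projection removed.  This is the baseline
    prefilter the robust decomposition is compared against: it removes the
    high-energy low-frequency content but is brittle to heavy-tailed
    outliers.
    """
    if isinstance(M, PatchMatrix):
        M = M.data
    M = np.asarray(M, dtype=float)
    n, T = M.shape
    if not 0 <= d <= min(n, T):
        raise ValueError(f"d must lie in [0, {min(n, T)}]")
    mean = M.mean(axis=1, keepdims=True)
    C = M - mean
    if d == 0:
        basis = np.zeros((n, 0))
        residuals = C
    else:
        U, _, _ = np.linalg.svd(C, full_matrices=False)
        basis = U[:, :d]
        residuals = C - basis @ (basis.T @ C)
    return PCABaselineResult(basis=basis, residuals=residuals, d=d,
                             mean=mean.ravel())


def estimate_rank(L: np.ndarray, threshold_fraction: float = 0.01) -> int:
    """Count singular values at or above ``threshold_fraction * sigma_max``.

    The intrinsic dimension of the low-rank part; a zero matrix has rank 0.
    """
    if not 0.0 < threshold_fraction < 1.0:
        raise ValueError("threshold_fraction must lie in (0, 1)")
    L = np.asarray(L, dtype=float)
    s = np.linalg.svd(L, compute_uv=False)
    if s.size == 0 or s[0] == 0.0:
        return 0
    return int(np.sum(s >= threshold_fraction * s[0]))


def lowrank_weight(L: np.ndarray, M: np.ndarray) -> float:
    """Frobenius-energy share of L in the decomposition of M.

    ``||L||_F / (||L||_F + ||M - L||_F)``, the relative weight of the
    typical part reported alongside the rank estimate in trade-off sweeps.
    """
    L = np.asarray(L, dtype=float)
    M = np.asarray(M, dtype=float)
    if L.shape != M.shape:
        raise ValueError("L and M must have the same shape")
    norm_M = np.linalg.norm(M)
    if norm_M == 0.0:
        raise ValueError("lowrank_weight is undefined for an all-zero M")
    nl = np.linalg.norm(L)
    ns = np.linalg.norm(M - L)
    return float(nl / (nl + ns))
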