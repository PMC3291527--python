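"""Sparse encoding under an overcomplete dictionary.

Three solvers for the combinatorial problem of picking K dictionary atoms
that best reconstruct a signal:

* ``subspace_pursuit`` — fast greedy refinement of a K-element support by
  alternating expansion (largest-amplitude coordinates of the backprojected
  residual) and shrinkage (K largest least-squares coefficients), reverting
  when the residual stops improving.
* ``cem_optimize`` — the cross-entropy method over Bernoulli support
  distributions: draw candidate supports at random, select the elite, and
  move the inclusion probabilities toward the elite empirical distribution.
  Slow but a global optimizer.
* ``sce_encode`` — the subspace cross-entropy combination: each outer round
  runs a CEM search scored by least-squares residual, then reshapes the
  Bernoulli parameters with the amplitude-ordered backprojection of the
  residual (the subspace-pursuit expansion step recast as a distribution
  update), weighted by the relative residual norm.

Backprojection uses the minimum-norm pseudoinverse of the full dictionary
by default (``correlation`` selects the classic plain-correlation variant).
Top-K selections break ties deterministically by lowest index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, NamedTuple

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "SparseCode",
    "BernoulliSupportDistribution",
    "CEMConfig",
    "least_squares_on_support",
    "subspace_pursuit",
    "cem_optimize",
    "sce_encode",
    "SparseCoder",
]

#: Bernoulli probabilities are kept inside [EPS, 1 - EPS]
EPS = 1e-3


def _dict_matrix(A, check_norms: bool = True) -> np.ndarray:
    """Return the n x m atom matrix, validating unit-norm nonzero columns."""
    A = np.asarray(getattr(A, "A", A), dtype=float)
    if A.ndim != 2:
        raise ValueError("dictionary must be a 2-D matrix")
    if check_norms:
        norms = np.linalg.norm(A, axis=0)
        if np.any(norms < 1e-12):
            raise ValueError("dictionary contains an all-zero column")
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("dictionary columns must have unit Euclidean norm")
    return A


@dataclass
class SparseCode:
    """Support, coefficients and residual of one signal under a dictionary."""

    support: np.ndarray
    coefficients: np.ndarray
    residual_norm: float
    iterations: int = 0
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.support = np.asarray(self.support, dtype=int)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.support.shape != self.coefficients.shape:
            raise ValueError("support and coefficients must align")

    def to_dense(self, m: int) -> np.ndarray:
        s = np.zeros(m)
        s[self.support] = self.coefficients
        return s


@dataclass
class BernoulliSupportDistribution:
    """Independent-Bernoulli distribution over atom supports."""

    p: np.ndarray

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if np.any(self.p < EPS - 1e-12) or np.any(self.p > 1.0 - EPS + 1e-12):
            raise ValueError(f"probabilities must lie in [{EPS}, {1 - EPS}]")
        if self.p.sum() <= 0:
            raise ValueError("expected number of active atoms must be positive")

    @property
    def expected_actives(self) -> float:
        return float(self.p.sum())


@dataclass
class CEMConfig:
    """Hyperparameters of the cross-entropy search (all configurable)."""

    n_samples: int = 1000
    elite_fraction: float = 0.05
    alpha: float = 0.7
    max_iterations: int = 50
    stagnation_patience: int = 5

    def __post_init__(self) -> None:
        if not 0.0 < self.elite_fraction < 1.0:
            raise ValueError("elite_fraction must lie in (0, 1)")
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must lie in (0, 1]")
        if self.n_samples < 1 or self.max_iterations < 1:
            raise ValueError("n_samples and max_iterations must be positive")


class LeastSquaresFit(NamedTuple):
    coefficients: np.ndarray
    degenerate: bool


def least_squares_on_support(A, y: np.ndarray, support) -> LeastSquaresFit:
    """Minimum-norm least-squares solution restricted to selected columns.

    A rank-deficient submatrix (e.g. duplicated columns) still yields the
    minimum-norm solution, with the ``degenerate`` flag set.
    """
    A = _dict_matrix(A, check_norms=False)
    support = np.asarray(support, dtype=int)
    if support.size == 0:
        raise ValueError("support must be nonempty")
    if support.min() < 0 or support.max() >= A.shape[1]:
        raise ValueError("support indices out of range")
    sub = A[:, support]
    coef, _, rank, _ = np.linalg.lstsq(sub, np.asarray(y, dtype=float), rcond=None)
    return LeastSquaresFit(coefficients=coef, degenerate=rank < support.size)


def _top_k(amplitudes: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k largest amplitudes, ties broken by lowest index."""
    order = np.argsort(-amplitudes, kind="stable")
    return order[:k]


def subspace_pursuit(
    A,
    y: np.ndarray,
    K: int,
    max_iter: int = 100,
    expansion_size: int | None = None,
    backprojection: str = "pinv",
    precomputed_backprojector: np.ndarray | None = None,
) -> SparseCode:
    """Greedy K-sparse encoding by subspace pursuit.

    Initialization takes the K largest-amplitude coordinates of the full
    backprojection of ``y``; each iteration expands the candidate set by
    the ``expansion_size`` (default K) largest-amplitude coordinates of the
    backprojected residual, solves least squares on the merged set, shrinks
    back to the K largest coefficients and recomputes the residual.  The
    loop stops when the residual norm fails to decrease (reverting to the
    previous index set), hits zero, or ``max_iter`` is reached, so the
    returned code carries the minimal recorded residual.

    ``backprojection='pinv'`` maps residuals to the representation space
    through the minimum-norm pseudoinverse of the full dictionary;
    ``'correlation'`` uses plain correlations ``A.T @ r``.
    """
    A = _dict_matrix(A)
    y = np.asarray(y, dtype=float).ravel()
    n, m = A.shape
    if y.size != n:
        raise ValueError("signal length must match dictionary rows")
    if not 1 <= K <= n:
        raise ValueError("K must satisfy 1 <= K <= n")
    if expansion_size is None:
        expansion_size = K
    if backprojection == "pinv":
        B = precomputed_backprojector
        if B is None:
            B = np.linalg.pinv(A)
    elif backprojection == "correlation":
        B = A.T
    else:
        raise ValueError(f"unknown backprojection {backprojection!r}")

    support = np.sort(_top_k(np.abs(B @ y), K))
    coef = np.linalg.lstsq(A[:, support], y, rcond=None)[0]
    r = y - A[:, support] @ coef
    res = float(np.linalg.norm(r))
    y_norm = float(np.linalg.norm(y))
    zero_tol = 1e-12 * max(y_norm, 1.0)
    iterations = 0
    for iterations in range(1, max_iter + 1):
        if res <= zero_tol:
            break
        expand = _top_k(np.abs(B @ r), expansion_size)
        merged = np.union1d(support, expand)
        coef_m = np.linalg.lstsq(A[:, merged], y, rcond=None)[0]
        keep = _top_k(np.abs(coef_m), K)
        new_support = np.sort(merged[keep])
        new_coef = np.linalg.lstsq(A[:, new_support], y, rcond=None)[0]
        new_r = y - A[:, new_support] @ new_coef
        new_res = float(np.linalg.norm(new_r))
        if new_res < res - zero_tol:
            support, coef, r, res = new_support, new_coef, new_r, new_res
        else:
            break  # no improvement: keep previous index set
    return SparseCode(
        support=support,
        coefficients=coef,
        residual_norm=res,
        iterations=iterations,
    )


def _truncate_support(mask: np.ndarray, p: np.ndarray, limit: int) -> np.ndarray:
    """Keep only the ``limit`` most probable active bits (ties: lowest index)."""
    active = np.flatnonzero(mask)
    if active.size <= limit:
        return mask
    order = np.argsort(-p[active], kind="stable")
    kept = active[order[:limit]]
    out = np.zeros_like(mask)
    out[kept] = True
    return out


def cem_optimize(
    score: Callable[[np.ndarray], float],
    m: int,
    target_actives: int,
    config: CEMConfig | None = None,
    seed: int | None = None,
    p0: np.ndarray | None = None,
) -> tuple[np.ndarray, BernoulliSupportDistribution, list[dict]]:
    """Cross-entropy optimization of a black-box score over binary vectors.

    Per iteration: draw ``n_samples`` supports from the current Bernoulli
    distribution, score them (larger is better; a sample on which ``score``
    raises is discarded with a warning), select the elite top
    ``elite_fraction``, and blend the inclusion probabilities toward the
    elite bit means with smoothing ``alpha``.  Sampled supports with more
    than ``3 * target_actives`` active bits are truncated to the most
    probable bits before scoring.  Stops after ``max_iterations`` or when
    the best score has stagnated for ``stagnation_patience`` iterations.

    Returns the best sample ever scored, the final distribution, and a
    per-iteration trace; the best-so-far score is non-decreasing.
    """
    if m < 1:
        raise ValueError("m must be at least 1")
    if not 1 <= target_actives <= m:
        raise ValueError("target_actives must lie in [1, m]")
    config = config or CEMConfig()
    rng = np.random.default_rng(seed)
    if p0 is None:
        p = np.full(m, target_actives / m)
    else:
        p = np.asarray(p0, dtype=float).copy()
    p = np.clip(p, EPS, 1.0 - EPS)
    limit = 3 * target_actives
    best_x: np.ndarray | None = None
    best_s = -np.inf
    stagnant = 0
    trace: list[dict] = []
    for it in range(config.max_iterations):
        samples = rng.random((config.n_samples, m)) < p
        scores = np.full(config.n_samples, -np.inf)
        for i in range(config.n_samples):
            x = _truncate_support(samples[i], p, limit)
            samples[i] = x
            try:
                scores[i] = float(score(x))
            except Exception as exc:  # discarded, iteration continues
                warnings.warn(f"score raised on a sample ({exc}); discarded",
                              RuntimeWarning)
        valid = np.isfinite(scores)
        if not valid.any():
            trace.append({"iteration": it, "best": best_s, "n_valid": 0})
            continue
        n_elite = max(1, int(np.floor(config.elite_fraction * valid.sum())))
        order = np.argsort(-scores, kind="stable")
        elite_idx = order[:n_elite]
        elite_mean = samples[elite_idx].mean(axis=0)
        p = config.alpha * elite_mean + (1.0 - config.alpha) * p
        p = np.clip(p, EPS, 1.0 - EPS)
        top = elite_idx[0]
        improved = scores[top] > best_s
        if improved:
            best_s = float(scores[top])
            best_x = samples[top].copy()
            stagnant = 0
        else:
            stagnant += 1
        trace.append({
            "iteration": it,
            "best": best_s,
            "elite_score": float(scores[elite_idx].mean()),
            "n_valid": int(valid.sum()),
        })
        if stagnant >= config.stagnation_patience:
            break
    if best_x is None:
        raise RuntimeError("cross-entropy search produced no valid sample")
    return best_x, BernoulliSupportDistribution(p=p), trace


def _renormalize_expected(p: np.ndarray, K: float, eps: float = EPS) -> np.ndarray:
    """Scale p multiplicatively (with clipping) so that sum(p) = K.

    Bisection on the multiplicative factor t of ``clip(t * p, eps, 1-eps)``,
    whose sum is monotone in t; feasible whenever
    ``m * eps <= K <= m * (1 - eps)``.
    """
    m = p.size
    if not m * eps <= K <= m * (1.0 - eps):
        raise ValueError("target expected actives infeasible under clipping")
    p = np.maximum(p, 1e-300)

    def total(t: float) -> float:
        return float(np.clip(t * p, eps, 1.0 - eps).sum())

    lo, hi = 1e-12, 1e12
    mid = 1.0
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if abs(total(mid) - K) < 1e-10:
            break
        if total(mid) < K:
            lo = mid
        else:
            hi = mid
    return np.clip(mid * p, eps, 1.0 - eps)


@dataclass
class SCEDiagnostics:
    """Per-outer-round diagnostics of the subspace cross-entropy search."""

    residual_norms: list = field(default_factory=list)
    expected_actives: list = field(default_factory=list)
    distributions: list = field(default_factory=list)


def sce_encode(
    A,
    y: np.ndarray,
    K: int,
    config: CEMConfig | None = None,
    outer_iters: int = 5,
    seed: int | None = None,
    backprojection: str = "pinv",
    return_diagnostics: bool = False,
):
    """Subspace cross-entropy sparse encoding.

    Outer loop: run a CEM round whose score for a sampled support T is the
    negative least-squares residual ``-||y - A_T lsq(y, T)||``; take the
    CE-optimized index set and its residual r; form an auxiliary Bernoulli
    distribution q from the amplitude-ordered backprojection of r, scaled
    to K expected active bits; blend it into the sampling distribution with
    weight ``w = min(1, ||r|| / ||y||)``; renormalize to K expected actives
    and clip.  The best support ever seen is kept and returned as a
    ``SparseCode``.
    """
    A = _dict_matrix(A)
    y = np.asarray(y, dtype=float).ravel()
    n, m = A.shape
    if y.size != n:
        raise ValueError("signal length must match dictionary rows")
    if not 1 <= K <= n:
        raise ValueError("K must satisfy 1 <= K <= n")
    if outer_iters < 1:
        raise ValueError("outer_iters must be at least 1")
    config = config or CEMConfig()
    if backprojection == "pinv":
        B = np.linalg.pinv(A)
    elif backprojection == "correlation":
        B = A.T
    else:
        raise ValueError(f"unknown backprojection {backprojection!r}")
    y_norm = float(np.linalg.norm(y))
    zero_tol = 1e-12 * max(y_norm, 1.0)

    def make_score():
        def score(mask: np.ndarray) -> float:
            sup = np.flatnonzero(mask)
            if sup.size == 0:
                return -y_norm  # no reconstruction
            sub = A[:, sup]
            coef = np.linalg.lstsq(sub, y, rcond=None)[0]
            return -float(np.linalg.norm(y - sub @ coef))
        return score

    child_seeds = np.random.SeedSequence(seed).spawn(outer_iters)
    p = np.full(m, K / m)
    best_code: SparseCode | None = None
    diag = SCEDiagnostics()
    score = make_score()
    for outer, child in enumerate(child_seeds, start=1):
        best_x, _, _ = cem_optimize(
            score, m, K, config=config,
            seed=child.generate_state(1)[0] & 0x7FFFFFFF, p0=p,
        )
        sup = np.flatnonzero(best_x)
        if sup.size == 0:
            coef = np.empty(0)
            degenerate = False
        else:
            coef, degenerate = least_squares_on_support(A, y, sup)
        r = y - (A[:, sup] @ coef if sup.size else 0.0)
        res = float(np.linalg.norm(r))
        if best_code is None or res < best_code.residual_norm:
            sup_sorted = np.sort(sup)
            if sup_sorted.size:
                coef_sorted = least_squares_on_support(
                    A, y, sup_sorted).coefficients
                # atoms the least-squares fit did not use carry no support
                active = np.abs(coef_sorted) > 1e-10 * max(y_norm, 1e-300)
                sup_sorted = sup_sorted[active]
                coef_sorted = coef_sorted[active]
                if sup_sorted.size:
                    coef_sorted = least_squares_on_support(
                        A, y, sup_sorted).coefficients
            else:
                coef_sorted = coef
            best_code = SparseCode(
                support=sup_sorted,
                coefficients=coef_sorted,
                residual_norm=res,
                iterations=outer,
                degenerate=bool(degenerate),
            )
        # subspace-pursuit style distribution update
        z = np.abs(B @ r)
        if z.sum() <= 0:
            q = np.full(m, K / m)
        else:
            q = K * z / z.sum()
        q = _renormalize_expected(q, K)
        w = min(1.0, res / max(y_norm, 1e-300))
        p = (1.0 - w) * p + w * q
        p = _renormalize_expected(p, K)
        diag.residual_norms.append(res)
        diag.expected_actives.append(float(p.sum()))
        diag.distributions.append(p.copy())
        if best_code.residual_norm <= zero_tol:
            break
    assert best_code is not None
    if return_diagnostics:
        return best_code, diag
    return best_code


class SparseCoder(TransformerMixin, BaseEstimator):
    """Scikit-learn style sparse coder over a fixed dictionary.

    ``transform(X)`` encodes each row of ``X`` with the selected algorithm
    (``'sp'`` for subspace pursuit, ``'sce'`` for subspace cross-entropy,
    ``'cem'`` for a single plain cross-entropy round) and returns the dense
    ``(n_samples, n_atoms)`` code matrix.
    """

    def __init__(self, dictionary=None, k: int = 3, algorithm: str = "sp",
                 cem_config: CEMConfig | None = None, outer_iters: int = 5,
                 random_state: int | None = None):
        self.dictionary = dictionary
        self.k = k
        self.algorithm = algorithm
        self.cem_config = cem_config
        self.outer_iters = outer_iters
        self.random_state = random_state

    def fit(self, X=None, y=None):
        if self.dictionary is None:
            raise ValueError("SparseCoder requires a dictionary")
        self.dictionary_ = _dict_matrix(self.dictionary)
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "dictionary_"):
            self.fit()
        X = np.asarray(X, dtype=float)
        A = self.dictionary_
        n, m = A.shape
        codes = np.zeros((X.shape[0], m))
        ss = np.random.SeedSequence(self.random_state).spawn(X.shape[0])
        B = np.linalg.pinv(A)
        for i, child in enumerate(ss):
            if self.algorithm == "sp":
                code = subspace_pursuit(A, X[i], self.k,
                                        precomputed_backprojector=B)
            elif self.algorithm in ("sce", "cem"):
                outer = 1 if self.algorithm == "cem" else self.outer_iters
                code = sce_encode(
                    A, X[i], self.k, config=self.cem_config,
                    outer_iters=outer,
                    seed=child.generate_state(1)[0] & 0x7FFFFFFF,
                )
            else:
                raise ValueError(f"unknown algorithm {self.algorithm!r}")
            codes[i] = code.to_dense(m)
        return codes
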