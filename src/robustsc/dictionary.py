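"""Overcomplete dictionary learning and the two-stage coding pipeline.

The sparse coding objective trades reconstruction error against the number
of active coefficients.  It is solved by alternating optimization: encode
each sample with a fixed dictionary (subspace pursuit or subspace
cross-entropy, see :mod:`robustsc.solvers`), then take a stochastic
gradient step on the reconstruction error with respect to the dictionary,
updating only the columns active in the code and renormalizing them to
unit norm.  Without the unit-norm constraint the l0-penalized objective is
degenerate under column rescaling, so renormalization after every update
is part of the model.

``two_stage_pipeline`` composes the full model: robust PCA first splits
the normalized patches into a low-rank typical part L and a sparse
atypical part S, then the dictionary is trained on the columns of S and
each sample is reconstructed as its L column plus the sparse combination
of learned atoms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .rpca import RPCAResult, rpca_decompose
from .solvers import CEMConfig, SparseCode, sce_encode, subspace_pursuit
from .synthetic import PatchMatrix

__all__ = [
    "Dictionary",
    "TrainingTrace",
    "init_dictionary",
    "sgd_update",
    "train_sparse_coder",
    "two_stage_pipeline",
    "TwoStageResult",
    "DictionaryLearner",
]

logger = logging.getLogger(__name__)


@dataclass
class Dictionary:
    """An ``n x m`` feature matrix with unit-norm columns (atoms)."""

    A: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        if self.A.ndim != 2 or self.A.shape[1] < 1:
            raise ValueError("dictionary must be a 2-D matrix with m >= 1")
        norms = np.linalg.norm(self.A, axis=0)
        if np.any(norms < 1e-12):
            raise ValueError("dictionary contains an all-zero column")
        if np.any(np.abs(norms - 1.0) > 1e-8):
            raise ValueError("dictionary columns must have unit norm within 1e-8")

    @property
    def n(self) -> int:
        return self.A.shape[0]

    @property
    def m(self) -> int:
        return self.A.shape[1]

    @property
    def overcompleteness(self) -> float:
        return self.m / self.n


@dataclass
class TrainingTrace:
    """Per-epoch diagnostics of dictionary training."""

    mean_residual: list = field(default_factory=list)
    mean_support: list = field(default_factory=list)
    eta: list = field(default_factory=list)


def init_dictionary(n: int, m: int, seed: int | None = None) -> Dictionary:
    """Random dictionary with i.i.d. Gaussian columns of unit norm."""
    if n < 1 or m < 1:
        raise ValueError("n and m must be positive")
    if m < n:
        logger.warning("dictionary is undercomplete (m=%d < n=%d)", m, n)
    rng = np.random.default_rng(seed)
    A = rng.standard_normal((n, m))
    A /= np.linalg.norm(A, axis=0)
    return Dictionary(A=A, seed=seed)


def _sgd_update_inplace(A: np.ndarray, x: np.ndarray, support: np.ndarray,
                        coefficients: np.ndarray, eta: float) -> None:
    if support.size == 0:
        return
    r = x - A[:, support] @ coefficients
    A[:, support] += eta * np.outer(r, coefficients)
    norms = np.linalg.norm(A[:, support], axis=0)
    norms[norms < 1e-12] = 1.0
    A[:, support] /= norms


def sgd_update(A, x: np.ndarray, code: SparseCode, eta: float) -> Dictionary:
    """One stochastic gradient step on the reconstruction error.

    Only columns in the code's support change:
    ``A_j <- A_j + eta * (x - A s) * s_j``, after which those columns are
    renormalized to unit norm.  When the residual vanishes the gradient is
    zero and the dictionary is returned unchanged.
    """
    if eta <= 0:
        raise ValueError("eta must be positive")
    seed = getattr(A, "seed", None)
    mat = np.array(getattr(A, "A", A), dtype=float, copy=True)
    _sgd_update_inplace(mat, np.asarray(x, dtype=float).ravel(),
                        code.support, code.coefficients, eta)
    return Dictionary(A=mat, seed=seed)


def _encode_one(A: np.ndarray, x: np.ndarray, K: int, solver: str,
                cem_config: CEMConfig | None, outer_iters: int,
                seed: int | None, backprojector: np.ndarray | None) -> SparseCode:
    if solver == "sp":
        return subspace_pursuit(A, x, K, precomputed_backprojector=backprojector)
    if solver == "sce":
        return sce_encode(A, x, K, config=cem_config, outer_iters=outer_iters,
                          seed=seed)
    raise ValueError(f"unknown solver {solver!r}")


def train_sparse_coder(
    X,
    m: int,
    K: int,
    epochs: int,
    eta0: float = 0.1,
    tau: float = 5.0,
    solver: str = "sp",
    seed: int | None = None,
    cem_config: CEMConfig | None = None,
    outer_iters: int = 3,
) -> tuple[Dictionary, TrainingTrace]:
    """Learn an overcomplete dictionary by alternating encode / update.

    Per sample: encode with the chosen solver at the current dictionary,
    then apply one stochastic gradient update.  Samples are shuffled each
    epoch (seeded); the learning rate decays as ``eta0 / (1 + epoch/tau)``.
    If the mean residual grows tenfold over an epoch the learning rate is
    halved and the event logged.  ``epochs=0`` returns the initial
    dictionary unchanged.
    """
    data = X.data if isinstance(X, PatchMatrix) else np.asarray(X, dtype=float)
    n, T = data.shape
    if K > n:
        raise ValueError("K may not exceed the input dimension")
    rng = np.random.default_rng(seed)
    A = init_dictionary(n, m, seed=int(rng.integers(2**31))).A
    trace = TrainingTrace()
    eta_scale = 1.0
    prev_mean = None
    for epoch in range(epochs):
        eta = eta_scale * eta0 / (1.0 + epoch / tau)
        order = rng.permutation(T)
        resid_sum = 0.0
        supp_sum = 0.0
        pinv_A = np.linalg.pinv(A) if solver == "sp" else None
        for t in order:
            x = data[:, t]
            sample_seed = int(rng.integers(2**31)) if solver == "sce" else None
            code = _encode_one(A, x, K, solver, cem_config, outer_iters,
                               sample_seed, pinv_A)
            _sgd_update_inplace(A, x, code.support, code.coefficients, eta)
            if solver == "sp":
                pinv_A = np.linalg.pinv(A)
            resid_sum += code.residual_norm
            supp_sum += np.count_nonzero(code.coefficients)
        mean_resid = resid_sum / T
        trace.mean_residual.append(mean_resid)
        trace.mean_support.append(supp_sum / T)
        trace.eta.append(eta)
        if prev_mean is not None and mean_resid > 10.0 * prev_mean:
            eta_scale *= 0.5
            logger.warning(
                "training diverging at epoch %d (mean residual %.3g -> %.3g); "
                "halving learning rate", epoch, prev_mean, mean_resid,
            )
        prev_mean = mean_resid
    return Dictionary(A=A, seed=seed), trace


@dataclass
class TwoStageResult:
    """Output of the full decomposition-then-sparse-coding pipeline."""

    rpca: RPCAResult | None
    L: np.ndarray
    S: np.ndarray
    dictionary: Dictionary
    codes: list
    trace: TrainingTrace

    def reconstruct(self, index: int) -> np.ndarray:
        """Reconstruction of sample ``index``: L column + sparse combination."""
        code = self.codes[index]
        return self.L[:, index] + self.dictionary.A[:, code.support] @ code.coefficients


def two_stage_pipeline(
    P,
    lambda_norm: float,
    m: int,
    K: int,
    epochs: int = 1,
    solver: str = "sp",
    seed: int | None = None,
    rpca_tol: float = 1e-7,
    rpca_max_iter: int = 500,
    eta0: float = 0.1,
    tau: float = 5.0,
    cem_config: CEMConfig | None = None,
    outer_iters: int = 3,
) -> TwoStageResult:
    """Robust decomposition followed by overcomplete sparse coding.

    The patch matrix P is decomposed by robust PCA at the given normalized
    trade-off (``lambda_norm=0`` disables the prefilter: L = 0, S = P,
    which reduces the pipeline to plain sparse coding).  The sparse part is
    stored as ``S = P - L`` so that the additive bookkeeping ``P = L + S``
    holds exactly; the dictionary is then trained on the columns of S and
    every column re-encoded with the final dictionary.
    """
    data = P.data if isinstance(P, PatchMatrix) else np.asarray(P, dtype=float)
    if lambda_norm < 0:
        raise ValueError("lambda_norm must be nonnegative")
    if lambda_norm == 0.0:
        rpca_res = None
        L = np.zeros_like(data)
        S = data.copy()
    else:
        rpca_res = rpca_decompose(data, lambda_norm=lambda_norm, tol=rpca_tol,
                                  max_iter=rpca_max_iter)
        L = rpca_res.L
        S = data - L  # absorb the residual so that P = L + S exactly
    if np.abs(S).max() < 1e-12 * max(np.abs(data).max(), 1e-300):
        raise RuntimeError(
            "degenerate decomposition: the atypical part vanished (trade-off "
            "too large); nothing left to sparse-code"
        )
    ss = np.random.SeedSequence(seed).spawn(2)
    train_seed = int(ss[0].generate_state(1)[0] & 0x7FFFFFFF)
    encode_seed_rng = np.random.default_rng(
        int(ss[1].generate_state(1)[0] & 0x7FFFFFFF))
    dictionary, trace = train_sparse_coder(
        S, m=m, K=K, epochs=epochs, eta0=eta0, tau=tau, solver=solver,
        seed=train_seed, cem_config=cem_config, outer_iters=outer_iters,
    )
    A = dictionary.A
    pinv_A = np.linalg.pinv(A)
    codes = []
    for t in range(S.shape[1]):
        sample_seed = (int(encode_seed_rng.integers(2**31))
                       if solver == "sce" else None)
        codes.append(
            _encode_one(A, S[:, t], K, solver, cem_config, outer_iters,
                        sample_seed, pinv_A)
        )
    return TwoStageResult(rpca=rpca_res, L=L, S=S, dictionary=dictionary,
                          codes=codes, trace=trace)


class DictionaryLearner(BaseEstimator):
    """Scikit-learn style estimator for overcomplete dictionary learning.

    ``fit(X)`` learns ``n_atoms`` unit-norm atoms from the rows of ``X``
    (samples as rows, as in scikit-learn's decomposition estimators) and
    exposes them as ``components_`` of shape ``(n_atoms, n_features)``;
    ``transform(X)`` returns the sparse codes as a dense matrix.
    """

    def __init__(self, n_atoms: int = 64, k: int = 3, epochs: int = 1,
                 eta0: float = 0.1, tau: float = 5.0, solver: str = "sp",
                 cem_config: CEMConfig | None = None, outer_iters: int = 3,
                 random_state: int | None = None):
        self.n_atoms = n_atoms
        self.k = k
        self.epochs = epochs
        self.eta0 = eta0
        self.tau = tau
        self.solver = solver
        self.cem_config = cem_config
        self.outer_iters = outer_iters
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_samples, n_features)")
        dictionary, trace = train_sparse_coder(
            X.T, m=self.n_atoms, K=self.k, epochs=self.epochs, eta0=self.eta0,
            tau=self.tau, solver=self.solver, seed=self.random_state,
            cem_config=self.cem_config, outer_iters=self.outer_iters,
        )
        self.dictionary_ = dictionary
        self.components_ = dictionary.A.T
        self.trace_ = trace
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "dictionary_"):
            raise RuntimeError("DictionaryLearner must be fitted first")
        X = np.asarray(X, dtype=float)
        A = self.dictionary_.A
        pinv_A = np.linalg.pinv(A)
        rng = np.random.default_rng(self.random_state)
        codes = np.zeros((X.shape[0], A.shape[1]))
        for i in range(X.shape[0]):
            sample_seed = (int(rng.integers(2**31))
                           if self.solver == "sce" else None)
            code = _encode_one(A, X[i], self.k, self.solver, self.cem_config,
                               self.outer_iters, sample_seed, pinv_A)
            codes[i] = code.to_dense(A.shape[1])
        return codes

    def fit_transform(self, X, y=None):
        return self.fit(X).transform(X)
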