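"""Synthetic stimulus generators and patch plumbing.

Every input class the two-stage coding pipeline assumes can be produced
here without external downloads: exactly low-rank-plus-sparse matrices,
images with power-law (~1/frequency) amplitude spectra emulating natural
scenes, k-sparse signals under a known dictionary, parametric Gabor
patches, and the patch extraction / normalization / temporal-concatenation
steps that turn images into training matrices.

All generators are pure functions of their arguments and a seed: rerunning
with the same seed yields byte-identical output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .gabor import GaborParams, gabor_patch

__all__ = [
    "ImageStack",
    "PatchMatrix",
    "PlantedDecomposition",
    "generate_lowrank_sparse",
    "generate_pink_noise_images",
    "extract_patches",
    "normalize_patches",
    "concatenate_temporal",
    "generate_planted_codes",
    "generate_gabor_patch",
]

logger = logging.getLogger(__name__)

#: default rejection threshold for nearly constant patches
DEFAULT_REJECT_STD = 1e-6


@dataclass
class ImageStack:
    """Stack of grayscale images, shape ``(height, width, n_images)``."""

    pixels: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 3:
            raise ValueError("pixels must be a 3-D array (height, width, n_images)")
        if self.pixels.shape[0] < 2 or self.pixels.shape[1] < 2:
            raise ValueError("images must be at least 2x2")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixel values must be finite")

    @property
    def n_images(self) -> int:
        return self.pixels.shape[2]


@dataclass
class PatchMatrix:
    """Column-wise stacked stimulus patches.

    ``data`` is an ``n x T`` matrix whose columns are row-major vectorized
    patches; ``patch_shape`` is ``(h, w)`` for static patches or
    ``(h, w, frames)`` for temporally concatenated ones.
    """

    data: np.ndarray
    patch_shape: tuple
    normalized: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D matrix (pixels x patches)")
        self.patch_shape = tuple(int(v) for v in self.patch_shape)
        if int(np.prod(self.patch_shape)) != self.data.shape[0]:
            raise ValueError(
                f"patch_shape {self.patch_shape} inconsistent with "
                f"{self.data.shape[0]} rows"
            )

    @property
    def n_pixels(self) -> int:
        return self.data.shape[0]

    @property
    def n_patches(self) -> int:
        return self.data.shape[1]


@dataclass
class PlantedDecomposition:
    """Ground-truth low-rank + entrywise-sparse instance, ``M = L0 + S0``."""

    M: np.ndarray
    L0: np.ndarray
    S0: np.ndarray
    rank_r: int
    sparse_fraction: float
    seed: int | None = None


def generate_lowrank_sparse(
    n1: int,
    n2: int,
    rank_r: int,
    sparse_fraction: float,
    magnitude: float = 1.0,
    seed: int | None = None,
) -> PlantedDecomposition:
    """Plant an exactly low-rank plus entrywise-sparse matrix.

    ``L0`` is the product of two independent standard-normal factor
    matrices scaled by ``1/sqrt(min(n1, n2))``; ``S0`` places
    ``floor(sparse_fraction * n1 * n2)`` spikes of value ``+-magnitude``
    (random signs) at uniformly random locations.  ``M = L0 + S0`` exactly.
    """
    if rank_r > min(n1, n2):
        raise ValueError("rank_r may not exceed min(n1, n2)")
    if rank_r < 0:
        raise ValueError("rank_r must be nonnegative")
    if not 0.0 <= sparse_fraction <= 1.0:
        raise ValueError("sparse_fraction must lie in [0, 1]")
    if magnitude <= 0:
        raise ValueError("magnitude must be positive")
    rng = np.random.default_rng(seed)
    if rank_r == 0:
        L0 = np.zeros((n1, n2))
    else:
        U = rng.standard_normal((n1, rank_r))
        V = rng.standard_normal((rank_r, n2))
        L0 = (U @ V) / np.sqrt(min(n1, n2))
    S0 = np.zeros((n1, n2))
    n_spikes = int(np.floor(sparse_fraction * n1 * n2))
    if n_spikes > 0:
        flat = rng.choice(n1 * n2, size=n_spikes, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_spikes)
        S0.ravel()[flat] = signs * magnitude
    return PlantedDecomposition(
        M=L0 + S0,
        L0=L0,
        S0=S0,
        rank_r=rank_r,
        sparse_fraction=sparse_fraction,
        seed=seed,
    )


def generate_pink_noise_images(
    count: int,
    size: int,
    spectral_exponent: float = 1.0,
    seed: int | None = None,
) -> ImageStack:
    """Generate images whose amplitude spectrum falls as ``f**-exponent``.

    White Gaussian noise is shaped in the Fourier domain by multiplying its
    amplitude with ``frequency**(-spectral_exponent)`` (zero frequency set
    to 0) and transformed back; the result is real-valued.  With exponent 1
    this emulates the famous 1/frequency amplitude statistics of natural
    images; exponent 0 returns (zero-mean) white noise.
    """
    if size < 8:
        raise ValueError("size must be at least 8")
    if count < 1:
        raise ValueError("count must be at least 1")
    rng = np.random.default_rng(seed)
    fx = np.fft.fftfreq(size)
    fr = np.hypot(fx[None, :], fx[:, None])
    with np.errstate(divide="ignore"):
        gain = np.where(fr > 0, fr ** (-spectral_exponent), 0.0)
    pixels = np.empty((size, size, count))
    for i in range(count):
        white = rng.standard_normal((size, size))
        shaped = np.fft.ifft2(np.fft.fft2(white) * gain).real
        pixels[:, :, i] = shaped
    return ImageStack(pixels=pixels, provenance=f"pink-noise exponent={spectral_exponent}")


def extract_patches(
    images: ImageStack,
    patch_size: tuple[int, int],
    count: int,
    seed: int | None = None,
) -> PatchMatrix:
    """Extract ``count`` patches at uniformly random positions and images.

    Patches are vectorized row-major into columns; no normalization is
    applied.
    """
    h, w = int(patch_size[0]), int(patch_size[1])
    H, W, n_img = images.pixels.shape
    if h > H or w > W:
        raise ValueError(f"patch {h}x{w} does not fit inside {H}x{W} images")
    if count < 1:
        raise ValueError("count must be at least 1")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n_img, size=count)
    ys = rng.integers(0, H - h + 1, size=count)
    xs = rng.integers(0, W - w + 1, size=count)
    data = np.empty((h * w, count))
    for t in range(count):
        patch = images.pixels[ys[t] : ys[t] + h, xs[t] : xs[t] + w, idx[t]]
        data[:, t] = patch.ravel(order="C")
    return PatchMatrix(data=data, patch_shape=(h, w), normalized=False)


def normalize_patches(
    P: PatchMatrix,
    reject_std_below: float = DEFAULT_REJECT_STD,
) -> PatchMatrix:
    """Normalize every patch column to zero mean and unit standard deviation.

    The population (divide-by-n) convention is used: the patch is the entire
    population of its pixels.  Columns whose raw standard deviation falls
    below ``reject_std_below`` are dropped and the drop count logged; if all
    columns are rejected a ``ValueError`` is raised.  The operation is
    idempotent on already-normalized input.
    """
    data = P.data
    means = data.mean(axis=0)
    stds = data.std(axis=0)  # population convention
    keep = stds >= reject_std_below
    n_dropped = int((~keep).sum())
    if n_dropped == data.shape[1]:
        raise ValueError("all columns rejected as near-constant")
    if n_dropped:
        logger.warning("normalize_patches dropped %d near-constant columns", n_dropped)
    out = (data[:, keep] - means[keep]) / stds[keep]
    return PatchMatrix(data=out, patch_shape=P.patch_shape, normalized=True)


def concatenate_temporal(
    patch_sequences: list[PatchMatrix | np.ndarray],
    frames: int,
) -> PatchMatrix:
    """Stack per-frame patch matrices into spatio-temporal columns.

    ``patch_sequences`` holds one patch matrix per frame (all the same
    shape); each frame column is normalized individually (zero mean, unit
    population std) and the ``frames`` vectorized frames are stacked in
    temporal order.  The stacked column is *not* re-normalized, so the
    output carries ``normalized=False``.
    """
    if frames < 1:
        raise ValueError("frames must be at least 1")
    if len(patch_sequences) != frames:
        raise ValueError(
            f"expected {frames} frame matrices, got {len(patch_sequences)}"
        )
    mats = []
    shape0 = None
    for fr_idx, item in enumerate(patch_sequences):
        if isinstance(item, PatchMatrix):
            mat, pshape = item.data, item.patch_shape
        else:
            mat = np.asarray(item, dtype=float)
            side = int(round(np.sqrt(mat.shape[0])))
            if side * side != mat.shape[0]:
                raise ValueError("raw frame arrays must have square patches")
            pshape = (side, side)
        if len(pshape) != 2:
            raise ValueError("frame patches must be static (h, w) patches")
        if shape0 is None:
            shape0, t0 = pshape, mat.shape[1]
        elif pshape != shape0 or mat.shape[1] != t0:
            raise ValueError(f"frame {fr_idx} has inconsistent shape")
        norm = normalize_patches(
            PatchMatrix(data=mat, patch_shape=pshape), reject_std_below=0.0
        )
        mats.append(norm.data)
    stacked = np.vstack(mats)
    h, w = shape0
    return PatchMatrix(data=stacked, patch_shape=(h, w, frames), normalized=False)


def generate_planted_codes(
    A,
    k: int,
    T: int,
    noise_sigma: float = 0.0,
    seed: int | None = None,
) -> tuple[PatchMatrix, np.ndarray]:
    """Generate signals as exactly k-sparse combinations of dictionary atoms.

    Each column is ``x = A @ s + eps`` with ``s`` having exactly ``k``
    nonzeros (uniform support, standard-normal amplitudes) and ``eps``
    i.i.d. Gaussian with standard deviation ``noise_sigma``.  Returns the
    signal matrix and the dense ``m x T`` matrix of true codes.
    """
    A = np.asarray(getattr(A, "A", A), dtype=float)
    n, m = A.shape
    if k > m:
        raise ValueError("k may not exceed the number of dictionary atoms")
    if k < 0:
        raise ValueError("k must be nonnegative")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be nonnegative")
    rng = np.random.default_rng(seed)
    codes = np.zeros((m, T))
    for t in range(T):
        if k > 0:
            support = rng.choice(m, size=k, replace=False)
            codes[support, t] = rng.standard_normal(k)
    X = A @ codes
    if noise_sigma > 0:
        X = X + noise_sigma * rng.standard_normal(X.shape)
    side = int(round(np.sqrt(n)))
    pshape = (side, side) if side * side == n else (n, 1)
    return PatchMatrix(data=X, patch_shape=pshape, normalized=False), codes


def generate_gabor_patch(params: GaborParams, size: int) -> np.ndarray:
    """Evaluate a parametric Gabor patch on a ``size x size`` grid."""
    return gabor_patch(params, size)
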