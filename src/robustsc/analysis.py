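"""Receptive-field characterization of learned filters.

Learned dictionary atoms (or linear filters estimated by reverse
correlation) are compared with early-vision receptive fields the standard
way: each filter is fitted with a parametric Gabor patch by bounded
nonlinear least squares (best of several seeded random restarts), the
dimensionless shape parameters ``nx = sigma_x * f`` and ``ny = sigma_y * f``
are collected over the population after discarding edge-localized and
vanishingly small fits, and reconstruction quality and spectral content
are summarized by mean SNR, radial amplitude spectra and the canonical
``f * exp(-(f/f0)^4)`` whitening-filter profile.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .gabor import GaborParams, gabor_patch
from .synthetic import PatchMatrix

__all__ = [
    "GaborFit",
    "reverse_correlation",
    "fit_gabor",
    "population_shapes",
    "mean_snr",
    "radial_amplitude_spectrum",
    "whitening_filter",
    "effective_filter_size",
]

logger = logging.getLogger(__name__)

#: per-column SNR ceiling (dB) for numerically exact reconstructions
SNR_CAP_DB = 100.0


@dataclass
class GaborFit:
    """Best-of-restarts Gabor fit of one filter."""

    params: GaborParams
    amplitude: float
    rmse: float
    discarded: str | None = None

    @property
    def nx(self) -> float:
        return self.params.nx

    @property
    def ny(self) -> float:
        return self.params.ny


def _as_filter_matrix(filters) -> np.ndarray:
    if isinstance(filters, PatchMatrix):
        return filters.data
    mat = np.asarray(getattr(filters, "A", filters), dtype=float)
    if mat.ndim != 2:
        raise ValueError("filters must form a 2-D matrix (pixels x units)")
    return mat


def reverse_correlation(stimuli, responses, ridge: float | None = None) -> np.ndarray:
    """Least-squares linear filter per unit from stimulus/response pairs.

    Solves the whitened cross-correlation ``(S S^T / T)^-1 (S R / T)`` with
    stimuli as columns of S and responses as a ``T x units`` matrix; for
    white stimuli this reduces to the plain spike-triggered average.  A
    singular stimulus covariance falls back to a small ridge regularizer,
    which is logged.
    """
    S = _as_filter_matrix(stimuli)
    R = np.asarray(responses, dtype=float)
    if R.ndim == 1:
        R = R[:, None]
    n, T = S.shape
    if R.shape[0] != T:
        raise ValueError("stimulus and response sample counts must match")
    C = S @ S.T / T
    X = S @ R / T
    if ridge is not None:
        C = C + ridge * np.eye(n)
    try:
        F = np.linalg.solve(C, X)
        if not np.all(np.isfinite(F)):
            raise np.linalg.LinAlgError("non-finite solution")
    except np.linalg.LinAlgError:
        reg = 1e-8 * np.trace(C) / n
        if reg <= 0:
            reg = 1e-12
        logger.warning(
            "singular stimulus covariance; ridge fallback with regularizer %.3g",
            reg,
        )
        F = np.linalg.solve(C + reg * np.eye(n), X)
    return F


def _gabor_model(theta_vec: np.ndarray, side: int) -> np.ndarray:
    x0, y0, th, f, phi, sx, sy, amp = theta_vec
    params = GaborParams(x0=x0, y0=y0, theta=th, f=f, phi=phi,
                         sigma_x=max(sx, 1e-9), sigma_y=max(sy, 1e-9))
    return gabor_patch(params, side, amplitude=amp)


def _data_driven_init(patch: np.ndarray, side: int) -> np.ndarray:
    """Moment/FFT based initial guess (center, dominant frequency, phase)."""
    w = patch**2
    total = w.sum()
    if total <= 0:
        cx = cy = (side - 1) / 2.0
        return np.array([cx, cy, 0.0, 0.1, 0.0, side / 4.0, side / 4.0, 1.0])
    ys, xs = np.mgrid[0:side, 0:side]
    cx = float((w * xs).sum() / total)
    cy = float((w * ys).sum() / total)
    F = np.fft.fft2(patch)
    amp = np.abs(F)
    amp[0, 0] = 0.0
    ky, kx = np.unravel_index(np.argmax(amp), amp.shape)
    fy = np.fft.fftfreq(side)[ky]
    fx = np.fft.fftfreq(side)[kx]
    f = float(np.hypot(fx, fy))
    th = float(np.mod(np.arctan2(fy, fx), np.pi))
    phi = float(np.angle(F[ky, kx]))
    scale = float(np.abs(patch).max())
    sigma = max(side / 6.0, 0.5)
    return np.array([cx, cy, th, max(f, 0.02), phi, sigma, sigma,
                     scale if scale > 0 else 1.0])


def _canonicalize(theta_vec: np.ndarray) -> np.ndarray:
    """Resolve the (theta + pi, -phi) Gabor symmetry to theta in [0, pi)."""
    out = theta_vec.copy()
    th = np.mod(out[2], 2.0 * np.pi)
    phi = out[4]
    if th >= np.pi:
        th -= np.pi
        phi = -phi
    out[2] = th
    out[4] = np.mod(phi, 2.0 * np.pi)
    return out


def fit_gabor(patch: np.ndarray, n_restarts: int = 20,
              seed: int | None = None) -> GaborFit:
    """Fit a Gabor function to a square patch by nonlinear least squares.

    The optimization runs from ``n_restarts`` initializations — one
    data-driven guess (intensity centroid, dominant Fourier component) and
    the rest drawn uniformly inside the parameter box — and the best
    solution by root-mean-square error is kept.  Parameter bounds: center
    within ``[-2, side + 2]``, frequency in ``[0, 0.5]`` cycles/pixel,
    envelope widths in ``[0.05, side]``.  The orientation is reported
    modulo pi (canonicalizing the (theta + pi, -phi) symmetry).  Seeded:
    the same patch and seed give an identical fit.
    """
    patch = np.asarray(patch, dtype=float)
    if patch.ndim != 2 or patch.shape[0] != patch.shape[1]:
        raise ValueError("patch must be square")
    side = patch.shape[0]
    if side < 4:
        raise ValueError("patch side must be at least 4")
    rng = np.random.default_rng(seed)
    scale = float(np.abs(patch).max())
    amp_bound = 10.0 * scale if scale > 0 else 10.0
    lower = np.array([-2.0, -2.0, -np.pi, 0.0, -2.0 * np.pi, 0.05, 0.05,
                      -amp_bound])
    upper = np.array([side + 2.0, side + 2.0, 2.0 * np.pi, 0.5, 2.0 * np.pi,
                      float(side), float(side), amp_bound])

    def residual(theta_vec):
        return (_gabor_model(theta_vec, side) - patch).ravel()

    inits = [_data_driven_init(patch, side)]
    for _ in range(max(0, n_restarts - 1)):
        x0 = rng.uniform(
            [0.0, 0.0, 0.0, 0.0, 0.0, 0.5, 0.5, -max(scale, 1e-3)],
            [side - 1.0, side - 1.0, np.pi, 0.45, 2.0 * np.pi,
             side / 2.0, side / 2.0, max(scale, 1e-3)],
        )
        inits.append(x0)

    best_vec = None
    best_cost = np.inf
    for x0 in inits:
        x0 = np.clip(x0, lower + 1e-12, upper - 1e-12)
        try:
            sol = least_squares(residual, x0, bounds=(lower, upper),
                                method="trf")
        except Exception:
            continue
        if sol.cost < best_cost:
            best_cost = sol.cost
            best_vec = sol.x
    if best_vec is None:
        params = GaborParams(x0=0.0, y0=0.0, theta=0.0, f=0.0, phi=0.0,
                             sigma_x=1e-6, sigma_y=1e-6)
        return GaborFit(params=params, amplitude=0.0, rmse=np.inf,
                        discarded="too_small")
    best_vec = _canonicalize(best_vec)
    rmse = float(np.sqrt(np.mean((_gabor_model(best_vec, side) - patch) ** 2)))
    params = GaborParams(
        x0=float(best_vec[0]), y0=float(best_vec[1]), theta=float(best_vec[2]),
        f=float(best_vec[3]), phi=float(best_vec[4]),
        sigma_x=float(best_vec[5]), sigma_y=float(best_vec[6]),
    )
    return GaborFit(params=params, amplitude=float(best_vec[7]), rmse=rmse)


def population_shapes(
    filters,
    patch_side: int,
    margin: float = 1.0,
    min_sigma: float = 0.3,
    n_restarts: int = 20,
    seed: int | None = None,
) -> pd.DataFrame:
    """Fit every filter with a Gabor and tabulate population shape statistics.

    Filters whose fitted center falls within ``margin`` pixels of the patch
    border (or outside it) are flagged ``edge``; fits with an envelope
    width below ``min_sigma`` pixels (default 0.3) are flagged
    ``too_small``.  Retained rows carry the dimensionless shape parameters
    ``nx = sigma_x * f`` and ``ny = sigma_y * f``.
    """
    mat = _as_filter_matrix(filters)
    if mat.shape[0] != patch_side * patch_side:
        raise ValueError("filters are not reshapeable to the given patch side")
    ss = np.random.SeedSequence(seed).spawn(mat.shape[1])
    rows = []
    for j, child in enumerate(ss):
        patch = mat[:, j].reshape(patch_side, patch_side)
        fit = fit_gabor(patch, n_restarts=n_restarts,
                        seed=int(child.generate_state(1)[0] & 0x7FFFFFFF))
        discarded = fit.discarded
        p = fit.params
        if discarded is None:
            inside = (margin <= p.x0 <= patch_side - 1 - margin
                      and margin <= p.y0 <= patch_side - 1 - margin)
            if not inside:
                discarded = "edge"
            elif min(p.sigma_x, p.sigma_y) < min_sigma:
                discarded = "too_small"
        rows.append({
            "filter_id": j, "x0": p.x0, "y0": p.y0, "theta": p.theta,
            "f": p.f, "phi": p.phi, "sigma_x": p.sigma_x, "sigma_y": p.sigma_y,
            "amplitude": fit.amplitude, "rmse": fit.rmse,
            "nx": p.nx, "ny": p.ny,
            "discarded": discarded if discarded is not None else "",
        })
    return pd.DataFrame(rows)


def mean_snr(X, Xhat, cap_db: float = SNR_CAP_DB) -> float:
    """Mean reconstruction SNR in dB over columns.

    Per column: ``10 log10(||x||^2 / ||x - xhat||^2)``, capped at
    ``cap_db`` when the residual is (numerically) zero.  Zero-norm columns
    are skipped with a warning.
    """
    X = _as_filter_matrix(X)
    Xh = _as_filter_matrix(Xhat)
    if X.shape != Xh.shape:
        raise ValueError("X and Xhat must have the same shape")
    signal = np.sum(X**2, axis=0)
    noise = np.sum((X - Xh) ** 2, axis=0)
    keep = signal > 0
    if not keep.all():
        warnings.warn(f"skipping {int((~keep).sum())} zero-norm columns",
                      RuntimeWarning)
    if not keep.any():
        raise ValueError("no nonzero columns to evaluate")
    with np.errstate(divide="ignore"):
        snr = 10.0 * np.log10(signal[keep] / noise[keep])
    return float(np.mean(np.minimum(snr, cap_db)))


def _as_image_stack(inputs) -> np.ndarray:
    """Coerce patches/filters to a (side, side, count) stack."""
    if hasattr(inputs, "pixels"):
        return np.asarray(inputs.pixels, dtype=float)
    if isinstance(inputs, PatchMatrix):
        if len(inputs.patch_shape) != 2 or inputs.patch_shape[0] != inputs.patch_shape[1]:
            raise ValueError("radial spectrum requires square static patches")
        side = inputs.patch_shape[0]
        return inputs.data.T.reshape(-1, side, side).transpose(1, 2, 0)
    arr = np.asarray(inputs, dtype=float)
    if arr.ndim == 3:
        return arr
    if arr.ndim == 2:
        if arr.shape[0] == arr.shape[1]:
            return arr[:, :, None]
        side = int(round(np.sqrt(arr.shape[0])))
        if side * side != arr.shape[0]:
            raise ValueError("columns are not square patches")
        return arr.T.reshape(-1, side, side).transpose(1, 2, 0)
    raise ValueError("cannot interpret input as square patches")


def radial_amplitude_spectrum(inputs, n_bins: int | None = None
                              ) -> tuple[np.ndarray, np.ndarray]:
    """Radially averaged 2-D Fourier amplitude spectrum, rescaled to [0, 1].

    The amplitude spectra of all inputs are averaged, binned by radial
    frequency up to the Nyquist limit (0.5 cycles/pixel) and normalized by
    the maximum bin.  Returns ``(bin_center_frequencies, amplitudes)``.
    """
    stack = _as_image_stack(inputs)
    h, w, count = stack.shape
    if h != w:
        raise ValueError("inputs must be square")
    if n_bins is None:
        n_bins = max(4, h // 2)
    amp = np.zeros((h, w))
    for i in range(count):
        amp += np.abs(np.fft.fft2(stack[:, :, i]))
    amp /= count
    fx = np.fft.fftfreq(w)
    fy = np.fft.fftfreq(h)
    fr = np.hypot(fx[None, :], fy[:, None])
    edges = np.linspace(0.0, 0.5, n_bins + 1)
    centers, means = [], []
    for b in range(n_bins):
        mask = (fr >= edges[b]) & (fr < edges[b + 1])
        if b == n_bins - 1:
            mask = (fr >= edges[b]) & (fr <= edges[b + 1])
        if mask.any():
            centers.append(0.5 * (edges[b] + edges[b + 1]))
            means.append(amp[mask].mean())
    curve = np.asarray(means)
    peak = curve.max()
    if peak > 0:
        curve = curve / peak
    return np.asarray(centers), curve


def whitening_filter(size: int, f0: float | None = None) -> np.ndarray:
    """Radially symmetric whitening gain ``f * exp(-(f/f0)^4)`` on the FFT grid.

    Flattens a ~1/f amplitude spectrum at low frequencies while rolling off
    near the cutoff ``f0`` (default 0.8 x Nyquist = 0.4 cycles/pixel); the
    gain is zero at DC.  Returned in unshifted FFT ordering.
    """
    if size < 8:
        raise ValueError("size must be at least 8")
    if f0 is None:
        f0 = 0.8 * 0.5
    if not 0.0 < f0 <= 0.5:
        raise ValueError("cutoff f0 must lie in (0, Nyquist]")
    f = np.fft.fftfreq(size)
    fr = np.hypot(f[None, :], f[:, None])
    return fr * np.exp(-((fr / f0) ** 4))


def effective_filter_size(filters, mass_fraction: float = 0.9) -> np.ndarray:
    """Fraction of coefficients holding ``mass_fraction`` of squared mass.

    For each filter column: the smallest number of coefficients whose
    squared values sum to at least the requested fraction of the total,
    divided by the filter length.  Structurally sparse (localized) filters
    score low; global filters approach the mass fraction itself.
    """
    if not 0.0 < mass_fraction <= 1.0:
        raise ValueError("mass_fraction must lie in (0, 1]")
    mat = _as_filter_matrix(filters)
    n = mat.shape[0]
    out = np.empty(mat.shape[1])
    for j in range(mat.shape[1]):
        sq = np.sort(mat[:, j] ** 2)[::-1]
        total = sq.sum()
        if total <= 0:
            out[j] = 0.0
            continue
        cum = np.cumsum(sq)
        out[j] = (int(np.searchsorted(cum, mass_fraction * total)) + 1) / n
    return out
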