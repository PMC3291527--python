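"""Parametric Gabor patches.

A Gabor patch is a Gaussian envelope multiplied by a cosine carrier.  It is
the standard parametric model for simple-cell receptive fields in primary
visual cortex, and the shape parameters ``nx = sigma_x * f`` and
``ny = sigma_y * f`` (envelope width in units of the carrier period) are the
conventional dimensionless summary of a fitted receptive field.

Conventions: pixel (0, 0) is the top-left corner, the x axis runs along
columns and the y axis along rows; ``theta`` is the orientation of the
normal to the stripes, so the carrier varies along the rotated x' axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GaborParams", "gabor_patch"]


@dataclass(frozen=True)
class GaborParams:
    """Parameters of a two-dimensional Gabor function.

    Attributes
    ----------
    x0, y0 : float
        Center of the envelope in pixel coordinates (x along columns).
    theta : float
        Orientation (radians) of the normal to the parallel stripes.
    f : float
        Carrier frequency in cycles per pixel, ``f >= 0``.
    phi : float
        Phase of the cosine carrier (radians).
    sigma_x, sigma_y : float
        Envelope standard deviations (pixels) along the rotated axes;
        their ratio is the ellipticity of the Gaussian envelope.
    """

    x0: float
    y0: float
    theta: float
    f: float
    phi: float
    sigma_x: float
    sigma_y: float

    def __post_init__(self) -> None:
        if not (self.sigma_x > 0 and self.sigma_y > 0):
            raise ValueError("envelope widths sigma_x, sigma_y must be positive")
        if self.f < 0:
            raise ValueError("carrier frequency f must be nonnegative")

    @property
    def nx(self) -> float:
        """Dimensionless shape parameter ``sigma_x * f``."""
        return self.sigma_x * self.f

    @property
    def ny(self) -> float:
        """Dimensionless shape parameter ``sigma_y * f``."""
        return self.sigma_y * self.f


def gabor_patch(params: GaborParams, size: int, amplitude: float = 1.0) -> np.ndarray:
    """Evaluate a Gabor function on a ``size`` x ``size`` pixel grid.

    The function is ``amplitude * exp(-x'^2/(2 sigma_x^2) - y'^2/(2 sigma_y^2))
    * cos(2 pi f x' + phi)`` where (x', y') are the coordinates rotated by
    ``theta`` about the center (x0, y0).

    Parameters
    ----------
    params : GaborParams
        Gabor parameters; widths must be positive.
    size : int
        Side length of the square grid, at least 4.
    amplitude : float
        Overall scale of the patch.

    Returns
    -------
    numpy.ndarray of shape (size, size)
    """
    if size < 4:
        raise ValueError("size must be at least 4")
    y, x = np.mgrid[0:size, 0:size].astype(float)
    dx = x - params.x0
    dy = y - params.y0
    c, s = np.cos(params.theta), np.sin(params.theta)
    xp = dx * c + dy * s
    yp = -dx * s + dy * c
    envelope = np.exp(
        -(xp**2) / (2.0 * params.sigma_x**2) - (yp**2) / (2.0 * params.sigma_y**2)
    )
    carrier = np.cos(2.0 * np.pi * params.f * xp + params.phi)
    return amplitude * envelope * carrier
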