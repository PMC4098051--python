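"""Trend correction by least-squares second-order polynomial surface fitting.

Pixel values differ systematically between lung and chest-wall regions, so
before any texture analysis each ROI has a quadratic intensity surface

    f(x, y) = c00 + c10 x + c01 y + c20 x^2 + c11 x y + c02 y^2

fitted by least squares over all pixels and subtracted.  Coordinates are
centred at the ROI midpoint, which conditions the design matrix; the fit is
a linear orthogonal projection, so correcting twice equals correcting once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import EnhancedImage, as_matrix


@dataclass
class TrendFit:
    """Fitted surface coefficients (c00, c10, c01, c20, c11, c02) and the
    RMS of the residual (intensity units)."""

    coeffs: np.ndarray
    residual_rms: float


def design_matrix(n: int) -> np.ndarray:
    """Quadratic-surface design matrix on centred grid coordinates.

    Rows follow C order of the pixel grid; columns are
    ``[1, x, y, x^2, x*y, y^2]`` with ``x`` the column coordinate and ``y``
    the row coordinate, both in ``[-(n-1)/2, (n-1)/2]``.
    """
    c = (n - 1) / 2.0
    y, x = np.mgrid[0:n, 0:n].astype(float)
    x = (x - c).ravel()
    y = (y - c).ravel()
    return np.column_stack([np.ones_like(x), x, y, x * x, x * y, y * y])


def fit_poly2_surface(roi) -> TrendFit:
    """Least-squares fit of a second-order polynomial surface to an ROI."""
    m = as_matrix(roi)
    if not np.all(np.isfinite(m)):
        raise ValueError("cannot fit a trend surface to non-finite pixels")
    n = m.shape[0]
    if m.ndim != 2 or m.shape[1] != n:
        raise ValueError("trend fitting requires a square matrix")
    if m.size < 6:
        raise ValueError("need at least 6 pixels to fit 6 coefficients")
    A = design_matrix(n)
    coeffs, *_ = np.linalg.lstsq(A, m.ravel(), rcond=None)
    resid = m.ravel() - A @ coeffs
    return TrendFit(coeffs=coeffs, residual_rms=float(np.sqrt(np.mean(resid**2))))


def evaluate_surface(coeffs: np.ndarray, n: int) -> np.ndarray:
    """Evaluate fitted coefficients on the n x n centred grid."""
    return (design_matrix(n) @ np.asarray(coeffs, dtype=float)).reshape(n, n)


def trend_correct(roi) -> EnhancedImage:
    """Subtract the fitted quadratic surface from an ROI.

    The output has (numerically) zero mean and is orthogonal to every
    quadratic basis surface.
    """
    m = as_matrix(roi)
    fit = fit_poly2_surface(m)
    corrected = m - evaluate_surface(fit.coeffs, m.shape[0])
    return EnhancedImage(
        matrix=corrected,
        branch="trend_only",
        params={"residual_rms": fit.residual_rms},
    )
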