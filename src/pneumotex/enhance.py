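"""The three enhancement branches applied to trend-corrected ROIs.

1.  Radial window functions (Hanning / Hamming / Blackman) taper the ROI
    towards its border, suppressing the spectral leakage lines that the
    discontinuous ROI edge would otherwise put on the u and v axes of the
    power spectrum.
2.  Morphological top-hat transform (image minus its grayscale opening with
    a flat square structuring element) keeps bright structures smaller than
    the structuring element -- nodular and irregular opacities -- while
    removing larger ridges such as vessels.
3.  Gray-level co-occurrence feature image: the joint probability matrix of
    gray-level pairs at displacement d along the 45/225-degree diagonal,
    computed on a quantized (default 6-bit) version of the trend-corrected
    ROI.  The probability matrix itself is the feature image handed to the
    spectrum stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import EnhancedImage, as_matrix

WINDOW_KINDS = ("hanning", "hamming", "blackman")


@dataclass(frozen=True)
class GlcomParams:
    """Co-occurrence parameters: displacement in pixels along the fixed
    45/225-degree direction pair, and quantization depth in bits."""

    distance_px: int = 1
    bits: int = 6

    def __post_init__(self) -> None:
        if self.distance_px < 1:
            raise ValueError("distance_px must be >= 1")
        if not 4 <= self.bits <= 12:
            raise ValueError("bits must be in [4, 12]")

    @property
    def levels(self) -> int:
        return 1 << self.bits


def window_weight(kind: str, n, N: int):
    """Window-function value at radial position ``n`` for length ``N``.

    Valid positions are ``-(N-1)/2 <= n <= (N-1)/2``; beyond that (the ROI
    corners under the radial rule) ``n`` is clamped to ``(N-1)/2`` so the
    weight takes the formula's edge value instead of wrapping around.
    """
    if kind not in WINDOW_KINDS:
        raise ValueError(f"unknown window kind {kind!r}")
    if N < 2:
        raise ValueError("window length N must be >= 2")
    half = (N - 1) / 2.0
    n = np.clip(np.abs(np.asarray(n, dtype=float)), 0.0, half)
    phase = 2.0 * np.pi * n / (N - 1)
    if kind == "hanning":
        w = 0.5 + 0.5 * np.cos(phase)
    elif kind == "hamming":
        w = 0.54 + 0.46 * np.cos(phase)
    else:  # blackman
        w = 0.42 + 0.5 * np.cos(phase) + 0.08 * np.cos(2.0 * phase)
    return w if w.ndim else float(w)


def radial_window(kind: str, N: int) -> np.ndarray:
    """N x N radially symmetric window: weight(r) at each pixel's Euclidean
    distance r from the matrix centre."""
    c = (N - 1) / 2.0
    y, x = np.mgrid[0:N, 0:N].astype(float)
    r = np.hypot(x - c, y - c)
    return np.asarray(window_weight(kind, r, N))


def apply_window(img, kind: str) -> EnhancedImage:
    """Multiply a trend-corrected image by the radial window of ``kind``."""
    m = as_matrix(img)
    w = radial_window(kind, m.shape[0])
    return EnhancedImage(matrix=m * w, branch="window", params={"kind": kind})


def _check_se(se_size: int, img_size: int) -> None:
    if se_size % 2 == 0:
        raise ValueError("structuring element size must be odd (no defined centre)")
    if se_size < 3:
        raise ValueError("structuring element size must be >= 3")
    if se_size > img_size:
        raise ValueError("structuring element larger than the image")


def opening(img, se_size: int) -> np.ndarray:
    """Grayscale opening (erosion then dilation) with a flat square
    structuring element; borders handled by edge replication."""
    m = as_matrix(img)
    _check_se(se_size, m.shape[0])
    return ndimage.grey_opening(m, size=(se_size, se_size), mode="nearest")


def top_hat(img, se_size: int) -> EnhancedImage:
    """White top-hat: image minus its opening.

    Nonnegative by the anti-extensivity of opening; retains bright
    structures smaller than the structuring element.
    """
    m = as_matrix(img)
    out = m - opening(m, se_size)
    return EnhancedImage(matrix=out, branch="tophat", params={"se_size": se_size})


def quantize(img, bits: int) -> np.ndarray:
    """Linear min-max rescale to integer gray levels 0 .. 2^bits - 1.

    A constant image maps to all zeros.  Bin widths are equal; the maximum
    value falls in the top bin.
    """
    if not 4 <= bits <= 12:
        raise ValueError("bits must be in [4, 12]")
    m = as_matrix(img)
    levels = 1 << bits
    lo, hi = float(m.min()), float(m.max())
    if hi == lo:
        return np.zeros_like(m, dtype=np.int64)
    q = np.floor((m - lo) / (hi - lo) * levels).astype(np.int64)
    return np.clip(q, 0, levels - 1)


def glcom_image(q: np.ndarray, params: GlcomParams) -> EnhancedImage:
    """Co-occurrence feature image of a quantized matrix.

    Pairs ``(q[p], q[p + d*(1, 1)])`` are counted along the 45-degree
    diagonal and its 225-degree reverse (making the matrix symmetric), then
    normalized to sum to 1, yielding the joint probability matrix used as a
    2^bits x 2^bits feature image.
    """
    q = np.asarray(q)
    if not np.issubdtype(q.dtype, np.integer):
        if not np.all(q == np.round(q)):
            raise ValueError("glcom_image requires an integer-valued matrix")
        q = q.astype(np.int64)
    levels = params.levels
    if q.min() < 0 or q.max() >= levels:
        raise ValueError(f"gray levels must lie in [0, {levels})")
    d = params.distance_px
    if d >= min(q.shape):
        raise ValueError("displacement exceeds image size")
    # 45 degrees: destination is d rows up, d columns right
    src = q[d:, :-d].ravel()
    dst = q[:-d, d:].ravel()
    counts = np.zeros((levels, levels), dtype=float)
    np.add.at(counts, (src, dst), 1.0)
    counts += counts.T.copy()  # 225 degrees is the reverse displacement
    total = counts.sum()
    if total > 0:
        counts /= total
    return EnhancedImage(
        matrix=counts,
        branch="glcom",
        params={"distance_px": d, "bits": params.bits},
    )
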