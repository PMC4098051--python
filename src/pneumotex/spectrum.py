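"""Power spectra, radial axis profiles, and feature-vector assembly.

The discrimination signal used throughout the pipeline is the distribution
of power-spectrum (PS) energy along the two radial directions through the
spectrum centre that carry the most aggregate energy -- the *main* and
*second* axes.  Each axis contributes its PS values at positive radial bins
1 .. N/2 (the DC bin is never a feature); the two profiles are concatenated
and jointly normalized so the branch feature vector has maximum 1.

Feature lengths: 32 for the image-domain branches (window, top-hat,
trend-corrected), 64 for the 6-bit co-occurrence feature image (a 64 x 64
matrix), and 128 for the combined window + top-hat + co-occurrence vector.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np

from .core import EnhancedImage, as_matrix
from .enhance import GlcomParams, apply_window, glcom_image, quantize, top_hat
from .preprocess import trend_correct


@dataclass
class PowerSpectrum:
    """Centred 2-D power spectrum of an enhanced image.

    ``matrix`` holds squared DFT magnitudes with zero frequency at the
    centre; ``pixel_mm`` is the sampling interval of the source image (None
    for the co-occurrence branch, whose axes are gray levels, not space).
    """

    matrix: np.ndarray
    pixel_mm: Optional[float]
    source_branch: str

    @property
    def size(self) -> int:
        return self.matrix.shape[0]


@dataclass
class AxisProfile:
    """PS values at positive radial bins 1 .. N/2 along one direction."""

    angle_deg: float
    values: np.ndarray
    rank: str  # "main" or "second"


@dataclass
class FeatureVector:
    """Per-branch normalized axis-profile features and their concatenation.

    ``branch_features`` maps branch name to its normalized vector (main
    profile followed by second profile).  ``combined`` concatenates the
    window, top-hat and co-occurrence branches in that fixed order
    (32 + 32 + 64 = 128 values).
    """

    branch_features: Dict[str, np.ndarray]
    angles: Dict[str, Tuple[float, float]] = field(default_factory=dict)

    @property
    def combined(self) -> np.ndarray:
        return np.concatenate(
            [self.branch_features[b] for b in ("window", "tophat", "glcom")]
        )


def power_spectrum(img) -> PowerSpectrum:
    """Squared magnitude of the unnormalized 2-D DFT, centred with fftshift.

    The DC bin may be large; it is never used as a feature.  For a real
    input the spectrum is centrally symmetric.
    """
    if isinstance(img, EnhancedImage):
        branch = img.branch
        pixel_mm = img.params.get("pixel_mm")
    else:
        branch, pixel_mm = "trend_only", None
    m = as_matrix(img)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("power_spectrum requires a square matrix")
    ps = np.abs(np.fft.fftshift(np.fft.fft2(m))) ** 2
    return PowerSpectrum(matrix=ps, pixel_mm=pixel_mm, source_branch=branch)


def bin_frequency(k: int, N: int, pixel_mm: float) -> float:
    """Spatial frequency (cycles/mm) of DFT bin ``k`` for an N-pixel image
    sampled at ``pixel_mm`` millimetres per pixel: k / (N * pixel_mm)."""
    if not 0 <= k <= N / 2:
        raise ValueError(f"bin index {k} outside [0, {N // 2}]")
    if pixel_mm <= 0:
        raise ValueError("pixel_mm must be positive")
    return k / (N * pixel_mm)


def candidate_angles(N: int) -> np.ndarray:
    """Quantized radial directions: all angles from the centre to lattice
    points on the half-spectrum boundary, folded to [0, 180) degrees."""
    h = N // 2
    pts = [(a, h) for a in range(-h, h + 1)]        # top edge
    pts += [(h, b) for b in range(0, h)]            # right edge
    pts += [(-h, b) for b in range(1, h)]           # left edge
    angles = {round(np.degrees(np.arctan2(b, a)) % 180.0, 9) for a, b in pts}
    return np.array(sorted(angles))


def sample_radial_line(ps_matrix: np.ndarray, angle_deg: float) -> np.ndarray:
    """PS values at radial bins 1 .. N/2 along ``angle_deg``, sampling the
    nearest lattice point at each integer radius (folding to the symmetric
    point when the offset leaves the grid, which is licensed by the central
    symmetry of a real image's PS)."""
    N = ps_matrix.shape[0]
    c = N // 2
    theta = np.radians(angle_deg)
    out = np.empty(N // 2)
    for i, r in enumerate(range(1, N // 2 + 1)):
        col = c + int(round(r * np.cos(theta)))
        row = c + int(round(r * np.sin(theta)))
        if not (0 <= row < N and 0 <= col < N):
            row, col = 2 * c - row, 2 * c - col
        out[i] = ps_matrix[row, col]
    return out


def find_axes(ps: PowerSpectrum) -> Tuple[AxisProfile, AxisProfile]:
    """Locate the main and second radial axes of a power spectrum.

    Each quantized direction is scored by the sum of PS over its positive
    bins 1 .. N/2; the main axis is the argmax and the second axis the
    best-scoring remaining direction (ties broken toward the smaller
    angle).  Only the positive half-spectrum is scanned -- the negative
    half mirrors it.  An all-zero spectrum yields all-zero profiles at the
    default angles 0 and 90 degrees.
    """
    m = ps.matrix
    angles = candidate_angles(m.shape[0])
    if not m.any():
        half = np.zeros(m.shape[0] // 2)
        return (
            AxisProfile(0.0, half, "main"),
            AxisProfile(90.0, half.copy(), "second"),
        )
    profiles = [sample_radial_line(m, a) for a in angles]
    scores = np.array([p.sum() for p in profiles])
    # argmax/argsort are stable, so ties resolve to the smaller angle
    order = np.argsort(-scores, kind="stable")
    i_main, i_second = order[0], order[1]
    return (
        AxisProfile(float(angles[i_main]), profiles[i_main], "main"),
        AxisProfile(float(angles[i_second]), profiles[i_second], "second"),
    )


def normalize_profile(values: np.ndarray) -> np.ndarray:
    """Divide a nonnegative feature vector by its maximum, mapping it into
    [0, 1] with max exactly 1.  Applied to the concatenated (main, second)
    profile pair, so the pair shares one scale.  An all-zero vector is
    returned unchanged with a warning."""
    values = np.asarray(values, dtype=float)
    if np.any(values < 0):
        raise ValueError("profiles must be nonnegative")
    peak = values.max() if values.size else 0.0
    if peak == 0.0:
        warnings.warn("all-zero profile cannot be normalized", RuntimeWarning,
                      stacklevel=2)
        return values.copy()
    return values / peak


def axis_features(ps: PowerSpectrum) -> Tuple[np.ndarray, Tuple[float, float]]:
    """Normalized (main, second) concatenated profile of one spectrum."""
    main, second = find_axes(ps)
    vec = normalize_profile(np.concatenate([main.values, second.values]))
    return vec, (main.angle_deg, second.angle_deg)


def branch_image(roi, branch: str, *, window_kind: str = "blackman",
                 se_size: int = 17, glcom_distance: int = 1,
                 glcom_bits: int = 6) -> EnhancedImage:
    """Run trend correction followed by one enhancement branch."""
    tc = trend_correct(roi)
    if branch == "trend_only":
        return tc
    if branch == "window":
        return apply_window(tc, window_kind)
    if branch == "tophat":
        return top_hat(tc, se_size)
    if branch == "glcom":
        params = GlcomParams(distance_px=glcom_distance, bits=glcom_bits)
        return glcom_image(quantize(tc.matrix, glcom_bits), params)
    raise ValueError(f"unknown branch {branch!r}")


def build_feature_vector(roi, branches=("trend_only", "window", "tophat", "glcom"),
                         **params) -> FeatureVector:
    """Full feature extraction for one ROI.

    For each requested branch: trend-correct, enhance, Fourier-transform,
    locate the main/second axes and normalize the concatenated profile
    pair.  Keyword parameters are passed to :func:`branch_image`.
    """
    feats: Dict[str, np.ndarray] = {}
    angles: Dict[str, Tuple[float, float]] = {}
    for branch in branches:
        img = branch_image(roi, branch, **params)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            vec, ang = axis_features(power_spectrum(img))
        feats[branch] = vec
        angles[branch] = ang
    return FeatureVector(branch_features=feats, angles=angles)
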