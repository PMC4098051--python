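"""Core domain types shared across the pipeline stages.

The unit of analysis is a small square grayscale patch (ROI) cut from the
lung field of a chest radiograph: 32 x 32 pixels at 0.175 mm/pixel, on a
12-bit-like intensity scale.  Every enhancement stage consumes and produces
:class:`EnhancedImage` matrices tagged with the branch that produced them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: ILO profusion subcategories handled by the pipeline, from normal lung
#: (0/0) to severe profusion (3/3).
SUBCATEGORIES = ("0/0", "1/1", "2/2", "3/3")

#: ILO shape/size classes: p/q/r are small rounded opacities of increasing
#: diameter, s/t are fine/medium irregular (linear) opacities.
SHAPE_CLASSES = ("p", "q", "r", "s", "t")
ROUNDED_CLASSES = ("p", "q", "r")
IRREGULAR_CLASSES = ("s", "t")

#: Diameter range (mm) per rounded size class, following the ILO convention
#: (p up to 1.5 mm, q 1.5-3 mm, r 3-10 mm).
OPACITY_DIAMETER_MM = {
    "p": (0.6, 1.5),
    "q": (1.5, 3.0),
    "r": (3.0, 10.0),
}

#: Expected number of opacities per ROI for each profusion subcategory.
#: Ordered to mimic increasing profusion; zero for a normal lung.
OPACITY_DENSITY = {"0/0": 0.0, "1/1": 3.0, "2/2": 7.0, "3/3": 14.0}

#: Enhancement branch identifiers.
BRANCHES = ("trend_only", "window", "tophat", "glcom")


@dataclass(frozen=True)
class TextureConfig:
    """Parameters of the synthetic lung-texture generator.

    Parameters
    ----------
    roi_size
        Side length of the square ROI in pixels (>= 8).
    pixel_mm
        Sampling interval in millimetres per pixel.
    subcategory
        ILO profusion subcategory; ``"0/0"`` means normal lung.
    shape_size
        Opacity class for abnormal ROIs (``p``/``q``/``r`` rounded,
        ``s``/``t`` irregular).
    opacity_density
        Expected opacities per ROI.  ``None`` resolves to the subcategory
        default in :data:`OPACITY_DENSITY`.  Must be 0 for 0/0.
    contrast
        Peak opacity amplitude expressed as a multiple of the background
        noise standard deviation.
    trend_coeffs
        Six coefficients (c00, c10, c01, c20, c11, c02) of the second-order
        polynomial background surface, evaluated on centred pixel
        coordinates.
    noise_sd
        Standard deviation of the correlated background noise
        (intensity units on the stored scale).
    noise_correlation_px
        Gaussian correlation length of the background noise, in pixels.
    ridge_rate
        Expected number of vessel-like ridges per ROI (Poisson mean).
    ridge_amplitude
        Ridge peak amplitude as a multiple of ``noise_sd``.
    ridge_fwhm_px
        Full width at half maximum of the ridge cross-section, in pixels.
        The default corresponds to a large vessel (about 3.5 mm at
        0.175 mm/pixel) -- wide enough that the top-hat transform with its
        default structuring elements suppresses most of it.
    seed
        Master RNG seed; per-ROI streams are derived from ``(seed, id)``.
    """

    roi_size: int = 32
    pixel_mm: float = 0.175
    subcategory: str = "0/0"
    shape_size: str = "q"
    opacity_density: Optional[float] = None
    contrast: float = 2.5
    trend_coeffs: tuple = (2048.0, 8.0, -5.0, 0.4, 0.15, -0.25)
    noise_sd: float = 30.0
    noise_correlation_px: float = 1.2
    ridge_rate: float = 1.5
    ridge_amplitude: float = 1.5
    ridge_fwhm_px: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.roi_size < 8:
            raise ValueError(f"roi_size must be >= 8, got {self.roi_size}")
        if self.pixel_mm <= 0:
            raise ValueError("pixel_mm must be positive")
        if self.subcategory not in SUBCATEGORIES:
            raise ValueError(
                f"subcategory must be one of {SUBCATEGORIES}, got {self.subcategory!r}"
            )
        if self.shape_size not in SHAPE_CLASSES:
            raise ValueError(
                f"shape_size must be one of {SHAPE_CLASSES}, got {self.shape_size!r}"
            )
        if len(self.trend_coeffs) != 6:
            raise ValueError("trend_coeffs must have exactly six coefficients")
        if self.noise_sd < 0 or self.noise_correlation_px < 0:
            raise ValueError("noise parameters must be nonnegative")
        if self.opacity_density is not None:
            if self.opacity_density < 0:
                raise ValueError("opacity_density must be nonnegative")
            if self.subcategory == "0/0" and self.opacity_density != 0:
                raise ValueError("subcategory 0/0 requires opacity_density 0")

    @property
    def density(self) -> float:
        """Resolved expected opacity count per ROI."""
        if self.opacity_density is not None:
            return float(self.opacity_density)
        return OPACITY_DENSITY[self.subcategory]

    @property
    def is_normal(self) -> bool:
        return self.subcategory == "0/0"


@dataclass
class LabelledRoi:
    """A labelled ROI: pixel matrix plus provenance metadata.

    ``label`` is ``"normal"`` iff the generating subcategory is 0/0.
    """

    pixels: np.ndarray
    label: str
    config: TextureConfig
    id: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.shape[0] != self.pixels.shape[1]:
            raise ValueError("ROI pixels must be a square 2-D matrix")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("ROI pixels must be finite")
        if self.label not in ("normal", "abnormal"):
            raise ValueError(f"label must be 'normal' or 'abnormal', got {self.label!r}")


@dataclass
class EnhancedImage:
    """Output of one enhancement branch.

    ``branch`` is one of ``trend_only`` (trend-corrected ROI), ``window``
    (radially windowed), ``tophat`` (morphological top-hat) or ``glcom``
    (gray-level co-occurrence feature image, a 2^bits x 2^bits joint
    probability matrix).
    """

    matrix: np.ndarray
    branch: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("enhanced image must be a square 2-D matrix")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("enhanced image must be finite")
        if self.branch not in BRANCHES:
            raise ValueError(f"unknown branch {self.branch!r}")


def as_matrix(img) -> np.ndarray:
    """Return the underlying 2-D array of an ROI, EnhancedImage or array."""
    if isinstance(img, EnhancedImage):
        return img.matrix
    if isinstance(img, LabelledRoi):
        return img.pixels
    return np.asarray(img, dtype=float)
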