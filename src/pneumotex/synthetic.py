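"""Synthetic lung-texture ROI generator.

Emulates the statistical structure of intercostal lung texture on digitised
chest radiographs at ROI scale: a smooth second-order polynomial intensity
trend (gross anatomy gradient), correlated Gaussian noise (parenchymal
granularity), occasional vessel-like ridges, and -- for abnormal ROIs --
superimposed small opacities: isotropic Gaussian blobs for the rounded
classes p/q/r, short random-walk line elements for the irregular classes
s/t.  Opacity counts are Poisson with a profusion-dependent mean so that
higher subcategories are denser.

Every ROI draws from its own RNG stream derived from ``(master seed, id)``,
so datasets are reproducible and order-independent.  Intensities live on a
12-bit-like scale whose defaults keep them positive; no clamping is applied
in memory (image export clips to the unsigned integer range).
"""

from __future__ import annotations

import zlib
from dataclasses import replace
from typing import Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import (
    IRREGULAR_CLASSES,
    OPACITY_DIAMETER_MM,
    ROUNDED_CLASSES,
    LabelledRoi,
    TextureConfig,
)

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

#: Stroke width (pixels, FWHM-like) of irregular opacity elements.
_IRREGULAR_WIDTH_PX = {"s": 1.0, "t": 2.0}


def _roi_streams(seed: int, roi_id: str) -> Tuple[np.random.Generator, np.random.Generator]:
    """Two independent RNG streams (background, opacities) for one ROI."""
    key = zlib.crc32(roi_id.encode("utf-8"))
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, key])
    bg_ss, op_ss = ss.spawn(2)
    return np.random.default_rng(bg_ss), np.random.default_rng(op_ss)


def _grid(n: int) -> Tuple[np.ndarray, np.ndarray]:
    c = (n - 1) / 2.0
    y, x = np.mgrid[0:n, 0:n].astype(float)
    return x - c, y - c


def polynomial_trend(config: TextureConfig) -> np.ndarray:
    """Second-order polynomial background surface on centred coordinates."""
    x, y = _grid(config.roi_size)
    c00, c10, c01, c20, c11, c02 = config.trend_coeffs
    return c00 + c10 * x + c01 * y + c20 * x * x + c11 * x * y + c02 * y * y


def _background(config: TextureConfig, rng: np.random.Generator) -> np.ndarray:
    img = polynomial_trend(config)
    n = config.roi_size
    if config.noise_sd > 0:
        w = rng.standard_normal((n, n))
        if config.noise_correlation_px > 0:
            w = ndimage.gaussian_filter(w, config.noise_correlation_px, mode="reflect")
        sd = w.std()
        if sd > 0:
            img = img + w * (config.noise_sd / sd)
    if config.ridge_rate > 0 and config.ridge_amplitude > 0 and config.noise_sd > 0:
        n_ridges = rng.poisson(config.ridge_rate)
        x, y = _grid(n)
        amp = config.ridge_amplitude * config.noise_sd
        sigma = max(config.ridge_fwhm_px * _FWHM_TO_SIGMA, 0.5)
        for _ in range(n_ridges):
            theta = rng.uniform(0.0, np.pi)
            offset = rng.uniform(-n / 2.0, n / 2.0)
            # distance of each pixel to the line x sin(t) - y cos(t) = offset
            dist = x * np.sin(theta) - y * np.cos(theta) - offset
            img = img + amp * np.exp(-0.5 * (dist / sigma) ** 2)
    return img


def _add_rounded(img: np.ndarray, config: TextureConfig, rng: np.random.Generator,
                 count: int) -> np.ndarray:
    lo, hi = OPACITY_DIAMETER_MM[config.shape_size]
    n = config.roi_size
    x, y = _grid(n)
    amp = config.contrast * config.noise_sd
    for _ in range(count):
        fwhm_px = rng.uniform(lo, hi) / config.pixel_mm
        cx = rng.uniform(-(n - 1) / 2.0, (n - 1) / 2.0)
        cy = rng.uniform(-(n - 1) / 2.0, (n - 1) / 2.0)
        r2 = (x - cx) ** 2 + (y - cy) ** 2
        img = img + amp * np.exp(-4.0 * np.log(2.0) * r2 / fwhm_px**2)
    return img


def _add_irregular(img: np.ndarray, config: TextureConfig, rng: np.random.Generator,
                   count: int) -> np.ndarray:
    n = config.roi_size
    amp = config.contrast * config.noise_sd
    width = _IRREGULAR_WIDTH_PX[config.shape_size]
    sigma = max(width * _FWHM_TO_SIGMA, 0.4)
    for _ in range(count):
        canvas = np.zeros((n, n))
        length = int(rng.integers(3, 11))
        px = rng.uniform(0, n - 1)
        py = rng.uniform(0, n - 1)
        ang = rng.uniform(0, 2 * np.pi)
        # random-walk stroke: unit steps with angular jitter, stamped at
        # sub-pixel resolution then blurred to the stroke width
        for _step in range(length * 4):
            ix, iy = int(round(px)), int(round(py))
            if 0 <= ix < n and 0 <= iy < n:
                canvas[iy, ix] = 1.0
            ang += rng.normal(0.0, 0.2)
            px += 0.25 * np.cos(ang)
            py += 0.25 * np.sin(ang)
        canvas = ndimage.gaussian_filter(canvas, sigma, mode="constant")
        peak = canvas.max()
        if peak > 0:
            img = img + canvas * (amp / peak)
    return img


def gen_normal_roi(config: TextureConfig, roi_id: str = "roi-000") -> LabelledRoi:
    """Generate one normal-lung ROI (subcategory 0/0 only)."""
    if config.subcategory != "0/0":
        raise ValueError(
            f"gen_normal_roi requires subcategory 0/0, got {config.subcategory!r}"
        )
    bg_rng, _ = _roi_streams(config.seed, roi_id)
    pixels = _background(config, bg_rng)
    return LabelledRoi(pixels=pixels, label="normal", config=config, id=roi_id,
                       meta={"n_opacities": 0})


def gen_abnormal_roi(config: TextureConfig, roi_id: str = "roi-000") -> LabelledRoi:
    """Generate one abnormal ROI: normal background plus planted opacities.

    The opacity count is Poisson with mean ``config.density``; rounded
    classes plant Gaussian blobs with FWHM drawn from the class diameter
    range, irregular classes plant short random-walk line elements.
    """
    if config.subcategory == "0/0":
        raise ValueError("gen_abnormal_roi requires subcategory 1/1, 2/2 or 3/3")
    bg_rng, op_rng = _roi_streams(config.seed, roi_id)
    img = _background(config, bg_rng)
    count = int(op_rng.poisson(config.density))
    if count > 0:
        if config.shape_size in ROUNDED_CLASSES:
            img = _add_rounded(img, config, op_rng, count)
        elif config.shape_size in IRREGULAR_CLASSES:
            img = _add_irregular(img, config, op_rng, count)
    return LabelledRoi(pixels=img, label="abnormal", config=config, id=roi_id,
                       meta={"n_opacities": count})


def gen_roi(config: TextureConfig, roi_id: str = "roi-000") -> LabelledRoi:
    """Dispatch to the normal or abnormal generator by subcategory."""
    if config.is_normal:
        return gen_normal_roi(config, roi_id)
    return gen_abnormal_roi(config, roi_id)


def gen_dataset(configs: Sequence[TextureConfig], n_per_class: int,
                seed: int = 0) -> Tuple[List[LabelledRoi], pd.DataFrame]:
    """Generate ``n_per_class`` ROIs for every config, with a manifest.

    Returns the ROI list and a manifest DataFrame with one row per ROI
    (id, label, subcategory, shape_size, seed).  ROI RNG streams depend
    only on ``(seed, id)``, so the dataset is reproducible and independent
    of generation order.
    """
    configs = list(configs)
    if not configs:
        raise ValueError("gen_dataset requires at least one TextureConfig")
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rois: List[LabelledRoi] = []
    rows = []
    for ci, cfg in enumerate(configs):
        cfg = replace(cfg, seed=seed)
        sub = cfg.subcategory.replace("/", "")
        for i in range(n_per_class):
            roi_id = f"c{ci:02d}-{sub}{cfg.shape_size}-{i:04d}"
            roi = gen_roi(cfg, roi_id)
            rois.append(roi)
            rows.append(
                {
                    "id": roi.id,
                    "label": roi.label,
                    "subcategory": cfg.subcategory,
                    "shape_size": cfg.shape_size,
                    "seed": seed,
                }
            )
    manifest = pd.DataFrame(rows, columns=["id", "label", "subcategory", "shape_size", "seed"])
    return rois, manifest


def default_study_configs(contrast: float = 2.5) -> List[TextureConfig]:
    """A balanced mixed-condition study: one normal config and one abnormal
    config per (subcategory, representative shape) pair."""
    abnormal = [
        ("1/1", "q"), ("2/2", "q"), ("3/3", "q"), ("2/2", "s"), ("3/3", "t"),
    ]
    cfgs = [TextureConfig(subcategory="0/0")]
    cfgs += [
        TextureConfig(subcategory=sub, shape_size=shape, contrast=contrast)
        for sub, shape in abnormal
    ]
    return cfgs
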