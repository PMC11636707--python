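"""Sediment-profile image analysis.

Converts blacklight photographs of core walls into vertical luminophore
concentration profiles. The water column is pre-painted a uniform mask
colour (default RGB 253, 3, 155), which defines the sediment surface
per image column; luminophore pixels are selected by an HSB threshold
on the ImageJ 0–255 convention (defaults Hue 1–130, Saturation 1–250,
Brightness 60–255); each selected pixel is assigned a depth below the
smoothed local surface and accumulated into depth bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter
from skimage.color import rgb2hsv

from .profiles import DEFAULT_N_INPUT, DepthProfile

DEFAULT_MASK_RGB = (253, 3, 155)


@dataclass
class HSBThreshold:
    """Inclusive HSB window on the 0–255 scale (ImageJ convention)."""

    hue_min: int = 1
    hue_max: int = 130
    sat_min: int = 1
    sat_max: int = 250
    bri_min: int = 60
    bri_max: int = 255

    def __post_init__(self) -> None:
        for lo, hi in ((self.hue_min, self.hue_max),
                       (self.sat_min, self.sat_max),
                       (self.bri_min, self.bri_max)):
            if not (0 <= lo <= hi <= 255):
                raise ValueError("each HSB range must satisfy 0 <= min <= max <= 255")


@dataclass
class SurfaceLine:
    """Per-column sediment-surface row index (pixels), smoothed."""

    rows: np.ndarray
    px_per_cm: float

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=float)
        if self.px_per_cm <= 0:
            raise ValueError("px_per_cm must be positive")


def detect_surface(image: np.ndarray, mask_rgb: tuple = DEFAULT_MASK_RGB,
                   smooth_window: int = 5, px_per_cm: float = 20.0,
                   tolerance: int = 0) -> SurfaceLine:
    """Locate the sediment–water interface from the painted water column.

    The surface row in each column is one past the last mask-coloured
    row; columns without any mask pixel are interpolated from their
    neighbours, and the result is smoothed with a running median of
    (odd) width ``smooth_window``. Mask matching is exact by default —
    the colour was applied digitally — with an optional per-channel
    ``tolerance`` for recompressed archival images.
    """
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise ValueError("smooth_window must be odd and >= 1")
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] < 3:
        raise ValueError("expected an RGB image (H, W, 3)")
    target = np.asarray(mask_rgb, dtype=int)
    diff = np.abs(img[:, :, :3].astype(int) - target)
    is_mask = (diff <= tolerance).all(axis=2)
    if not is_mask.any():
        raise ValueError("no water-column mask pixels found in the image")
    h, w = is_mask.shape
    rows = np.full(w, np.nan)
    for col in range(w):
        idx = np.flatnonzero(is_mask[:, col])
        if idx.size:
            rows[col] = idx[-1] + 1
    missing = np.isnan(rows)
    if missing.any():
        cols = np.arange(w)
        rows[missing] = np.interp(cols[missing], cols[~missing], rows[~missing])
    if smooth_window > 1:
        rows = median_filter(rows, size=smooth_window, mode="nearest")
    rows = np.clip(rows, 0, h)
    return SurfaceLine(rows=rows, px_per_cm=px_per_cm)


def threshold_luminophores(image: np.ndarray,
                           thr: HSBThreshold | None = None) -> np.ndarray:
    """Boolean raster of luminophore pixels via the HSB window.

    Hue, saturation and brightness are each mapped to 0–255 to match
    the ImageJ threshold convention; a pixel is tracer iff all three
    components fall inside their inclusive ranges (the default hue
    window 1–130 does not wrap the colour wheel).
    """
    thr = thr or HSBThreshold()
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] < 3:
        raise ValueError("expected an RGB image (H, W, 3)")
    hsv = rgb2hsv(img[:, :, :3])
    h = hsv[:, :, 0] * 255.0
    s = hsv[:, :, 1] * 255.0
    v = hsv[:, :, 2] * 255.0
    return (
        (h >= thr.hue_min) & (h <= thr.hue_max)
        & (s >= thr.sat_min) & (s <= thr.sat_max)
        & (v >= thr.bri_min) & (v <= thr.bri_max)
    )


def extract_profile(mask: np.ndarray, surface: SurfaceLine,
                    bin_width_cm: float | None = None, *,
                    t_yr: float | None = None,
                    n_input: float = DEFAULT_N_INPUT,
                    core_id: str = "", view: str = "",
                    depth_max_cm: float | None = None) -> DepthProfile:
    """Accumulate tracer pixels into depth bins below the local surface.

    Each tracer pixel's depth is ``(row − surface row of its column) /
    px_per_cm``; pixels above the surface (tracer resting on the
    interface) are assigned depth 0. The default bin width is one pixel
    row. An all-zero mask yields a valid, flagged all-zero profile.
    """
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    if surface.rows.shape[0] != w:
        raise ValueError("mask and surface dimensions disagree")
    if bin_width_cm is None:
        bin_width_cm = 1.0 / surface.px_per_cm
    if bin_width_cm <= 0:
        raise ValueError("bin_width_cm must be positive")
    rr, cc = np.nonzero(mask)
    depths = (rr - surface.rows[cc]) / surface.px_per_cm
    depths = np.maximum(depths, 0.0)
    if depth_max_cm is None:
        depth_max_cm = float(np.max((h - surface.rows)) / surface.px_per_cm)
        depth_max_cm = max(depth_max_cm, bin_width_cm)
    n_bins = int(np.ceil(depth_max_cm / bin_width_cm))
    edges = np.arange(n_bins + 1) * bin_width_cm
    counts, _ = np.histogram(np.clip(depths, 0, edges[-1] - 1e-12), bins=edges)
    centres = (edges[:-1] + edges[1:]) / 2
    flags = {} if counts.sum() else {"empty": True}
    return DepthProfile(
        x=centres, counts=counts.astype(float), bin_width=bin_width_cm,
        t_yr=t_yr, n_input=n_input, core_id=core_id, view=view, flags=flags,
    )


def profile_image(image: np.ndarray, *, mask_rgb: tuple = DEFAULT_MASK_RGB,
                  thr: HSBThreshold | None = None, px_per_cm: float = 20.0,
                  smooth_window: int = 5, bin_width_cm: float | None = None,
                  **extract_kwargs) -> DepthProfile:
    """Full image → profile pipeline: surface, threshold, extraction."""
    surface = detect_surface(image, mask_rgb=mask_rgb,
                             smooth_window=smooth_window, px_per_cm=px_per_cm)
    mask = threshold_luminophores(image, thr)
    # the painted water column must never count as tracer
    img = np.asarray(image)
    is_water = (img[:, :, :3].astype(int) == np.asarray(mask_rgb, int)).all(axis=2)
    mask &= ~is_water
    return extract_profile(mask, surface, bin_width_cm, **extract_kwargs)
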