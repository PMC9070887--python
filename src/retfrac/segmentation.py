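"""Retinal vessel segmentation by multiscale line filtering.

The detector follows the multiscale line-operator family used by
semi-automated fundus toolchains: at each scale ``L`` the basic response of
a pixel is the maximum, over a bank of orientations, of the mean intensity
along a length-``L`` line through the pixel minus the mean intensity of the
surrounding ``W x W`` window, evaluated on the inverted image so vessels
(dark on bright) respond positively.  Per-scale responses are standardised,
averaged together with the standardised inverted intensity, and min–max
normalised to [0, 1].  A hysteresis double threshold then keeps pixels above
``t_high`` plus any ``t_low`` pixels 8-connected to them, and the mask is
cleaned by dropping small components and filling small holes.

The whole path is deterministic: identical inputs give bit-identical masks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage.filters import apply_hysteresis_threshold
from skimage.morphology import remove_small_holes, remove_small_objects

__all__ = [
    "SegmentationParams",
    "VesselMask",
    "line_response",
    "double_threshold",
    "clean_mask",
    "segment_vessels",
]


@dataclass(frozen=True)
class SegmentationParams:
    """Tunables of the line detector and the mask post-processing.

    ``line_lengths`` must be odd and no longer than ``window_size`` (also
    odd); ``n_orientations`` spans 180 degrees in equal steps.  Thresholds
    act on the [0, 1]-normalised response.  ``dark_vessels`` says whether
    vessels are darker than background (fundus default); set False for
    bright-on-dark rasters.
    """

    window_size: int = 15
    line_lengths: tuple[int, ...] = (1, 3, 5, 7, 9, 11, 13, 15)
    n_orientations: int = 12
    t_low: float = 0.3
    t_high: float = 0.6
    min_component_px: int = 50
    max_hole_px: int = 20
    dark_vessels: bool = True

    def __post_init__(self) -> None:
        if self.window_size % 2 == 0 or self.window_size < 1:
            raise ValueError("window_size must be odd and positive")
        if not self.line_lengths:
            raise ValueError("line_lengths must be nonempty")
        for L in self.line_lengths:
            if L % 2 == 0 or L < 1 or L > self.window_size:
                raise ValueError(
                    f"line length {L} must be odd, >=1 and <= window_size"
                )
        if not (0 <= self.t_low < self.t_high <= 1):
            raise ValueError("need 0 <= t_low < t_high <= 1")
        if self.n_orientations < 1:
            raise ValueError("n_orientations must be >= 1")


@dataclass(frozen=True)
class VesselMask:
    """Binary vessel raster with the same shape as its source image."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "pixels", np.asarray(self.pixels, dtype=bool))


def _line_kernel(length: int, angle_rad: float) -> np.ndarray:
    """Mean-filter kernel of a 1-px-wide digital line through the centre."""
    if length == 1:
        return np.ones((1, 1))
    half = (length - 1) // 2
    k = np.zeros((length, length))
    dr, dc = -np.sin(angle_rad), np.cos(angle_rad)
    for t in range(-half, half + 1):
        r = int(round(half + t * dr))
        c = int(round(half + t * dc))
        k[r, c] = 1.0
    return k / k.sum()


def _standardize(a: np.ndarray) -> np.ndarray:
    sd = a.std()
    if sd == 0:
        return np.zeros_like(a)
    return (a - a.mean()) / sd


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Reduce an image array to a float grayscale plane.

    3-channel input keeps the green channel only (highest vessel contrast in
    fundus photography); single-channel input passes through.
    """
    img = np.asarray(image)
    if img.ndim == 3:
        img = img[..., 1]
    return img.astype(float)


def line_response(image: np.ndarray, params: SegmentationParams) -> np.ndarray:
    """Multiscale line-detector response, min–max normalised to [0, 1]."""
    img = to_grayscale(image)
    if not np.all(np.isfinite(img)):
        raise ValueError("image intensities must be finite")
    if min(img.shape) < params.window_size:
        raise ValueError(
            f"window_size {params.window_size} exceeds image extent {img.shape}"
        )
    # work on the inverted image so that dark vessels give positive response
    inv = img.max() - img if params.dark_vessels else img.copy()

    win_mean = ndimage.uniform_filter(inv, size=params.window_size, mode="reflect")
    angles = np.pi * np.arange(params.n_orientations) / params.n_orientations

    responses = []
    for L in params.line_lengths:
        best = np.full(img.shape, -np.inf)
        for ang in angles:
            kern = _line_kernel(L, ang)
            line_mean = ndimage.correlate(inv, kern, mode="reflect")
            np.maximum(best, line_mean, out=best)
        responses.append(_standardize(best - win_mean))
    responses.append(_standardize(inv))

    combined = np.mean(responses, axis=0)
    lo, hi = combined.min(), combined.max()
    if hi == lo:  # structureless image
        return np.zeros_like(combined)
    return (combined - lo) / (hi - lo)


def double_threshold(response: np.ndarray, t_low: float, t_high: float) -> np.ndarray:
    """Hysteresis threshold: seeds at >= t_high grow through >= t_low (8-conn)."""
    if t_low >= t_high:
        raise ValueError(f"need t_low < t_high, got ({t_low}, {t_high})")
    resp = np.asarray(response, dtype=float)
    return apply_hysteresis_threshold(resp, t_low, t_high).astype(bool)


def clean_mask(mask: np.ndarray, min_component_px: int, max_hole_px: int) -> VesselMask:
    """Drop 8-connected components < min_component_px; fill 4-connected holes
    < max_hole_px."""
    m = np.asarray(mask, dtype=bool)
    # max_size removes/fills components of size <= threshold, so pass
    # threshold - 1 to drop strictly-smaller components only
    m = remove_small_objects(m, max_size=min_component_px - 1, connectivity=2)
    m = remove_small_holes(m, max_size=max_hole_px - 1, connectivity=1)
    return VesselMask(m)


def segment_vessels(
    image: np.ndarray, params: SegmentationParams | None = None
) -> VesselMask:
    """Full segmentation: line response -> double threshold -> cleanup."""
    params = params or SegmentationParams()
    resp = line_response(image, params)
    raw = double_threshold(resp, params.t_low, params.t_high)
    return clean_mask(raw, params.min_component_px, params.max_hole_px)
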