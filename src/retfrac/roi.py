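"""Optic-disc-anchored annular regions of interest.

All retinal metrics are evaluated inside annuli concentric with the optic
disc.  With ``R`` the optic-disc radius (in pixels):

* ROI 1 — the vessel-caliber zone 0.5 to 1.0 disc *diameters* beyond the
  disc margin, i.e. radial distances in ``(2R, 3R]``.
* ROI 2 — the tortuosity / monofractal zone, radii ``(1.5R, 3R]``.
* ROI 3 — the whole image minus the optic disc, radii ``(R, edge]``.

Distances are Euclidean from pixel centre to disc centre, in pixel units.
The boundary rule is half-open (``inner < d <= outer``) so that concentric
ROIs partition cleanly; a pixel exactly at distance ``inner`` is excluded.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "OpticDisc",
    "AnnulusROI",
    "InvalidAnnotationError",
    "make_roi1",
    "make_roi2",
    "make_roi3",
    "rasterize_roi",
    "load_disc_annotation",
]


class InvalidAnnotationError(ValueError):
    """Raised for a malformed or geometrically impossible disc annotation."""


@dataclass(frozen=True)
class OpticDisc:
    """Optic-disc annotation: centre (row, col) and radius, all in pixels.

    Coordinates are 0-based pixel indices; the radius must be positive.
    """

    center_row: float
    center_col: float
    radius_px: float

    def __post_init__(self) -> None:
        if not (self.radius_px > 0):
            raise InvalidAnnotationError(
                f"optic-disc radius must be positive, got {self.radius_px!r}"
            )
        for name in ("center_row", "center_col"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise InvalidAnnotationError(f"{name} must be finite, got {v!r}")

    def validate_within(self, shape: tuple[int, int]) -> None:
        """Check the disc centre lies inside an image of the given shape."""
        r, c = self.center_row, self.center_col
        if not (0 <= r < shape[0] and 0 <= c < shape[1]):
            raise InvalidAnnotationError(
                f"disc centre ({r}, {c}) outside image of shape {shape}"
            )


#: sentinel outer radius meaning "to the image edge"
TO_IMAGE_EDGE = math.inf


@dataclass(frozen=True)
class AnnulusROI:
    """Annular region ``inner < d <= outer`` around the optic-disc centre."""

    inner_radius_px: float
    outer_radius_px: float
    label: str

    def __post_init__(self) -> None:
        if not (0 <= self.inner_radius_px < self.outer_radius_px):
            raise InvalidAnnotationError(
                f"need 0 <= inner < outer, got ({self.inner_radius_px}, "
                f"{self.outer_radius_px})"
            )


def make_roi1(disc: OpticDisc) -> AnnulusROI:
    """Caliber zone: 0.5–1.0 disc diameters beyond the disc margin (2R–3R)."""
    R = disc.radius_px
    return AnnulusROI(2.0 * R, 3.0 * R, "ROI1")


def make_roi2(disc: OpticDisc) -> AnnulusROI:
    """Tortuosity / monofractal zone: 1.5–3.0 times the disc radius."""
    R = disc.radius_px
    return AnnulusROI(1.5 * R, 3.0 * R, "ROI2")


def make_roi3(disc: OpticDisc) -> AnnulusROI:
    """Whole image minus the optic disc (outer radius runs to the edge)."""
    return AnnulusROI(disc.radius_px, TO_IMAGE_EDGE, "ROI3")


def rasterize_roi(
    roi: AnnulusROI, disc: OpticDisc, shape: tuple[int, int]
) -> np.ndarray:
    """Rasterize an annulus to a boolean mask of the given (rows, cols) shape.

    A pixel is inside when ``inner < d <= outer`` with ``d`` the Euclidean
    distance from the pixel centre to the disc centre.  Warns and returns an
    all-false mask if the annulus misses the image entirely.
    """
    rows, cols = int(shape[0]), int(shape[1])
    if rows <= 0 or cols <= 0:
        raise ValueError(f"shape must be positive, got {shape}")
    rr = np.arange(rows, dtype=float)[:, None] - disc.center_row
    cc = np.arange(cols, dtype=float)[None, :] - disc.center_col
    d = np.hypot(rr, cc)
    mask = (d > roi.inner_radius_px) & (d <= roi.outer_radius_px)
    if not mask.any():
        warnings.warn(
            f"{roi.label} annulus [{roi.inner_radius_px}, {roi.outer_radius_px}] "
            f"contains no pixel of a {rows}x{cols} image",
            stacklevel=2,
        )
    return mask


def load_disc_annotation(path: str | Path) -> OpticDisc:
    """Read the JSON sidecar {"center_row", "center_col", "radius_px"}."""
    with open(path) as fh:
        data = json.load(fh)
    try:
        return OpticDisc(
            center_row=float(data["center_row"]),
            center_col=float(data["center_col"]),
            radius_px=float(data["radius_px"]),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise InvalidAnnotationError(f"malformed disc annotation {path}: {exc}") from exc
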