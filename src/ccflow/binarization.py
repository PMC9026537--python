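"""Flow-deficit segmentation by Phansalkar local adaptive thresholding.

The Phansalkar threshold was designed for low-contrast stained cytology
images and is the community standard for choriocapillaris flow-deficit
binarization. For each pixel, with local window mean m and population
standard deviation s over a square window of side 2r+1:

    T = m * (1 + p * exp(-q * m) + k * (s / r_dyn - 1))

A pixel is a flow deficit iff its intensity is <= T (deficits are the
dark phase; ties count as deficit so an all-zero image is 100% deficit).

Constants default to the canonical values popularized by the Fiji
Auto Local Threshold implementation: k=0.25, r_dyn=0.5, p=2, q=10 on
[0,1]-normalized intensities. The window is square (the "radius" names
its half-side), which admits an exact separable-filter implementation
and a transparent sliding-window oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .compensation import BOUNDARY_MODE
from .image_io import EnFaceImage

__all__ = [
    "ThresholdParams",
    "BinaryDeficitMask",
    "local_stats",
    "phansalkar_threshold_map",
    "segment_flow_deficits",
]


@dataclass(frozen=True)
class ThresholdParams:
    """Window radius and the four Phansalkar constants."""

    radius_px: int = 4
    k: float = 0.25
    p: float = 2.0
    q: float = 10.0
    r_dyn: float = 0.5

    def __post_init__(self) -> None:
        if not (isinstance(self.radius_px, (int, np.integer)) and self.radius_px >= 1):
            raise ValueError(f"radius_px must be an integer >= 1, got {self.radius_px!r}")
        if not self.r_dyn > 0:
            raise ValueError(f"r_dyn must be > 0, got {self.r_dyn!r}")
        for name in ("k", "p", "q"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)!r}")


@dataclass
class BinaryDeficitMask:
    """Boolean grid marking flow-deficit pixels (True = deficit)."""

    pixels: np.ndarray
    pixel_pitch_um: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError(
                f"mask must be a nonempty 2-D grid, got shape {self.pixels.shape}"
            )
        if not self.pixel_pitch_um > 0:
            raise ValueError(f"pixel_pitch_um must be > 0, got {self.pixel_pitch_um!r}")

    @property
    def deficit_fraction(self) -> float:
        return float(self.pixels.mean())

    def complement(self) -> "BinaryDeficitMask":
        return BinaryDeficitMask(~self.pixels, self.pixel_pitch_um)


def _as_pixels(img) -> np.ndarray:
    return img.pixels if isinstance(img, EnFaceImage) else np.asarray(img, dtype=np.float64)


def local_stats(img, radius_px: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel mean and population SD over the (2r+1)² window, mirror-padded.

    Computed with separable uniform filters on x and x²; the variance is
    clipped at zero to absorb floating-point cancellation.
    """
    pixels = _as_pixels(img)
    if not radius_px >= 1:
        raise ValueError(f"radius_px must be >= 1, got {radius_px!r}")
    if radius_px >= min(pixels.shape):
        raise ValueError(
            f"radius_px={radius_px} too large for image of shape {pixels.shape}"
        )
    size = 2 * int(radius_px) + 1
    mean = ndimage.uniform_filter(pixels, size=size, mode=BOUNDARY_MODE)
    mean_sq = ndimage.uniform_filter(pixels * pixels, size=size, mode=BOUNDARY_MODE)
    var = np.maximum(mean_sq - mean * mean, 0.0)
    return mean, np.sqrt(var)


def phansalkar_threshold_map(img, params: ThresholdParams) -> np.ndarray:
    """Per-pixel Phansalkar threshold T = m(1 + p·e^{-qm} + k(s/r_dyn - 1))."""
    m, s = local_stats(img, params.radius_px)
    return m * (1.0 + params.p * np.exp(-params.q * m) + params.k * (s / params.r_dyn - 1.0))


def segment_flow_deficits(img: EnFaceImage, params: ThresholdParams) -> BinaryDeficitMask:
    """Binarize: deficit wherever intensity <= its local threshold."""
    threshold = phansalkar_threshold_map(img, params)
    return BinaryDeficitMask(
        pixels=img.pixels <= threshold,
        pixel_pitch_um=img.pixel_pitch_um,
    )
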