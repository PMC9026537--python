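"""Signal-attenuation compensation of the en-face flow image.

Deposits above the choriocapillaris cast shadows that darken both the
flow and the structure channel. The compensation chain multiplies the
flow image by the inverted, Gaussian-smoothed structure image, then
rescales by the global maximum:

    compensated = flow * smooth(1 - structure, sigma) / max(...)

Dark (shadowed) structure regions invert to bright multipliers, lifting
the attenuated flow signal before local thresholding. Division by the
global maximum (rather than a min-max stretch) preserves the zero level
that the deficit polarity depends on. All smoothing uses mirror
(symmetric) boundary padding so the corner ROIs see no artificial dark
rim.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image_io import EnFaceImage

__all__ = [
    "CompensationParams",
    "invert_image",
    "gaussian_smooth",
    "compensate_flow",
]

#: scipy.ndimage boundary mode for mirror padding (edge pixel repeated,
#: equivalent to np.pad mode="symmetric"); used for every filter in the package.
BOUNDARY_MODE = "reflect"


@dataclass(frozen=True)
class CompensationParams:
    """Tunables of the compensation stage.

    blur_sigma_px : float
        Standard deviation (pixels) of the Gaussian applied to the
        inverted structure image. Default 2.0: wide enough to suppress
        speckle in the shadow estimate, narrow enough to keep
        deposit-scale shadows.
    """

    blur_sigma_px: float = 2.0

    def __post_init__(self) -> None:
        if not self.blur_sigma_px > 0:
            raise ValueError(f"blur_sigma_px must be > 0, got {self.blur_sigma_px!r}")


def invert_image(img: EnFaceImage) -> EnFaceImage:
    """Photographic negative: every pixel v becomes 1 - v."""
    return img.with_pixels(1.0 - img.pixels)


def gaussian_smooth(img: EnFaceImage, sigma_px: float) -> EnFaceImage:
    """2-D Gaussian blur with mirror boundary handling, clipped to [0, 1]."""
    if not sigma_px > 0:
        raise ValueError(f"sigma_px must be > 0, got {sigma_px!r}")
    blurred = ndimage.gaussian_filter(img.pixels, sigma=sigma_px, mode=BOUNDARY_MODE)
    return img.with_pixels(np.clip(blurred, 0.0, 1.0))


def compensate_flow(
    flow: EnFaceImage,
    structure: EnFaceImage,
    params: CompensationParams | None = None,
) -> EnFaceImage:
    """Compensate the flow image with the co-registered structure image.

    Returns a ``compensated``-modality image whose brightest pixel is
    exactly 1, unless the product is identically zero (returned as-is
    with a warning, no division).
    """
    params = params or CompensationParams()
    if flow.pixels.shape != structure.pixels.shape:
        raise ValueError(
            "flow and structure dimensions differ: "
            f"{flow.pixels.shape} vs {structure.pixels.shape}"
        )
    if flow.pixel_pitch_um != structure.pixel_pitch_um:
        raise ValueError(
            "flow and structure pixel pitch differ: "
            f"{flow.pixel_pitch_um} vs {structure.pixel_pitch_um}"
        )
    shadow = gaussian_smooth(invert_image(structure), params.blur_sigma_px)
    product = flow.pixels * shadow.pixels
    peak = float(product.max())
    if peak == 0.0:
        warnings.warn(
            "compensated product is identically zero; returning all-zero image",
            stacklevel=2,
        )
        out = product
    else:
        out = product / peak
    return EnFaceImage(
        pixels=out,
        pixel_pitch_um=flow.pixel_pitch_um,
        modality="compensated",
        eye_id=flow.eye_id,
    )
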