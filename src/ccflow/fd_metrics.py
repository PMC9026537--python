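"""Corner-ROI extraction and flow-deficit particle metrics.

Quantification is restricted to four 1 × 1 mm squares flush with the
corners of the 6 × 6 mm scan: equidistant, comparable regions that stay
clear of any central neovascular lesion. Corners are named anatomically
(superonasal, superotemporal, inferonasal, inferotemporal); row 0 of the
pixel grid is superior, and the nasal side is resolved from laterality —
for a right eye (OD) the nasal retina is on the left image side
(column 0), for a left eye (OS) on the right. Mirroring an image
left-to-right while flipping laterality therefore leaves every
corner-labeled metric unchanged.

Per ROI, connected components of deficit pixels (8-connectivity, no
size or circularity exclusion, border-touching components included)
yield the four metrics: FD% (deficit area fraction × 100), FD count,
mean FD size in µm², and total FD area in mm². Per-eye values are the
arithmetic means over the four corners.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import fmean

import numpy as np
from scipy import ndimage

from .binarization import BinaryDeficitMask
from .image_io import EnFaceImage

__all__ = [
    "CORNERS",
    "ROISpec",
    "ComponentSet",
    "FDMetrics",
    "EyeAverages",
    "EyeRecord",
    "roi_side_px",
    "extract_corner_rois",
    "label_components",
    "compute_fd_metrics",
    "average_eye_metrics",
    "corner_metrics",
]

CORNERS = ("superonasal", "superotemporal", "inferonasal", "inferotemporal")

#: 8-connectivity structuring element for particle labeling.
_EIGHT = np.ones((3, 3), dtype=bool)


def roi_side_px(size_mm: float, pixel_pitch_um: float) -> int:
    """ROI side in pixels: physical side rounded to the nearest integer."""
    side = int(round(size_mm * 1000.0 / pixel_pitch_um))
    if side < 1:
        raise ValueError(
            f"ROI of {size_mm} mm is below one pixel at pitch {pixel_pitch_um} µm/px"
        )
    return side


@dataclass(frozen=True)
class ROISpec:
    """One corner ROI: anatomical corner, physical size, derived pixel side."""

    corner: str
    size_mm: float
    side_px: int
    pixel_pitch_um: float

    def __post_init__(self) -> None:
        if self.corner not in CORNERS:
            raise ValueError(f"corner must be one of {CORNERS}, got {self.corner!r}")
        if self.side_px < 1:
            raise ValueError("side_px must be >= 1")

    @property
    def area_mm2(self) -> float:
        """Physical ROI area from the realized pixel grid."""
        return (self.side_px * self.pixel_pitch_um / 1000.0) ** 2


@dataclass
class ComponentSet:
    """Labeled flow-deficit particles: label 0 is background (flow)."""

    labels: np.ndarray
    sizes_px: np.ndarray  # pixel count per component, >= 1 each

    @property
    def n_components(self) -> int:
        return int(self.sizes_px.size)


@dataclass(frozen=True)
class FDMetrics:
    """The four per-ROI flow-deficit quantities."""

    fd_percent: float
    n_fd: int
    mean_fd_size_um2: float
    total_fd_area_mm2: float
    roi: ROISpec


@dataclass(frozen=True)
class EyeAverages:
    """Arithmetic means of the four corner metrics."""

    fd_percent: float
    n_fd: float
    mean_fd_size_um2: float
    total_fd_area_mm2: float


@dataclass
class EyeRecord:
    """One eye's labels plus its corner metrics and averages per radius."""

    eye_id: str
    group: str
    mnv_status: str
    # radius_px -> {corner: FDMetrics}
    corner_metrics: dict[int, dict[str, FDMetrics]]
    # radius_px -> EyeAverages
    averages: dict[int, EyeAverages]


def _corner_slices(side_px: int, shape: tuple[int, int], laterality: str):
    """Map anatomical corners to row/col slices. Row 0 = superior."""
    if laterality not in ("OD", "OS"):
        raise ValueError(f"laterality must be 'OD' or 'OS', got {laterality!r}")
    rows, cols = shape
    top = slice(0, side_px)
    bottom = slice(rows - side_px, rows)
    left = slice(0, side_px)
    right = slice(cols - side_px, cols)
    nasal, temporal = (left, right) if laterality == "OD" else (right, left)
    return {
        "superonasal": (top, nasal),
        "superotemporal": (top, temporal),
        "inferonasal": (bottom, nasal),
        "inferotemporal": (bottom, temporal),
    }


def extract_corner_rois(grid, size_mm: float = 1.0, laterality: str = "OD"):
    """Crop the four corner ROIs from an image or deficit mask.

    Returns ``{corner: (ROISpec, crop)}`` where crop has the input's type.
    Rejects ROIs that would overlap (side exceeding half the image in
    either dimension).
    """
    if isinstance(grid, EnFaceImage):
        pixels, pitch = grid.pixels, grid.pixel_pitch_um
    elif isinstance(grid, BinaryDeficitMask):
        pixels, pitch = grid.pixels, grid.pixel_pitch_um
    else:
        raise TypeError(f"expected EnFaceImage or BinaryDeficitMask, got {type(grid)}")
    side = roi_side_px(size_mm, pitch)
    rows, cols = pixels.shape
    if 2 * side > rows or 2 * side > cols:
        raise ValueError(
            f"corner ROIs of {side} px would overlap on a {rows}x{cols} image"
        )
    out = {}
    for corner, (rs, cs) in _corner_slices(side, pixels.shape, laterality).items():
        spec = ROISpec(corner=corner, size_mm=size_mm, side_px=side, pixel_pitch_um=pitch)
        crop = pixels[rs, cs]
        if isinstance(grid, EnFaceImage):
            out[corner] = (spec, grid.with_pixels(crop))
        else:
            out[corner] = (spec, BinaryDeficitMask(crop, pitch))
    return out


def label_components(mask: BinaryDeficitMask) -> ComponentSet:
    """Connected deficit particles under 8-connectivity; no exclusions."""
    labels, n = ndimage.label(mask.pixels, structure=_EIGHT)
    if n == 0:
        sizes = np.zeros(0, dtype=np.int64)
    else:
        sizes = np.bincount(labels.ravel())[1:].astype(np.int64)
    return ComponentSet(labels=labels, sizes_px=sizes)


def compute_fd_metrics(mask: BinaryDeficitMask, roi: ROISpec) -> FDMetrics:
    """Particle metrics of one corner-ROI mask crop."""
    n_px = mask.pixels.size
    deficit_px = int(mask.pixels.sum())
    comps = label_components(mask)
    pitch = mask.pixel_pitch_um
    deficit_area_um2 = deficit_px * pitch * pitch
    return FDMetrics(
        fd_percent=100.0 * deficit_px / n_px,
        n_fd=comps.n_components,
        mean_fd_size_um2=deficit_area_um2 / comps.n_components if comps.n_components else 0.0,
        total_fd_area_mm2=deficit_area_um2 * 1e-6,
        roi=roi,
    )


def average_eye_metrics(corner_metrics: dict[str, FDMetrics] | list[FDMetrics]) -> EyeAverages:
    """Arithmetic mean of each metric over exactly four corner ROIs."""
    values = list(corner_metrics.values()) if isinstance(corner_metrics, dict) else list(corner_metrics)
    if len(values) != 4:
        raise ValueError(f"expected exactly 4 corner metric sets, got {len(values)}")
    return EyeAverages(
        fd_percent=fmean(m.fd_percent for m in values),
        n_fd=fmean(m.n_fd for m in values),
        mean_fd_size_um2=fmean(m.mean_fd_size_um2 for m in values),
        total_fd_area_mm2=fmean(m.total_fd_area_mm2 for m in values),
    )


def corner_metrics(
    mask: BinaryDeficitMask, size_mm: float = 1.0, laterality: str = "OD"
) -> dict[str, FDMetrics]:
    """Crop the four corner ROIs of a full-scan mask and measure each."""
    rois = extract_corner_rois(mask, size_mm=size_mm, laterality=laterality)
    return {corner: compute_fd_metrics(crop, spec) for corner, (spec, crop) in rois.items()}
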